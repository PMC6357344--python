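"""Clonal read-depth stripping and extension of the phasing tree.

For a site pair whose younger member first arises in clone ``m``, only the
reads drawn from clones ``i >= m`` carry information about the pair's
linkage mode.  The remaining clones bias the raw mode counts in a
predictable way: a clone carrying *neither* mutation reads (A,A) on both
haplotypes and inflates the cis class ``N^A`` by its full read share,
while a clone carrying only the older mutation (origin ``a <= i < m``)
reads (B,A) on one haplotype and (A,A) on the other, splitting its share
evenly between the classes.  The default stripping mode removes exactly
that expected non-carrier contribution:

    P^A = |F| * (sum_{i<a} r_i + 1/2 * sum_{a<=i<m} r_i)
    P^B = |F| * (1/2 * sum_{a<=i<m} r_i)

where ``a``/``m`` are the smaller/larger origin-clone labels of the pair
and ``r_i`` the clone proportions.  The adjusted counts ``N^hat = N - P``
(clamped at zero) feed a re-normalized weight

    W' = f'_A - f'_B,   f'_A = (((1-eps)^2+eps^2) N^A_hat
                                + 2 eps (1-eps) N^B_hat) / (N^A_hat + N^B_hat),

and a pair becomes an edge of the stripped graph G' iff ``|W'| > delta``
(default 0.1) and its support meets the coverage threshold.  The phased
founding-clone forest is then extended through G' exactly as it was grown,
each newly attached site inheriting its state from the edge sign.  If
sites remain unattached, the coverage and weight thresholds are halved
(down to floors) and the extension retried, trading precision for a lower
false-negative rate.

An alternative mode, ``"as-printed"``, applies the literal level-``k``
formulas ``P^A = |F| (sum_{0<=i<=k} r_i + 1/2 sum_{i>k} r_i)`` and
``P^B = |F| * 1/2 sum_{i>k} r_i`` with clamping; since those sums total
``|F|`` for normalized proportions, it zeroes most counts and is retained
for fidelity experiments only.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Mapping, Sequence

import numpy as np

from .phasing import (
    LinkageCounts,
    PhasedTree,
    PhasingGraph,
    SpanningForest,
    edge_weight,
)
import heapq

MODE_AS_PRINTED = "as-printed"
MODE_UNINFORMATIVE = "uninformative-read"


@dataclasses.dataclass(frozen=True)
class StrippedCounts:
    """Adjusted linkage-class counts after removing non-carrier depth."""

    p_a: float
    p_b: float
    n_a_hat: float
    n_b_hat: float

    @property
    def total(self) -> float:
        return self.n_a_hat + self.n_b_hat


@dataclasses.dataclass
class StripConfig:
    """Thresholds for the stripped graph and its adaptive loosening."""

    delta: float = 0.1
    cov: float = 2.0
    delta_floor: float = 0.025
    cov_floor: float = 1.0
    mode: str = MODE_UNINFORMATIVE
    adaptive: bool = True
    max_extra_rounds: int = 2

    def __post_init__(self):
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie in (0, 1)")
        if self.delta_floor > self.delta or self.cov_floor > self.cov:
            raise ValueError("floors must not exceed the initial thresholds")
        if self.mode not in (MODE_AS_PRINTED, MODE_UNINFORMATIVE):
            raise ValueError(f"unknown strip mode {self.mode!r}")


def strip_counts(
    counts,
    proportions,
    k: int,
    k_young: int | None = None,
    mode: str = MODE_UNINFORMATIVE,
) -> StrippedCounts:
    """Strip the expected non-carrier read depth from a pair's counts.

    ``k`` is the origin clone of the older site and ``k_young`` (>= k,
    default equal) that of the younger site; only clones from ``k_young``
    up carry both mutations.  In ``"as-printed"`` mode ``k`` is the last
    fully stripped level and ``k_young`` is ignored.
    """
    r = np.asarray(proportions, dtype=float)
    if abs(r.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must sum to 1")
    if k_young is None:
        k_young = k
    if not (0 <= k <= k_young < len(r)):
        raise ValueError("clone indices out of range")
    if isinstance(counts, LinkageCounts):
        n_a, n_b, total = counts.n_cis, counts.n_trans, counts.total
    else:
        arr = np.asarray(counts, dtype=float)
        n_a = arr[0] + arr[3]
        n_b = arr[1] + arr[2]
        total = arr.sum()
    if mode == MODE_AS_PRINTED:
        p_a = total * (r[: k + 1].sum() + 0.5 * r[k + 1 :].sum())
        p_b = total * 0.5 * r[k + 1 :].sum()
    elif mode == MODE_UNINFORMATIVE:
        half = 0.5 * r[k:k_young].sum()
        p_a = total * (r[:k].sum() + half)
        p_b = total * half
    else:
        raise ValueError(f"unknown strip mode {mode!r}")
    return StrippedCounts(
        p_a=p_a,
        p_b=p_b,
        n_a_hat=max(n_a - p_a, 0.0),
        n_b_hat=max(n_b - p_b, 0.0),
    )


def stripped_weight(stripped: StrippedCounts, epsilon: float) -> float:
    """Re-normalized linkage weight ``W'`` from adjusted counts.

    Raises when no informative depth survives the strip (no-edge signal).
    """
    if stripped.total <= 0:
        raise ValueError("no informative depth after stripping")
    counts = LinkageCounts(n_aa=stripped.n_a_hat, n_ab=stripped.n_b_hat)
    return edge_weight(counts, epsilon)


def build_stripped_graph(
    pair_counts: Mapping[tuple[int, int], np.ndarray],
    assignments: np.ndarray,
    proportions,
    epsilon: float,
    delta: float = 0.1,
    cov: float = 2.0,
    mode: str = MODE_UNINFORMATIVE,
    homozygous: np.ndarray | None = None,
) -> PhasingGraph:
    """The stripped graph G' over pairs involving a descendant site.

    Founding-founding pairs are excluded (they were handled in G).  A pair
    becomes an edge iff its support reaches ``cov``, informative depth
    survives the strip, and ``|W'| > delta`` (strict).
    """
    edges: dict[tuple[int, int], tuple[float, float, np.ndarray]] = {}
    vertices: set[int] = set()
    for (i, j), c4 in pair_counts.items():
        si, sj = int(assignments[i]), int(assignments[j])
        if si < 0 or sj < 0:
            continue
        if homozygous is not None and (homozygous[i] or homozygous[j]):
            continue
        if si == 0 and sj == 0:
            continue
        a, m = (si, sj) if si <= sj else (sj, si)
        sc = strip_counts(c4, proportions, a, m, mode)
        # the pair's coverage level in the stripped data is the depth that
        # survives the strip; the Cov threshold applies to that
        if sc.total < cov or sc.total <= 0:
            continue
        w = stripped_weight(sc, epsilon)
        # strict threshold, robust to float rounding at the boundary
        if abs(w) > delta + 1e-12:
            # rank stripped edges by surviving informative depth: after
            # clamping, |W'| saturates and no longer reflects reliability
            edges[(i, j)] = (w, sc.total, c4)
            vertices.add(i)
            vertices.add(j)
    return PhasingGraph(
        vertices=np.asarray(sorted(vertices), dtype=np.int64), edges=edges
    )


def extend_tree(
    forest: SpanningForest,
    gprime: PhasingGraph,
    config: StripConfig | None = None,
    rebuild: Callable[[float, float], PhasingGraph] | None = None,
    target_vertices: Sequence[int] | None = None,
) -> SpanningForest:
    """Extend the phased forest T into T' through the stripped graph.

    Frontier-greedy exactly like the initial growth, but seeded with the
    existing trees' vertices and phases; an edge joining two already
    phased trees is skipped (trees are never merged, so fragment
    boundaries are preserved).  Components of G' touching no phased vertex
    are grown as fresh trees (descendant-only fragments).

    With ``config.adaptive`` and a ``rebuild(cov, delta)`` callback, the
    thresholds are halved (not below their floors) and the extension
    retried while target vertices remain unattached, at most
    ``max_extra_rounds`` times.
    """
    config = config or StripConfig()
    trees = [
        PhasedTree(
            seed=t.seed,
            vertices=list(t.vertices),
            edges=list(t.edges),
            phase=dict(t.phase),
        )
        for t in forest.trees
    ]
    out = SpanningForest(trees=trees)
    _extend_once(out, gprime)
    if config.adaptive and rebuild is not None:
        cov, delta = config.cov, config.delta
        targets = (
            set(int(v) for v in target_vertices)
            if target_vertices is not None
            else set(gprime.vertices.tolist())
        )
        for _ in range(config.max_extra_rounds):
            placed = set(out.phase_map())
            if targets <= placed:
                break
            if cov <= config.cov_floor and delta <= config.delta_floor:
                break
            cov = max(cov / 2.0, config.cov_floor)
            delta = max(delta / 2.0, config.delta_floor)
            _extend_once(out, rebuild(cov, delta))
    return out


def _extend_once(forest: SpanningForest, graph: PhasingGraph) -> None:
    adj = graph.adjacency()
    phased: dict[int, PhasedTree] = forest.vertex_tree()
    heap: list[tuple[float, float, int, int, float]] = []
    for t in forest.trees:
        for v in t.vertices:
            for (u, w, f) in adj.get(v, ()):
                if u not in phased:
                    heapq.heappush(heap, (-abs(w), -f, v, u, w))
    while heap:
        _, _, u, v, w = heapq.heappop(heap)
        if v in phased:
            continue
        tree = phased[u]
        tree.vertices.append(v)
        tree.edges.append((u, v, w))
        tree.phase[v] = tree.phase[u] if w >= 0 else 1 - tree.phase[u]
        phased[v] = tree
        for (x, wx, fx) in adj.get(v, ()):
            if x not in phased:
                heapq.heappush(heap, (-abs(wx), -fx, v, x, wx))
    # descendant-only components: grow fresh trees the same way
    remaining = [v for v in graph.vertices.tolist() if v not in phased and adj[v]]
    if remaining:
        from .phasing import grow_spanning_forest

        sub_edges = {
            (i, j): e
            for (i, j), e in graph.edges.items()
            if i not in phased and j not in phased
        }
        sub = PhasingGraph(
            vertices=np.asarray(sorted(remaining), dtype=np.int64),
            edges=sub_edges,
        )
        for t in grow_spanning_forest(sub).trees:
            if len(t.vertices) > 1:
                forest.trees.append(t)
                for v in t.vertices:
                    phased[v] = t
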