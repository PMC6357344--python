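"""Weighted phasing graph and greedy maximum spanning forest.

For a pair of variant sites the short chains covering both fall into the
cis modes {(A,A), (B,B)} or the trans modes {(A,B), (B,A)}.  With a
per-base error probability ``epsilon``, a chain drawn from a cis-linked
haplotype reports a cis mode with probability ``(1-eps)^2 + eps^2`` and a
trans mode with probability ``2*eps*(1-eps)`` (both sites correct or both
flipped versus exactly one flipped).  The edge weight is the difference of
the two error-aware mode probabilities,

    W = f_A - f_B,
    f_A = (((1-eps)^2 + eps^2) * N^A + 2*eps*(1-eps) * N^B) / |F|,

with ``N^A = N_AA + N_BB``, ``N^B = N_AB + N_BA`` and ``|F|`` the total
support.  ``f_A + f_B = 1`` always, so ``W`` lies in [-1, 1]; its sign
encodes the linkage mode (positive = cis) and its magnitude the
reliability.  Pairs with support below a coverage threshold ``Cov``
(default 2) get no edge.

Phasing proceeds per connected component: a seed vertex is anchored to
state B and the component is grown frontier-greedily, always adding the
incident edge of largest ``|W|`` — Prim's algorithm under ``|W|``, which
yields a maximum spanning tree.  Each vertex's state on the tracked
haplotype follows from the edge sign (positive = same state as its
neighbor).  Phase is recoverable only up to a global flip per component.
"""

from __future__ import annotations

import dataclasses
import heapq
from typing import Iterable, Mapping, Sequence

import numpy as np

from .assembly import ShortChain

#: mode index encoding: m = 2 * state_i + state_j
MODE_AA, MODE_AB, MODE_BA, MODE_BB = 0, 1, 2, 3


@dataclasses.dataclass(frozen=True)
class LinkageCounts:
    """Per-pair mode counts (chain support, weighted by multiplicity)."""

    n_aa: float = 0.0
    n_ab: float = 0.0
    n_ba: float = 0.0
    n_bb: float = 0.0

    @property
    def n_cis(self) -> float:
        """N^A: support for the {(A,A), (B,B)} linkage class."""
        return self.n_aa + self.n_bb

    @property
    def n_trans(self) -> float:
        """N^B: support for the {(A,B), (B,A)} linkage class."""
        return self.n_ab + self.n_ba

    @property
    def total(self) -> float:
        return self.n_aa + self.n_ab + self.n_ba + self.n_bb

    @classmethod
    def from_array(cls, arr) -> "LinkageCounts":
        return cls(*(float(v) for v in arr))

    def as_array(self) -> np.ndarray:
        return np.array([self.n_aa, self.n_ab, self.n_ba, self.n_bb])


def count_linkage(chains: Iterable[ShortChain], i: int, j: int) -> LinkageCounts:
    """Tally linkage modes for one site pair over the given chains.

    Each chain covering both sites contributes the summed multiplicity of
    its supporting VPEs that themselves cover both sites, in the mode given
    by the chain's states.
    """
    counts = np.zeros(4)
    for c in chains:
        if i in c.states and j in c.states:
            mult = sum(
                v.multiplicity
                for v in c.support
                if i in v.sites and j in v.sites
            )
            if mult:
                counts[2 * c.states[i] + c.states[j]] += mult
    return LinkageCounts.from_array(counts)


# pair-index templates, cached by VPE length
_PAIR_TEMPLATES: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _pair_template(n: int):
    t = _PAIR_TEMPLATES.get(n)
    if t is None:
        t = np.triu_indices(n, k=1)
        _PAIR_TEMPLATES[n] = t
    return t


def linkage_table(
    chains: Iterable[ShortChain], n_sites: int
) -> dict[tuple[int, int], np.ndarray]:
    """All pairwise linkage counts in one pass.

    Returns ``{(i, j): [N_AA, N_AB, N_BA, N_BB]}`` with ``i < j``.
    Equivalent to :func:`count_linkage` over every covered pair, but
    vectorized: every supporting VPE contributes its multiplicity to all
    site pairs it covers, in the chain's (= its own) linkage mode.
    """
    ii, jj, mode, wt = [], [], [], []
    for c in chains:
        for v in c.support:
            L = len(v.sites)
            if L < 2:
                continue
            a, b = _pair_template(L)
            s = np.asarray(v.sites)
            st = np.asarray(v.states)
            ii.append(s[a])
            jj.append(s[b])
            mode.append(2 * st[a] + st[b])
            wt.append(np.full(len(a), float(v.multiplicity)))
    if not ii:
        return {}
    ii = np.concatenate(ii)
    jj = np.concatenate(jj)
    mode = np.concatenate(mode)
    wt = np.concatenate(wt)
    key = (ii.astype(np.int64) * n_sites + jj) * 4 + mode
    uniq, inv = np.unique(key, return_inverse=True)
    sums = np.bincount(inv, weights=wt)
    table: dict[tuple[int, int], np.ndarray] = {}
    pair_key = uniq // 4
    modes = uniq % 4
    for k in range(len(uniq)):
        pk = int(pair_key[k])
        pair = (pk // n_sites, pk % n_sites)
        arr = table.get(pair)
        if arr is None:
            arr = np.zeros(4)
            table[pair] = arr
        arr[modes[k]] = sums[k]
    return table


def edge_weight(counts, epsilon: float) -> float:
    """Error-aware linkage weight ``W = f_A - f_B`` for one site pair.

    Raises if the pair has no support (an undefined weight means no edge).
    """
    if not (0.0 <= epsilon < 1.0):
        raise ValueError("epsilon must lie in [0, 1)")
    if isinstance(counts, LinkageCounts):
        n_cis, n_trans = counts.n_cis, counts.n_trans
    else:
        arr = np.asarray(counts, dtype=float)
        n_cis = arr[MODE_AA] + arr[MODE_BB]
        n_trans = arr[MODE_AB] + arr[MODE_BA]
    total = n_cis + n_trans
    if total <= 0:
        raise ValueError("edge weight undefined for zero support")
    both = (1 - epsilon) ** 2 + epsilon**2
    one = 2 * epsilon * (1 - epsilon)
    f_a = (both * n_cis + one * n_trans) / total
    f_b = (both * n_trans + one * n_cis) / total
    return f_a - f_b


@dataclasses.dataclass
class PhasingGraph:
    """Weighted undirected graph over variant-site vertices.

    ``edges[(i, j)] = (W, F, counts4)`` with ``i < j``; an edge exists only
    where the pair's support met the coverage threshold (and, for stripped
    graphs, the weight threshold).
    """

    vertices: np.ndarray
    edges: dict[tuple[int, int], tuple[float, float, np.ndarray]]

    def adjacency(self) -> dict[int, list[tuple[int, float, float]]]:
        adj: dict[int, list[tuple[int, float, float]]] = {
            int(v): [] for v in self.vertices
        }
        for (i, j), (w, f, _) in self.edges.items():
            adj[i].append((j, w, f))
            adj[j].append((i, w, f))
        return adj


def build_graph(
    pair_counts: Mapping[tuple[int, int], np.ndarray],
    vertices: Sequence[int],
    epsilon: float,
    cov: float = 2.0,
) -> PhasingGraph:
    """Graph over the founding-clone sites.

    An edge joins every vertex pair whose support ``|F|`` reaches the
    coverage threshold; the weight is :func:`edge_weight`.
    """
    vert = np.asarray(sorted(int(v) for v in vertices), dtype=np.int64)
    vset = set(vert.tolist())
    edges: dict[tuple[int, int], tuple[float, float, np.ndarray]] = {}
    for (i, j), c4 in pair_counts.items():
        if i not in vset or j not in vset:
            continue
        total = float(c4.sum())
        if total < cov:
            continue
        edges[(i, j)] = (edge_weight(c4, epsilon), total, c4)
    return PhasingGraph(vertices=vert, edges=edges)


@dataclasses.dataclass
class PhasedTree:
    """One phased connected component: a spanning tree plus vertex states.

    ``phase[v]`` is the state (0 = A, 1 = B) of site ``v`` on the tracked
    haplotype; the whole tree's phase is defined only up to a global flip.
    """

    seed: int
    vertices: list[int]
    edges: list[tuple[int, int, float]]
    phase: dict[int, int]


@dataclasses.dataclass
class SpanningForest:
    trees: list[PhasedTree]

    def phase_map(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for t in self.trees:
            out.update(t.phase)
        return out

    def vertex_tree(self) -> dict[int, PhasedTree]:
        out: dict[int, PhasedTree] = {}
        for t in self.trees:
            for v in t.vertices:
                out[v] = t
        return out

    @property
    def n_vertices(self) -> int:
        return sum(len(t.vertices) for t in self.trees)

    def total_weight(self) -> float:
        return sum(abs(w) for t in self.trees for (_, _, w) in t.edges)


def grow_spanning_forest(graph: PhasingGraph) -> SpanningForest:
    """Maximum spanning forest under ``|W|``, phased as it grows.

    Per connected component the seed is the vertex with the largest summed
    incident ``|W|`` (ties: smaller index), anchored to state B.  Frontier
    edges are added in order of decreasing ``|W|`` (ties: larger support,
    then smaller indices); each new vertex's state follows the edge sign.
    """
    adj = graph.adjacency()
    forest = SpanningForest(trees=[])
    visited: set[int] = set()
    strength = {
        v: sum(abs(w) for (_, w, _) in nbrs) for v, nbrs in adj.items()
    }
    for v in graph.vertices.tolist():
        if v in visited or not adj[v]:
            continue
        comp = _component(adj, v)
        seed = min(comp, key=lambda u: (-strength[u], u))
        tree = _grow_tree(adj, seed, visited)
        forest.trees.append(tree)
    # vertices with no incident edge become unphased singleton trees
    for v in graph.vertices.tolist():
        if v not in visited:
            visited.add(v)
            forest.trees.append(
                PhasedTree(seed=v, vertices=[v], edges=[], phase={v: 1})
            )
    return forest


def _component(adj, start) -> list[int]:
    seen = {start}
    stack = [start]
    while stack:
        u = stack.pop()
        for (w, _, _) in adj[u]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return sorted(seen)


def _grow_tree(adj, seed: int, visited: set[int]) -> PhasedTree:
    tree = PhasedTree(seed=seed, vertices=[seed], edges=[], phase={seed: 1})
    visited.add(seed)
    heap: list[tuple[float, float, int, int, float]] = []
    _push_edges(heap, adj, seed, visited)
    while heap:
        _, _, u, v, w = heapq.heappop(heap)
        if v in visited:
            continue
        visited.add(v)
        tree.vertices.append(v)
        tree.edges.append((u, v, w))
        tree.phase[v] = tree.phase[u] if w >= 0 else 1 - tree.phase[u]
        _push_edges(heap, adj, v, visited)
    return tree


def _push_edges(heap, adj, u, visited):
    for (v, w, f) in adj[u]:
        if v not in visited:
            heapq.heappush(heap, (-abs(w), -f, u, v, w))
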