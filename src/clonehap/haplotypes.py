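"""From the extended phasing forest to the 2I clonal haplotypes, and scoring.

Each phased tree is linearized into a *fragment*: its sites sorted by
reference position, with their tracked states forming one haplotype of the
last (youngest) sub-clone over that span; trees with fewer than two sites
carry no linkage information and are not reported.  Since every placed
site is heterozygous in the last clone, its companion haplotype is the
sitewise complement.  The ancestral clones' haplotypes follow from the
inheritance principle: walking from clone ``i+1`` back to clone ``i``,

    h_{2i,j} = A                          if h_{2(i+1),j} = A
             = B   if sub(j) <= i         (the mutation predates clone i+1)
             = A   if sub(j) > i          (the mutation arose later)

and the companion chain is the complement wherever the site already exists
in clone ``i`` (``sub(j) <= i``), reference state otherwise.

Reconstruction quality is summarized by four quantities: the recognition
rate (fraction of all variant sites placed into some fragment), the
accuracy rate (fraction of placed sites whose clone label and haplotype
side match the truth, after choosing per fragment the global flip that
maximizes matches — absolute phase is unobservable), the longest fragment
span in reference bp, and the fragment count.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np

from .phasing import SpanningForest
from .simulate import TruthSet

logger = logging.getLogger(__name__)

UNPLACED = -1


@dataclasses.dataclass
class Fragment:
    """A maximal run of tree-connected, phased sites."""

    sites: np.ndarray  # site indices, sorted by reference position
    states: np.ndarray  # tracked-haplotype states (0/1) per site
    start_pos: int
    end_pos: int

    @property
    def span(self) -> int:
        """Reference-bp extent, inclusive of both end sites."""
        return self.end_pos - self.start_pos + 1

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclasses.dataclass
class HaplotypeSet:
    """The reconstructed 2I x N haplotype matrix plus its fragments.

    Matrix cells are 1 (B), 0 (A) or -1 (unplaced).  Rows ``2i`` and
    ``2i+1`` are clone ``i``'s haplotype pair; row ``2(I-1)`` is the
    tracked haplotype the fragments were phased on.
    """

    matrix: np.ndarray
    fragments: list[Fragment]
    sub: np.ndarray
    n_subclones: int

    @property
    def placed(self) -> np.ndarray:
        return np.flatnonzero(self.matrix[-2] != UNPLACED)


def linearize_tree(
    forest: SpanningForest, positions: np.ndarray, min_sites: int = 2
) -> list[Fragment]:
    """Sort each phased tree by reference position into a fragment.

    Trees with fewer than ``min_sites`` sites (isolated vertices) are
    dropped: a lone site is not linked to anything, so no part of a
    haplotype has been recognized at it.
    """
    frags: list[Fragment] = []
    for t in forest.trees:
        if len(t.vertices) < min_sites:
            continue
        sites = np.asarray(sorted(t.vertices, key=lambda v: positions[v]))
        states = np.asarray([t.phase[v] for v in sites], dtype=np.int8)
        frags.append(
            Fragment(
                sites=sites,
                states=states,
                start_pos=int(positions[sites[0]]),
                end_pos=int(positions[sites[-1]]),
            )
        )
    frags.sort(key=lambda f: f.start_pos)
    return frags


def derive_ancestors(
    fragments: list[Fragment],
    assignments: np.ndarray,
    n_subclones: int,
    n_sites: int,
) -> HaplotypeSet:
    """Fill the full 2I x N matrix from the last-clone fragments.

    A placed site lacking a clone label cannot be propagated through the
    inheritance formulas and is excluded (with a log message).  The output
    always satisfies the inheritance invariant by construction; it is
    asserted anyway.
    """
    I = n_subclones
    mat = np.full((2 * I, n_sites), UNPLACED, dtype=np.int8)
    kept_fragments: list[Fragment] = []
    for f in fragments:
        labelled = assignments[f.sites] >= 0
        if not np.all(labelled):
            logger.info(
                "derive_ancestors: dropping %d unlabelled site(s) from a fragment",
                int((~labelled).sum()),
            )
        sites = f.sites[labelled]
        states = f.states[labelled]
        if len(sites) < 2:
            continue
        if np.all(labelled):
            kept_fragments.append(f)
        else:
            kept_fragments.append(
                Fragment(
                    sites=sites,
                    states=states,
                    start_pos=int(f.start_pos),
                    end_pos=int(f.end_pos),
                )
            )
        sub = assignments[sites]
        mat[2 * (I - 1), sites] = states
        mat[2 * (I - 1) + 1, sites] = 1 - states
        for i in range(I - 2, -1, -1):
            child = mat[2 * (i + 1), sites]
            father = np.where((child == 1) & (sub <= i), 1, 0).astype(np.int8)
            mat[2 * i, sites] = father
            mat[2 * i + 1, sites] = np.where(sub <= i, 1 - father, 0).astype(
                np.int8
            )
    hset = HaplotypeSet(
        matrix=mat,
        fragments=kept_fragments,
        sub=np.asarray(assignments),
        n_subclones=I,
    )
    _assert_inheritance(hset)
    return hset


def _assert_inheritance(hset: HaplotypeSet) -> None:
    mat = hset.matrix
    for i in range(hset.n_subclones - 1):
        for off in (0, 1):
            parent = mat[2 * i + off]
            child = mat[2 * (i + 1) + off]
            bad = (parent == 1) & (child == 0)
            if np.any(bad):
                raise AssertionError(
                    "inheritance violated in derived haplotypes at sites "
                    f"{np.flatnonzero(bad)[:5].tolist()}"
                )


@dataclasses.dataclass
class Metrics:
    """The four reconstruction-quality summaries."""

    recognition_rate: float
    accuracy_rate: float
    longest_length: int
    fragment_count: int
    n_sites: int
    n_placed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def score(hset: HaplotypeSet, truth: TruthSet) -> Metrics:
    """Score a reconstruction against the simulation truth.

    A placed site counts as correct when its inferred clone label equals
    the true origin clone and its haplotype side matches the truth under
    the per-fragment global flip that maximizes matches (phase is defined
    only up to a flip per fragment).
    """
    n = truth.n_sites
    if hset.matrix.shape[1] != n:
        raise ValueError(
            "reconstruction and truth cover different site sets "
            f"({hset.matrix.shape[1]} vs {n})"
        )
    n_placed = 0
    n_correct = 0
    longest = 0
    for f in hset.fragments:
        sites = f.sites
        n_placed += len(sites)
        longest = max(longest, f.span)
        clone_ok = hset.sub[sites] == truth.sub[sites]
        # tracked haplotype = side 0 by convention; state B puts the
        # mutation on the tracked side
        side_hat = np.where(f.states == 1, 0, 1)
        m0 = int(np.sum(clone_ok & (side_hat == truth.side[sites])))
        m1 = int(np.sum(clone_ok & ((1 - side_hat) == truth.side[sites])))
        n_correct += max(m0, m1)
    return Metrics(
        recognition_rate=n_placed / n if n else 0.0,
        accuracy_rate=n_correct / n_placed if n_placed else 0.0,
        longest_length=longest,
        fragment_count=len(hset.fragments),
        n_sites=n,
        n_placed=n_placed,
    )
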