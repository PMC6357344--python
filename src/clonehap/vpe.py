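"""Collapsing read pairs to variant-position extracts (VPEs).

A VPE is a read pair reduced to the ordered allele states it carries at the
known variant sites: ``A`` for the reference base, ``B`` for the alternate.
Read pairs carrying fewer than two variant sites are discarded — a single
site says nothing about linkage.  Read pairs whose extracts are identical
(same sites, same states) collapse into one VPE with summed multiplicity,
which is what makes downstream assembly tractable.

States are encoded internally as integers: 0 = A (reference), 1 = B
(alternate).  A base matching neither allele (sequencing error to a third
base) removes that site from the extract, as does a disagreement between
overlapping mates; the model is strictly biallelic.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np

from .simulate import ReadPairSet

logger = logging.getLogger(__name__)

#: state codes
A, B = 0, 1
_OTHER = 2  # third allele / conflict marker, never emitted in a VPE

STATE_CHARS = ("A", "B")


@dataclasses.dataclass(frozen=True)
class VariantSite:
    """One biallelic SNV locus (positions are 0-based internally)."""

    index: int
    position: int
    ref: str
    alt: str
    vaf: float | None = None
    sub: int | None = None


class SiteSet:
    """Position-sorted, consecutively indexed variant sites.

    The workhorse container: parallel numpy arrays over sites, with
    optional per-site VAF (``vaf``) and clone labels (``sub``) attached by
    later pipeline stages.
    """

    def __init__(self, positions, ref_codes, alt_codes):
        positions = np.asarray(positions, dtype=np.int64)
        ref_codes = np.asarray(ref_codes, dtype=np.uint8)
        alt_codes = np.asarray(alt_codes, dtype=np.uint8)
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        if len(positions) and np.any(np.diff(positions) == 0):
            raise ValueError("duplicate variant positions")
        self.positions = positions
        self.ref_codes = ref_codes[order]
        self.alt_codes = alt_codes[order]
        self.vaf: np.ndarray | None = None
        self.sub: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.positions)

    def site(self, j: int) -> VariantSite:
        from .simulate import BASES

        return VariantSite(
            index=j,
            position=int(self.positions[j]),
            ref=chr(BASES[self.ref_codes[j]]),
            alt=chr(BASES[self.alt_codes[j]]),
            vaf=None if self.vaf is None else float(self.vaf[j]),
            sub=None if self.sub is None else int(self.sub[j]),
        )

    def __iter__(self):
        return (self.site(j) for j in range(len(self)))

    @classmethod
    def from_truth(cls, truth) -> "SiteSet":
        return cls(truth.positions, truth.ref_codes, truth.alt_codes)


@dataclasses.dataclass(frozen=True)
class VPE:
    """One collapsed variant-position extract.

    ``sites`` are strictly increasing site indices; ``states`` the matching
    allele states (0 = A, 1 = B); ``multiplicity`` the number of read pairs
    that collapsed into this extract.
    """

    sites: tuple[int, ...]
    states: tuple[int, ...]
    multiplicity: int = 1

    def __post_init__(self):
        if len(self.sites) < 2:
            raise ValueError("a VPE needs at least two variant sites")
        if len(self.sites) != len(self.states):
            raise ValueError("sites and states must align")
        if any(b <= a for a, b in zip(self.sites, self.sites[1:])):
            raise ValueError("site indices must be strictly increasing")

    @property
    def start(self) -> int:
        return self.sites[0]


def _site_calls(read_set: ReadPairSet, positions: np.ndarray):
    """All (pair, site, base) observations of one library.

    Returns parallel arrays: pair index within the library, site index, and
    the observed base code at that site.
    """
    rl = read_set.read_length
    n = read_set.n_pairs
    starts = np.concatenate([read_set.start1, read_set.start2])
    seqs = np.concatenate([read_set.seq1, read_set.seq2], axis=0)
    pair_ids = np.concatenate([np.arange(n), np.arange(n)])
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    seqs = seqs[order]
    pair_ids = pair_ids[order]
    out_pair, out_site, out_base = [], [], []
    for j, p in enumerate(positions):
        lo = np.searchsorted(starts, p - rl + 1, side="left")
        hi = np.searchsorted(starts, p, side="right")
        if hi > lo:
            offsets = (p - starts[lo:hi]).astype(np.intp)
            out_base.append(seqs[np.arange(lo, hi), offsets])
            out_site.append(np.full(hi - lo, j, dtype=np.int64))
            out_pair.append(pair_ids[lo:hi])
    if not out_pair:
        e = np.empty(0, dtype=np.int64)
        return e, e, e.astype(np.uint8)
    return (
        np.concatenate(out_pair),
        np.concatenate(out_site),
        np.concatenate(out_base),
    )


def compute_vaf(read_set: ReadPairSet, sites: SiteSet) -> np.ndarray:
    """Per-site variant allele frequency from one library's pileup.

    ``V_p`` = reads supporting the alternate base / reads covering the
    site.  Sites with zero depth get ``nan`` and are excluded downstream.
    """
    pair, site, base = _site_calls(read_set, sites.positions)
    n = len(sites)
    depth = np.bincount(site, minlength=n).astype(float)
    alt_mask = base == sites.alt_codes[site]
    alt = np.bincount(site[alt_mask], minlength=n).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1), np.nan)
    vaf[depth == 0] = np.nan
    return vaf


def extract_vpes(
    read_sets: Iterable[ReadPairSet] | ReadPairSet, sites: SiteSet
) -> list[VPE]:
    """Collapse every retained read pair (>= 2 covered sites) to a VPE.

    Observations at a site matching neither allele are dropped from the
    extract, as are sites where the two mates of a pair disagree; a pair is
    retained only if at least two sites survive.  Identical extracts merge
    with summed multiplicity.  The sum of multiplicities over the result
    equals the number of retained pairs.
    """
    if isinstance(read_sets, ReadPairSet):
        read_sets = [read_sets]
    counts: dict[tuple[tuple[int, ...], tuple[int, ...]], int] = {}
    ref_codes = sites.ref_codes
    alt_codes = sites.alt_codes
    for rs in read_sets:
        pair, site, base = _site_calls(rs, sites.positions)
        if len(pair) == 0:
            continue
        state = np.full(len(pair), _OTHER, dtype=np.int8)
        state[base == ref_codes[site]] = A
        state[base == alt_codes[site]] = B
        order = np.lexsort((site, pair))
        pair, site, state = pair[order], site[order], state[order]
        bounds = np.flatnonzero(np.diff(pair)) + 1
        for s_arr, st_arr in zip(
            np.split(site, bounds), np.split(state, bounds)
        ):
            key = _pair_extract(s_arr, st_arr)
            if key is not None:
                counts[key] = counts.get(key, 0) + 1
    vpes = [
        VPE(sites=k[0], states=k[1], multiplicity=m) for k, m in counts.items()
    ]
    vpes.sort(key=lambda v: (v.sites, v.states))
    return vpes


def _pair_extract(site_arr, state_arr):
    """Resolve one pair's site observations into a VPE key, or None."""
    out_sites: list[int] = []
    out_states: list[int] = []
    i, n = 0, len(site_arr)
    while i < n:
        j = i + 1
        st = int(state_arr[i])
        while j < n and site_arr[j] == site_arr[i]:
            if state_arr[j] != st:
                st = _OTHER  # overlapping mates disagree: drop the site
            j += 1
        if st != _OTHER:
            out_sites.append(int(site_arr[i]))
            out_states.append(st)
        i = j
    if len(out_sites) < 2:
        return None
    return tuple(out_sites), tuple(out_states)
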