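"""Independent oracles and small builders used across the test suite."""

from __future__ import annotations

import itertools

import numpy as np

from clonehap import ReadPairSet, SiteSet, VPE
from clonehap.simulate import encode_sequence


def make_sites(positions, ref="A", alt="C"):
    """A SiteSet with uniform ref/alt bases at the given positions."""
    n = len(positions)
    refs = np.full(n, encode_sequence(ref)[0], dtype=np.uint8)
    alts = np.full(n, encode_sequence(alt)[0], dtype=np.uint8)
    return SiteSet(np.asarray(positions), refs, alts)


def make_pairs(reference, pair_specs, read_length):
    """Hand-build a ReadPairSet.

    ``pair_specs`` is a list of ``(start1, start2, subs)`` where ``subs``
    maps absolute reference positions to replacement base characters
    (applied to whichever mate covers the position).
    """
    ref = np.asarray(reference, dtype=np.uint8)
    n = len(pair_specs)
    start1 = np.zeros(n, dtype=np.int64)
    start2 = np.zeros(n, dtype=np.int64)
    seq1 = np.zeros((n, read_length), dtype=np.uint8)
    seq2 = np.zeros((n, read_length), dtype=np.uint8)
    for k, (s1, s2, subs) in enumerate(pair_specs):
        start1[k], start2[k] = s1, s2
        seq1[k] = ref[s1 : s1 + read_length]
        seq2[k] = ref[s2 : s2 + read_length]
        for pos, base in (subs or {}).items():
            code = encode_sequence(base)[0]
            if s1 <= pos < s1 + read_length:
                seq1[k, pos - s1] = code
            if s2 <= pos < s2 + read_length:
                seq2[k, pos - s2] = code
    return ReadPairSet(
        ref_name="chrT",
        ref_length=len(ref),
        read_length=read_length,
        start1=start1,
        start2=start2,
        seq1=seq1,
        seq2=seq2,
    )


def vpe(sites, states, mult=1):
    return VPE(sites=tuple(sites), states=tuple(states), multiplicity=mult)


def _consistent_union(vpes):
    """Union state map of a VPE subset, or None on conflict."""
    states = {}
    for v in vpes:
        for s, b in zip(v.sites, v.states):
            if states.get(s, b) != b:
                return None
            states[s] = b
    return states


def minimal_chain_cover(vpes):
    """Brute-force minimum number of conflict-free chains supporting all VPEs.

    Exhaustive search over assignments of VPEs to chains; exponential,
    only usable for <= ~8 VPEs.  Serves as the independent oracle for the
    greedy short-chain construction.
    """
    n = len(vpes)
    if n == 0:
        return 0
    for k in range(1, n + 1):
        for assignment in itertools.product(range(k), repeat=n):
            if len(set(assignment)) != k:
                continue
            ok = True
            for c in range(k):
                group = [v for v, a in zip(vpes, assignment) if a == c]
                if _consistent_union(group) is None:
                    ok = False
                    break
            if ok:
                return k
    return n


def max_spanning_weight_networkx(edges):
    """Total |W| of a maximum spanning forest, via networkx (oracle)."""
    import networkx as nx

    g = nx.Graph()
    for (i, j), w in edges.items():
        g.add_edge(i, j, weight=abs(w))
    forest = nx.maximum_spanning_tree(g)
    return sum(d["weight"] for _, _, d in forest.edges(data=True))
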