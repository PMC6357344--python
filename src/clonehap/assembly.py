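"""Greedy local assembly of VPEs into short chains.

VPEs are partitioned into groups by their starting site index and each
group is reduced to a minimal set of *short chains*: allele-state vectors
that jointly support (are consistent with) every VPE in the group.
Finding the truly minimal set is an integer program; like most fragment
assemblers we use a greedy approximation, processing VPEs longest-first so
that later, shorter extracts tend to be contained in existing chains.

Chains from consecutive groups that overlap and agree on all shared sites
are then merged into longer chains, and at every site the number of
distinct chains retained is capped at ``2I`` — a mixture of ``I``
sub-clones has only ``2I`` haplotypes, so any additional pattern at a site
is an artifact (typically a sequencing-error extract) and is pruned.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from .vpe import VPE


class ShortChain:
    """A locally assembled allele-state vector with its supporting VPEs."""

    __slots__ = ("states", "support", "multiplicity", "group_start")

    def __init__(self, vpe: VPE):
        self.states: dict[int, int] = dict(zip(vpe.sites, vpe.states))
        self.support: list[VPE] = [vpe]
        self.multiplicity: int = vpe.multiplicity
        self.group_start: int = vpe.start

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(sorted(self.states))

    def state_vector(self) -> tuple[int, ...]:
        return tuple(self.states[s] for s in sorted(self.states))

    def is_consistent(self, vpe: VPE) -> bool:
        """No conflict at any shared site."""
        st = self.states
        return all(st.get(s, b) == b for s, b in zip(vpe.sites, vpe.states))

    def contains(self, vpe: VPE) -> bool:
        """All of the VPE's sites present with equal states."""
        st = self.states
        return all(
            s in st and st[s] == b for s, b in zip(vpe.sites, vpe.states)
        )

    def add(self, vpe: VPE) -> None:
        """Fold a consistent VPE in: union the states, extend the support."""
        self.states.update(zip(vpe.sites, vpe.states))
        self.support.append(vpe)
        self.multiplicity += vpe.multiplicity

    def merge(self, other: "ShortChain") -> None:
        self.states.update(other.states)
        self.support.extend(other.support)
        self.multiplicity += other.multiplicity

    def compatible(self, other: "ShortChain") -> bool:
        """Overlap on >= 1 site and agree everywhere shared."""
        a, b = self.states, other.states
        if len(b) < len(a):
            a, b = b, a
        shared = 0
        for s, st in a.items():
            if s in b:
                if b[s] != st:
                    return False
                shared += 1
        return shared > 0

    def __repr__(self):  # pragma: no cover - debugging aid
        sts = "".join("AB"[self.states[s]] for s in sorted(self.states))
        return f"ShortChain({self.sites}, {sts}, mult={self.multiplicity})"


def group_by_start(vpes: Iterable[VPE]) -> list[list[VPE]]:
    """Partition VPEs by starting site index, groups ordered by start."""
    groups: dict[int, list[VPE]] = {}
    for v in vpes:
        groups.setdefault(v.start, []).append(v)
    return [groups[k] for k in sorted(groups)]


def build_short_chains(group: Sequence[VPE]) -> list[ShortChain]:
    """Greedily build a small chain set supporting every VPE of one group.

    VPEs are processed longest-first (ties: higher multiplicity, then
    lexicographic states).  A VPE already contained in a chain only adds
    support; one consistent with a chain extends it; otherwise it seeds a
    new chain.  Every VPE ends up supporting exactly one chain.
    """
    order = sorted(
        group,
        key=lambda v: (-len(v.sites), -v.multiplicity, v.states, v.sites),
    )
    chains: list[ShortChain] = []
    for v in order:
        target = None
        for c in chains:
            if c.contains(v):
                target = c
                break
        if target is None:
            for c in chains:
                if c.is_consistent(v):
                    target = c
                    break
        if target is None:
            chains.append(ShortChain(v))
        else:
            target.add(v)
    return chains


def arrange_groups(
    chain_groups: Sequence[Sequence[ShortChain]],
    n_subclones: int,
    prune: bool = True,
) -> list[ShortChain]:
    """Link chains across start groups and prune excess patterns.

    Groups are processed in start order; a chain merges into the first
    already-arranged chain it overlaps and fully agrees with.  Afterwards,
    any chain ranked below the ``2I`` highest-support chains at one of its
    sites is pruned: a sample of ``I`` sub-clones has only ``2I``
    haplotypes, so deeper-ranked patterns are artifacts.
    """
    active: list[ShortChain] = []
    site_index: dict[int, list[ShortChain]] = {}
    for grp in chain_groups:
        for c in sorted(
            grp, key=lambda c: (-c.multiplicity, c.sites, c.state_vector())
        ):
            candidates: list[ShortChain] = []
            seen: set[int] = set()
            for s in c.states:
                for a in site_index.get(s, ()):
                    if id(a) not in seen:
                        seen.add(id(a))
                        candidates.append(a)
            candidates.sort(key=lambda a: -a.multiplicity)
            target = None
            for a in candidates:
                if a.compatible(c):
                    target = a
                    break
            if target is None:
                active.append(c)
                for s in c.states:
                    site_index.setdefault(s, []).append(c)
            else:
                new_sites = [s for s in c.states if s not in target.states]
                target.merge(c)
                for s in new_sites:
                    site_index.setdefault(s, []).append(target)
    if not prune:
        return active
    cap = 2 * n_subclones
    dead: set[int] = set()
    for s, chains_at in site_index.items():
        if len(chains_at) <= cap:
            continue
        ranked = sorted(
            chains_at,
            key=lambda c: (
                -c.multiplicity,
                -len(c.states),
                c.sites,
                c.state_vector(),
            ),
        )
        for c in ranked[cap:]:
            dead.add(id(c))
    return [c for c in active if id(c) not in dead]
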