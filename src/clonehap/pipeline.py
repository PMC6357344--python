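"""End-to-end orchestration: reads -> VPEs -> clusters -> phased haplotypes.

The stages run in a fixed order: extract VPEs and VAFs from the aligned
read pairs, cluster VAFs into the clonal structure, assemble VPEs into
short chains, build the founding-clone phasing graph and its maximum
spanning forest, strip non-carrier read depth to attach the descendant
sites, and finally derive the 2I clonal haplotypes.  Everything is
deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import assembly, clonal, haplotypes, phasing, stripping, vpe
from .simulate import ReadPairSet, SimConfig, SimulatedSample, simulate_sample


@dataclasses.dataclass
class PipelineParams:
    """Tunable knobs of the phasing pipeline (defaults as documented)."""

    epsilon: float = 0.01
    cov_threshold: float = 2.0
    delta: float = 0.1
    strip_mode: str = stripping.MODE_UNINFORMATIVE
    adaptive: bool = True
    max_clusters: int = 6
    fixed_subclones: int | None = None
    min_separation: float = 0.05
    hom_threshold: float = 0.9
    seed: int = 0

    def strip_config(self) -> stripping.StripConfig:
        return stripping.StripConfig(
            delta=self.delta,
            cov=self.cov_threshold,
            mode=self.strip_mode,
            adaptive=self.adaptive,
        )


@dataclasses.dataclass
class PhaseResult:
    """Everything one pipeline run produces, stage by stage."""

    sites: vpe.SiteSet
    vaf: np.ndarray
    vpes: list[vpe.VPE]
    structure: clonal.ClonalStructure
    chains: list
    forest: phasing.SpanningForest
    haplotype_set: haplotypes.HaplotypeSet


def phase_read_sets(
    read_sets: list[ReadPairSet],
    sites: vpe.SiteSet,
    base_index: int = 0,
    params: PipelineParams | None = None,
    structure: clonal.ClonalStructure | None = None,
) -> PhaseResult:
    """Run the full phasing pipeline on aligned read pairs.

    ``base_index`` selects the library used for VAF estimation (the base
    library).  A precomputed clonal structure (e.g. imported clusters) can
    be supplied to skip the VAF clustering stage.
    """
    params = params or PipelineParams()
    base = read_sets[base_index]
    vaf = vpe.compute_vaf(base, sites)
    sites.vaf = vaf
    vpes = vpe.extract_vpes(read_sets, sites)
    if structure is None:
        structure = clonal.cluster_vafs(
            vaf,
            max_clusters=params.max_clusters,
            fixed_subclones=params.fixed_subclones,
            seed=params.seed,
            min_separation=params.min_separation,
            hom_threshold=params.hom_threshold,
        )
    sites.sub = structure.assignments
    groups = assembly.group_by_start(vpes)
    chain_groups = [assembly.build_short_chains(g) for g in groups]
    chains = assembly.arrange_groups(chain_groups, structure.n_subclones)
    counts = phasing.linkage_table(chains, len(sites))
    g = phasing.build_graph(
        counts,
        structure.founding_sites,
        params.epsilon,
        cov=params.cov_threshold,
    )
    forest = phasing.grow_spanning_forest(g)
    strip_cfg = params.strip_config()

    def _gprime(cov: float, delta: float) -> phasing.PhasingGraph:
        return stripping.build_stripped_graph(
            counts,
            structure.assignments,
            structure.proportions,
            params.epsilon,
            delta=delta,
            cov=cov,
            mode=params.strip_mode,
            homozygous=structure.homozygous,
        )

    forest = stripping.extend_tree(
        forest,
        _gprime(params.cov_threshold, params.delta),
        config=strip_cfg,
        rebuild=_gprime if params.adaptive else None,
        target_vertices=structure.phaseable,
    )
    frags = haplotypes.linearize_tree(forest, sites.positions)
    hset = haplotypes.derive_ancestors(
        frags, structure.assignments, structure.n_subclones, len(sites)
    )
    return PhaseResult(
        sites=sites,
        vaf=vaf,
        vpes=vpes,
        structure=structure,
        chains=chains,
        forest=forest,
        haplotype_set=hset,
    )


@dataclasses.dataclass
class SimulationRun:
    """A simulated sample together with its reconstruction and score."""

    sample: SimulatedSample
    result: PhaseResult
    metrics: haplotypes.Metrics


def run_simulated(
    sim_config: SimConfig,
    params: PipelineParams | None = None,
    base_index: int = 0,
) -> SimulationRun:
    """Simulate a sample, phase it, and score against the planted truth."""
    params = params or PipelineParams(seed=sim_config.seed)
    sample = simulate_sample(sim_config)
    sites = vpe.SiteSet.from_truth(sample.truth)
    result = phase_read_sets(
        sample.read_sets, sites, base_index=base_index, params=params
    )
    metrics = haplotypes.score(result.haplotype_set, sample.truth)
    return SimulationRun(sample=sample, result=result, metrics=metrics)
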