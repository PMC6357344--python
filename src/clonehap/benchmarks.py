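"""Standard study configurations and replicate runners.

These fix the simulation conditions the package is validated under: a
200 kb synthetic reference, germline SNV rate 0.1%, somatic SNV rate 1%,
three sub-clones mixed 3:5:2, a 1000 bp-insert base library at 100x plus
1500/2000 bp libraries at 50x, 250 bp reads, per-base error 0.01.  The
reference is scaled to 200 kb so that a full replicate (simulation plus
phasing) runs in seconds; the mutation and coverage parameters are not
scaled.
"""

from __future__ import annotations

import numpy as np

from .haplotypes import Metrics
from .pipeline import PipelineParams, run_simulated
from .simulate import LibrarySpec, SimConfig

REFERENCE_LENGTH = 200_000
READ_LENGTH = 250
EPSILON = 0.01


def default_config(
    seed: int,
    extra_coverage: float = 50.0,
    base_only: bool = False,
    reference_length: int = REFERENCE_LENGTH,
) -> SimConfig:
    """The default three-clone study configuration.

    ``extra_coverage`` sets the two non-base libraries' fold coverage;
    ``base_only`` drops them entirely.
    """
    libs = [LibrarySpec(1000.0, READ_LENGTH, 100.0)]
    if not base_only:
        libs.append(LibrarySpec(1500.0, READ_LENGTH, extra_coverage))
        libs.append(LibrarySpec(2000.0, READ_LENGTH, extra_coverage))
    return SimConfig(
        reference_length=reference_length,
        germline_rate=0.001,
        somatic_rate=0.01,
        n_subclones=3,
        proportions=(0.3, 0.5, 0.2),
        libraries=tuple(libs),
        epsilon=EPSILON,
        seed=seed,
    )


def run_replicates(seeds, **config_kwargs) -> list[Metrics]:
    """One full simulate-and-phase run per seed, returning the metrics."""
    out = []
    for seed in seeds:
        cfg = default_config(int(seed), **config_kwargs)
        out.append(run_simulated(cfg, PipelineParams(seed=int(seed))).metrics)
    return out


def mean_recognition(metrics) -> float:
    return float(np.mean([m.recognition_rate for m in metrics]))


def mean_accuracy(metrics) -> float:
    return float(np.mean([m.accuracy_rate for m in metrics]))


def coverage_sweep(base_seed: int, coverages=(20.0, 50.0, 80.0, 100.0),
                   n_seeds: int = 3) -> dict[float, float]:
    """Mean recognition rate per extra-library coverage setting."""
    out = {}
    for cov in coverages:
        seeds = [base_seed + 31 * k for k in range(n_seeds)]
        out[cov] = mean_recognition(run_replicates(seeds, extra_coverage=cov))
    return out
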