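"""Synthetic tumor sequencing data under a linear clonal-evolution model.

A bulk tumor sample is modelled as a mixture of ``I`` sub-clones related by
a linear phylogeny ``S_0 -> S_1 -> ... -> S_{I-1}``: the founding clone
``S_0`` carries the mutations shared by every tumor cell, and each
descendant sub-clone adds its own somatic mutations on one haplotype while
inheriting both parental haplotypes unchanged.  Every locus mutates at most
once and never reverts, so a variant that first arises in ``S_i`` is
present, on the same haplotype side, in every ``S_j`` with ``j >= i`` (the
inheritance principle).  A site arising in clone ``s`` therefore has an
expected variant allele frequency of ``0.5 * sum_{i >= s} r_i`` in the
pooled sample, where ``r_i`` are the clone proportions.

The generator plants germline heterozygous SNVs (labelled clone 0, carried
by all clones on one haplotype side) and somatic SNVs (assigned to a clone
uniformly at random), then samples read pairs from the mixture: each pair
picks a clone with probability ``r_i``, one of its two haplotypes
uniformly, an insert length from a normal distribution truncated to at
least twice the read length, and a uniform start position; each emitted
base is flipped to a uniformly chosen different base with probability
``epsilon``.  Reads are emitted pre-aligned at their true coordinates.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

#: mapping from the internal 2-bit base code (0..3) to the ASCII base
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: mapping from ASCII bytes to base codes; 255 marks a non-ACGT byte
BASE_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    BASE_CODES[_b] = _i
for _i, _b in enumerate(b"acgt"):
    BASE_CODES[_b] = _i
del _i, _b


def encode_sequence(seq: str | bytes) -> np.ndarray:
    """Turn an ACGT string into the internal uint8 code array."""
    raw = np.frombuffer(seq.encode() if isinstance(seq, str) else seq, dtype=np.uint8)
    codes = BASE_CODES[raw]
    if np.any(codes == 255):
        bad = chr(raw[codes == 255][0])
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return codes


def decode_sequence(codes: np.ndarray) -> str:
    """Inverse of :func:`encode_sequence`."""
    return BASES[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclasses.dataclass(frozen=True)
class LibrarySpec:
    """One paired-end sequencing library.

    Parameters
    ----------
    insert_size_mean
        Mean outer distance between the two mates, in bases.  Larger
        inserts link more distant variant sites.
    read_length
        Length of each mate, in bases.
    coverage
        Target fold coverage contributed by this library.
    insert_size_sd
        Standard deviation of the insert size; defaults to 5% of the mean.
    """

    insert_size_mean: float
    read_length: int
    coverage: float
    insert_size_sd: float | None = None

    def __post_init__(self):
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if 2 * self.read_length > self.insert_size_mean:
            raise ValueError("insert_size_mean must be >= 2 * read_length")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.insert_size_sd is None:
            object.__setattr__(self, "insert_size_sd", 0.05 * self.insert_size_mean)
        if self.insert_size_sd < 0:
            raise ValueError("insert_size_sd must be non-negative")


#: the default three-library design: a 1000 bp base library at 100x used
#: for allele-frequency estimation, plus 1500/2000 bp libraries at 50x that
#: bridge longer gaps between variant sites.
DEFAULT_LIBRARIES = (
    LibrarySpec(1000.0, 250, 100.0),
    LibrarySpec(1500.0, 250, 50.0),
    LibrarySpec(2000.0, 250, 50.0),
)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated tumor sample.

    Defaults follow the study conditions this package is validated under:
    germline SNV rate 0.1%, somatic SNV rate 1%, three sub-clones mixed at
    3:5:2, per-base error probability 0.01.
    """

    reference_length: int
    germline_rate: float = 0.001
    somatic_rate: float = 0.01
    n_subclones: int = 3
    proportions: tuple[float, ...] = (0.3, 0.5, 0.2)
    libraries: tuple[LibrarySpec, ...] = DEFAULT_LIBRARIES
    epsilon: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.reference_length < 1:
            raise ValueError("reference_length must be >= 1")
        for name in ("germline_rate", "somatic_rate", "epsilon"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_subclones < 1:
            raise ValueError("n_subclones must be >= 1")
        props = tuple(float(p) for p in self.proportions)
        object.__setattr__(self, "proportions", props)
        if len(props) != self.n_subclones:
            raise ValueError("proportions must have one entry per sub-clone")
        if any(p <= 0 for p in props):
            raise ValueError("all proportions must be positive")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        object.__setattr__(self, "libraries", tuple(self.libraries))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["libraries"] = [dataclasses.asdict(l) for l in self.libraries]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        d["libraries"] = tuple(LibrarySpec(**l) for l in d["libraries"])
        d["proportions"] = tuple(d["proportions"])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class TruthSet:
    """Planted variant sites and the true clonal haplotype matrix.

    ``sub[j]`` is the clone in which site ``j`` first arose (0 for germline
    and founding-clone somatic sites) and ``side[j]`` the haplotype (0/1)
    that carries the mutation in that clone and all its descendants.
    """

    positions: np.ndarray  # (n,) sorted reference coordinates, 0-based
    ref_codes: np.ndarray  # (n,) uint8
    alt_codes: np.ndarray  # (n,) uint8
    sub: np.ndarray  # (n,) originating clone label
    side: np.ndarray  # (n,) haplotype side carrying the mutation
    n_subclones: int

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def haplotype_matrix(self) -> np.ndarray:
        """(2I, n) matrix over {0, 1}; 1 marks the non-reference state B.

        Rows ``2i`` and ``2i+1`` are the two haplotypes of clone ``i``.
        """
        n = self.n_sites
        mat = np.zeros((2 * self.n_subclones, n), dtype=np.uint8)
        for i in range(self.n_subclones):
            carried = self.sub <= i
            rows = 2 * i + self.side[carried]
            mat[rows, np.flatnonzero(carried)] = 1
        return mat

    def validate(self) -> None:
        """Assert the evolutionary invariants of the truth matrix."""
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.ref_codes == self.alt_codes):
            raise ValueError("ref and alt must differ at every site")
        if np.any((self.sub < 0) | (self.sub >= self.n_subclones)):
            raise ValueError("sub labels out of range")
        mat = self.haplotype_matrix()
        for i in range(self.n_subclones - 1):
            parent = mat[2 * i] | mat[2 * i + 1]
            child = mat[2 * (i + 1)] | mat[2 * (i + 1) + 1]
            if np.any(parent & ~child):
                raise ValueError("inheritance violated: mutation lost in a descendant")
        # heterozygosity at origination: never both haplotypes mutated
        for i in range(self.n_subclones):
            if np.any(mat[2 * i] & mat[2 * i + 1]):
                raise ValueError("site homozygous-alt within a clone")


def generate_reference(length: int, seed=0) -> np.ndarray:
    """Uniform random DNA as a base-code array; reproducible for a seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _as_rng(seed)
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def plant_mutations(reference: np.ndarray, config: SimConfig, rng=None) -> TruthSet:
    """Plant germline and somatic SNVs on the clonal haplotypes.

    Germline sites are heterozygous in every clone (label 0); somatic sites
    are assigned uniformly to clones ``0..I-1`` and to one haplotype side,
    then propagated to all descendants.  Expected total site count is
    ``length * (germline_rate + somatic_rate)``.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    length = len(reference)
    n_germ = rng.binomial(length, config.germline_rate)
    n_som = rng.binomial(length, config.somatic_rate)
    n = n_germ + n_som
    if n > length:
        raise ValueError("mutation rates too high for reference length")
    positions = np.sort(rng.choice(length, size=n, replace=False))
    is_somatic = np.zeros(n, dtype=bool)
    is_somatic[rng.choice(n, size=n_som, replace=False)] = True
    sub = np.zeros(n, dtype=np.int64)
    sub[is_somatic] = rng.integers(0, config.n_subclones, size=n_som)
    side = rng.integers(0, 2, size=n).astype(np.int64)
    ref_codes = reference[positions]
    alt_codes = (ref_codes + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    truth = TruthSet(
        positions=positions,
        ref_codes=ref_codes,
        alt_codes=alt_codes,
        sub=sub,
        side=side,
        n_subclones=config.n_subclones,
    )
    truth.validate()
    return truth


@dataclasses.dataclass
class ReadPairSet:
    """A library's worth of aligned read pairs, kept as dense arrays.

    ``seq1``/``seq2`` are ``(n_pairs, read_length)`` base-code matrices;
    ``start1``/``start2`` the 0-based mapping coordinates of each mate.
    ``hap`` optionally records the true generating haplotype row.
    """

    ref_name: str
    ref_length: int
    read_length: int
    start1: np.ndarray
    start2: np.ndarray
    seq1: np.ndarray
    seq2: np.ndarray
    hap: np.ndarray | None = None
    name: str = "lib"

    @property
    def n_pairs(self) -> int:
        return len(self.start1)


def haplotype_sequences(reference: np.ndarray, truth: TruthSet) -> np.ndarray:
    """(2I, L) base-code matrix of the full clonal haplotype sequences."""
    mat = truth.haplotype_matrix()
    haps = np.tile(reference, (2 * truth.n_subclones, 1))
    for row in range(2 * truth.n_subclones):
        carried = mat[row] == 1
        haps[row, truth.positions[carried]] = truth.alt_codes[carried]
    return haps


def simulate_reads(
    reference: np.ndarray,
    truth: TruthSet,
    config: SimConfig,
    rng=None,
    ref_name: str = "chrS",
) -> list[ReadPairSet]:
    """Draw read pairs for every library in ``config``.

    The pair count per library is ``coverage * L / (2 * read_length)``.
    Each pair samples a clone with probability ``r_i``, a haplotype side
    uniformly, and an insert from Normal(mean, sd) truncated to at least
    ``2 * read_length`` (and at most the reference length).
    """
    rng = _as_rng(config.seed + 1 if rng is None else rng)
    length = len(reference)
    max_insert = max(l.insert_size_mean for l in config.libraries)
    if length < max_insert:
        raise ValueError("reference shorter than the largest insert size")
    haps = haplotype_sequences(reference, truth)
    r = np.asarray(config.proportions)
    out: list[ReadPairSet] = []
    for li, lib in enumerate(config.libraries):
        rl = lib.read_length
        n_pairs = int(round(lib.coverage * length / (2 * rl)))
        clone = rng.choice(config.n_subclones, size=n_pairs, p=r)
        hap_row = 2 * clone + rng.integers(0, 2, size=n_pairs)
        insert = np.rint(
            rng.normal(lib.insert_size_mean, lib.insert_size_sd, size=n_pairs)
        ).astype(np.int64)
        insert = np.clip(insert, 2 * rl, length)
        start1 = np.floor(rng.random(n_pairs) * (length - insert + 1)).astype(np.int64)
        start2 = start1 + insert - rl
        offs = np.arange(rl)
        seq1 = haps[hap_row[:, None], start1[:, None] + offs]
        seq2 = haps[hap_row[:, None], start2[:, None] + offs]
        if config.epsilon > 0:
            for seq in (seq1, seq2):
                mask = rng.random(seq.shape) < config.epsilon
                idx = np.nonzero(mask)
                shift = rng.integers(1, 4, size=len(idx[0])).astype(np.uint8)
                seq[idx] = (seq[idx] + shift) % 4
        out.append(
            ReadPairSet(
                ref_name=ref_name,
                ref_length=length,
                read_length=rl,
                start1=start1,
                start2=start2,
                seq1=seq1,
                seq2=seq2,
                hap=hap_row,
                name=f"lib{li}",
            )
        )
    return out


@dataclasses.dataclass
class SimulatedSample:
    """Bundle of everything one simulation produces."""

    config: SimConfig
    reference: np.ndarray
    truth: TruthSet
    read_sets: list[ReadPairSet]
    ref_name: str = "chrS"


def simulate_sample(config: SimConfig, ref_name: str = "chrS") -> SimulatedSample:
    """Generate reference, truth and reads from a single root seed."""
    rng = _as_rng(config.seed)
    reference = generate_reference(config.reference_length, rng)
    truth = plant_mutations(reference, config, rng)
    read_sets = simulate_reads(reference, truth, config, rng, ref_name=ref_name)
    return SimulatedSample(config, reference, truth, read_sets, ref_name)
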