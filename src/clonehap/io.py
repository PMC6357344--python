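"""Readers and writers for the pipeline's on-disk formats.

Standard formats go through the standard libraries: SAM via pysam, VCF via
pysam's VariantFile (plain uncompressed VCF is fine), FASTA reading via
pyfaidx, tables via pandas.  Internal coordinates are 0-based half-open;
1-based coordinates appear only at the VCF/SAM boundary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

from .clonal import ClonalStructure
from .haplotypes import Fragment, HaplotypeSet, Metrics
from .simulate import (
    BASE_CODES,
    BASES,
    ReadPairSet,
    SimConfig,
    TruthSet,
    decode_sequence,
)
from .vpe import SiteSet, VPE

logger = logging.getLogger(__name__)


class InputFormatError(ValueError):
    """Raised when an input file cannot be parsed as expected."""


# ---------------------------------------------------------------- FASTA


def write_fasta(path, name: str, codes: np.ndarray, width: int = 70) -> None:
    seq = decode_sequence(codes)
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> tuple[str, np.ndarray]:
    """First record of a FASTA file as (name, base codes)."""
    fa = Fasta(str(path))
    names = list(fa.keys())
    if not names:
        raise InputFormatError(f"no sequences in {path}")
    name = names[0]
    seq = str(fa[name][:]).upper()
    fa.close()
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = BASE_CODES[raw]
    if np.any(codes == 255):
        raise InputFormatError(f"non-ACGT character in {path}")
    return name, codes


# ------------------------------------------------------------------ SAM


def write_sam(path, rps: ReadPairSet) -> None:
    """Write a read-pair set as a plain SAM file at its true coordinates."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": rps.ref_name, "LN": int(rps.ref_length)}],
    }
    rl = rps.read_length
    with pysam.AlignmentFile(str(path), "w", header=dict(header)) as out:
        for k in range(rps.n_pairs):
            for mate, (start, other, seq) in enumerate(
                [
                    (rps.start1[k], rps.start2[k], rps.seq1[k]),
                    (rps.start2[k], rps.start1[k], rps.seq2[k]),
                ]
            ):
                a = pysam.AlignedSegment()
                a.query_name = f"{rps.name}:{k}"
                a.query_sequence = decode_sequence(seq)
                a.flag = 0x1 | 0x2 | (0x40 if mate == 0 else 0x80)
                a.flag |= 0x20 if mate == 0 else 0x10
                a.reference_id = 0
                a.reference_start = int(start)
                a.mapping_quality = 60
                a.cigarstring = f"{rl}M"
                a.next_reference_id = 0
                a.next_reference_start = int(other)
                tlen = int(other) + rl - int(start) if mate == 0 else -(int(start) + rl - int(other))
                a.template_length = tlen
                a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                out.write(a)


def read_sam(path, name: str | None = None) -> ReadPairSet:
    """Load a SAM/BAM file of uniform-length paired reads.

    Mates are joined by query name.  A read whose mate is missing is
    dropped (it is handled as a single read upstream of VPE extraction
    only through the VAF pileup of the base library).
    """
    with pysam.AlignmentFile(str(path), "r") as fh:
        if fh.nreferences != 1:
            raise InputFormatError("expected exactly one reference sequence")
        ref_name = fh.references[0]
        ref_length = fh.lengths[0]
        first: dict[str, pysam.AlignedSegment] = {}
        pairs: list[tuple[pysam.AlignedSegment, pysam.AlignedSegment]] = []
        rl = None
        for a in fh.fetch(until_eof=True):
            if a.is_unmapped or a.query_sequence is None:
                continue
            if rl is None:
                rl = a.query_length
            elif a.query_length != rl:
                raise InputFormatError(
                    "read lengths are not uniform within the file"
                )
            mate = first.pop(a.query_name, None)
            if mate is None:
                first[a.query_name] = a
            else:
                r1, r2 = (mate, a) if mate.is_read1 else (a, mate)
                pairs.append((r1, r2))
    if first:
        logger.warning("read_sam: dropped %d unpaired reads", len(first))
    n = len(pairs)
    rl = rl or 0
    start1 = np.zeros(n, dtype=np.int64)
    start2 = np.zeros(n, dtype=np.int64)
    seq1 = np.zeros((n, rl), dtype=np.uint8)
    seq2 = np.zeros((n, rl), dtype=np.uint8)
    for k, (r1, r2) in enumerate(pairs):
        start1[k] = r1.reference_start
        start2[k] = r2.reference_start
        seq1[k] = BASE_CODES[np.frombuffer(r1.query_sequence.encode(), np.uint8)]
        seq2[k] = BASE_CODES[np.frombuffer(r2.query_sequence.encode(), np.uint8)]
    return ReadPairSet(
        ref_name=ref_name,
        ref_length=ref_length,
        read_length=rl,
        start1=start1,
        start2=start2,
        seq1=seq1,
        seq2=seq2,
        name=name or Path(str(path)).stem,
    )


# ------------------------------------------------------------------ VCF


def write_truth_vcf(path, truth: TruthSet, ref_name: str, ref_length: int) -> None:
    """Truth sites as VCF with clone label and haplotype side in INFO."""
    header = pysam.VariantHeader()
    header.contigs.add(ref_name, length=int(ref_length))
    header.info.add("SUB", 1, "Integer", "Origin sub-clone label (0 = founding)")
    header.info.add("SIDE", 1, "Integer", "Haplotype side carrying the mutation")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in range(truth.n_sites):
            rec = out.new_record(
                contig=ref_name,
                start=int(truth.positions[j]),
                stop=int(truth.positions[j]) + 1,
                alleles=(
                    chr(BASES[truth.ref_codes[j]]),
                    chr(BASES[truth.alt_codes[j]]),
                ),
            )
            rec.info["SUB"] = int(truth.sub[j])
            rec.info["SIDE"] = int(truth.side[j])
            out.write(rec)


def load_sites(path) -> SiteSet:
    """Variant sites from a VCF or a TSV with position/ref/alt columns.

    Only biallelic SNVs are kept; skipped records are counted in the log.
    Duplicate positions or an empty site list are errors.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _load_sites_vcf(path)
    return _load_sites_tsv(path)


def load_truth_vcf(path, n_subclones: int | None = None) -> TruthSet:
    """Read back a truth VCF written by :func:`write_truth_vcf`."""
    pos, ref, alt, sub, side = [], [], [], [], []
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh:
            pos.append(rec.start)
            ref.append(BASE_CODES[ord(rec.ref)])
            alt.append(BASE_CODES[ord(rec.alts[0])])
            sub.append(int(rec.info["SUB"]))
            side.append(int(rec.info["SIDE"]))
    if not pos:
        raise InputFormatError(f"no records in {path}")
    sub = np.asarray(sub, dtype=np.int64)
    return TruthSet(
        positions=np.asarray(pos, dtype=np.int64),
        ref_codes=np.asarray(ref, dtype=np.uint8),
        alt_codes=np.asarray(alt, dtype=np.uint8),
        sub=sub,
        side=np.asarray(side, dtype=np.int64),
        n_subclones=n_subclones or int(sub.max()) + 1,
    )


def _load_sites_vcf(path) -> SiteSet:
    pos, ref, alt = [], [], []
    skipped = 0
    with pysam.VariantFile(path) as fh:
        for rec in fh:
            if (
                rec.alts is None
                or len(rec.alts) != 1
                or len(rec.ref) != 1
                or len(rec.alts[0]) != 1
                or rec.ref.upper() not in "ACGT"
                or rec.alts[0].upper() not in "ACGT"
            ):
                skipped += 1
                continue
            pos.append(rec.start)
            ref.append(BASE_CODES[ord(rec.ref.upper())])
            alt.append(BASE_CODES[ord(rec.alts[0].upper())])
    if skipped:
        logger.info("load_sites: skipped %d non-SNV records", skipped)
    if not pos:
        raise InputFormatError(f"no usable SNV records in {path}")
    try:
        return SiteSet(pos, ref, alt)
    except ValueError as e:
        raise InputFormatError(str(e)) from e


def _load_sites_tsv(path) -> SiteSet:
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    try:
        pos = df[cols["position"]].to_numpy()
        ref = df[cols["ref"]].astype(str)
        alt = df[cols["alt"]].astype(str)
    except KeyError as e:
        raise InputFormatError(f"missing column in {path}: {e}") from e
    keep = (ref.str.len() == 1) & (alt.str.len() == 1)
    keep &= ref.str.upper().isin(list("ACGT")) & alt.str.upper().isin(list("ACGT"))
    skipped = int((~keep).sum())
    if skipped:
        logger.info("load_sites: skipped %d non-SNV records", skipped)
    if not keep.any():
        raise InputFormatError(f"no usable SNV records in {path}")
    ref_codes = [BASE_CODES[ord(b.upper())] for b in ref[keep]]
    alt_codes = [BASE_CODES[ord(b.upper())] for b in alt[keep]]
    try:
        return SiteSet(pos[keep.to_numpy()], ref_codes, alt_codes)
    except ValueError as e:
        raise InputFormatError(str(e)) from e


def write_sites_tsv(path, sites: SiteSet) -> None:
    df = pd.DataFrame(
        {
            "position": sites.positions,
            "ref": [chr(BASES[c]) for c in sites.ref_codes],
            "alt": [chr(BASES[c]) for c in sites.alt_codes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- TSVs


def write_vpes(path, vpes: list[VPE]) -> None:
    rows = [
        {
            "start_index": v.start,
            "site_indices": ",".join(map(str, v.sites)),
            "states": ",".join("AB"[s] for s in v.states),
            "multiplicity": v.multiplicity,
        }
        for v in vpes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vpes(path) -> list[VPE]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        sites = tuple(int(x) for x in str(row["site_indices"]).split(","))
        states = tuple("AB".index(s) for s in str(row["states"]).split(","))
        out.append(VPE(sites=sites, states=states, multiplicity=int(row["multiplicity"])))
    return out


def write_vaf(path, sites: SiteSet, vaf: np.ndarray) -> None:
    pd.DataFrame({"position": sites.positions, "vaf": vaf}).to_csv(
        path, sep="\t", index=False
    )


def read_vaf(path, sites: SiteSet) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    by_pos = dict(zip(df["position"].astype(int), df["vaf"].astype(float)))
    return np.array([by_pos.get(int(p), np.nan) for p in sites.positions])


def write_chains(path, chains) -> None:
    rows = [
        {
            "group_start": c.group_start,
            "site_indices": ",".join(map(str, c.sites)),
            "states": ",".join("AB"[s] for s in c.state_vector()),
            "support": c.multiplicity,
        }
        for c in chains
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_clusters(path, sites: SiteSet, structure: ClonalStructure) -> None:
    pd.DataFrame(
        {
            "position": sites.positions,
            "clone": structure.assignments,
            "vaf": sites.vaf if sites.vaf is not None else np.nan,
        }
    ).to_csv(path, sep="\t", index=False)


def write_structure_json(path, structure: ClonalStructure) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n_subclones": int(structure.n_subclones),
                "cluster_means": [float(m) for m in structure.cluster_means],
                "proportions": [float(r) for r in structure.proportions],
                "n_homozygous_flagged": int(structure.homozygous.sum()),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def write_haplotypes(path, hset: HaplotypeSet) -> None:
    """2I rows x N sites, cells A/B and '.' for unplaced."""
    chars = np.full(hset.matrix.shape, ".", dtype="<U1")
    chars[hset.matrix == 0] = "A"
    chars[hset.matrix == 1] = "B"
    with open(path, "w") as fh:
        fh.write("# rows: haplotypes 2i, 2i+1 per clone i; columns: sites\n")
        for row in chars:
            fh.write("\t".join(row) + "\n")


def read_haplotypes(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            cells = line.rstrip("\n").split("\t")
            rows.append([{"A": 0, "B": 1, ".": -1}[c] for c in cells])
    return np.asarray(rows, dtype=np.int8)


def write_fragments_bed(path, fragments, ref_name: str) -> None:
    """Fragment spans as 0-based half-open BED records."""
    with open(path, "w") as fh:
        for k, f in enumerate(fragments):
            fh.write(
                f"{ref_name}\t{f.start_pos}\t{f.end_pos + 1}\tfragment{k}"
                f"\t{f.n_sites}\n"
            )


def write_metrics(path, metrics: Metrics) -> None:
    with open(path, "w") as fh:
        fh.write(metrics.to_json(indent=2))
        fh.write("\n")


def write_sim_config(path, config: SimConfig) -> None:
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_truth_haplotypes(path, truth: TruthSet) -> None:
    mat = truth.haplotype_matrix()
    chars = np.where(mat == 1, "B", "A")
    with open(path, "w") as fh:
        fh.write("# rows: haplotypes 2i, 2i+1 per clone i; columns: sites\n")
        for row in chars:
            fh.write("\t".join(row) + "\n")


def write_fragments_tsv(path, fragments) -> None:
    """Fragments with explicit site membership (for re-scoring)."""
    rows = [
        {
            "start_pos": f.start_pos,
            "end_pos": f.end_pos,
            "site_indices": ",".join(map(str, f.sites)),
            "states": ",".join("AB"[s] for s in f.states),
        }
        for f in fragments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path) -> list[Fragment]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        sites = np.array([int(x) for x in str(row["site_indices"]).split(",")])
        states = np.array(
            ["AB".index(s) for s in str(row["states"]).split(",")], dtype=np.int8
        )
        out.append(
            Fragment(
                sites=sites,
                states=states,
                start_pos=int(row["start_pos"]),
                end_pos=int(row["end_pos"]),
            )
        )
    return out


def read_clusters(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"position", "clone"} <= set(df.columns):
        raise InputFormatError(f"{path} lacks position/clone columns")
    return df
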