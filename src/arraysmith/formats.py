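"""Canonical in-memory representations and file I/O.

Coordinates are 1-based inclusive throughout (VCF convention); window
arithmetic elsewhere in the package treats intervals as closed. BED input is
converted from 0-based half-open at the boundary.

Multi-allelic records are kept as single records — the tri-allelic probe rule
operates on whole sites. A missing genotype is never conflated with
homozygous-reference; downstream fractions are computed over non-missing
calls only.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: INFO keys used when reading/writing VCF annotations.
DEFAULT_INFO_KEYS = {
    "strand_bias_p": "SBP",
    "tail_bias_p": "TBP",
    "design_score": "SCORE",
}


@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """One sample's call at a site.

    ``allele_indices`` is ``None`` for a missing call; depth is kept even
    when the call has been masked so that coverage statistics stay honest.
    """

    allele_indices: tuple[int, int] | None
    depth: int = 0

    @property
    def is_missing(self) -> bool:
        return self.allele_indices is None

    @property
    def is_het(self) -> bool:
        return self.allele_indices is not None and self.allele_indices[0] != self.allele_indices[1]


@dataclass(slots=True)
class VariantRecord:
    """A candidate site with per-sample genotype calls."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    site_quality: float
    combined_depth: int
    per_sample: dict[str, GenotypeCall]
    annotations: dict[str, float] = field(default_factory=dict)
    snp_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref_allele:
            raise ValueError("ref allele must be non-empty")
        if not self.alt_alleles or self.ref_allele in self.alt_alleles:
            raise ValueError("alt alleles must be non-empty and distinct from ref")
        if not self.snp_id:
            self.snp_id = f"{self.chrom}_{self.pos}"

    def alleles(self) -> tuple[str, ...]:
        return (self.ref_allele, *self.alt_alleles)

    def genotype_nucleotides(self, sample: str) -> tuple[str, str] | None:
        call = self.per_sample[sample]
        if call.is_missing:
            return None
        alleles = self.alleles()
        i, j = call.allele_indices
        return alleles[i], alleles[j]


@dataclass(frozen=True)
class PanelConfig:
    """Discovery panel roles.

    ``diploid_members`` are the accessions whose heterozygosity drives
    selection; ``dh_members`` are fully homozygous double haploids used as
    paralogy detectors; ``reduced_weight_members`` (a subset of the
    diploids, e.g. a crab-apple outgroup) are filled last during selection.
    """

    diploid_members: tuple[str, ...]
    dh_members: tuple[str, ...]
    reduced_weight_members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.diploid_members) & set(self.dh_members):
            raise ValueError("diploid and DH members must be disjoint")
        if not set(self.reduced_weight_members) <= set(self.diploid_members):
            raise ValueError("reduced-weight members must be diploid members")

    @property
    def all_samples(self) -> tuple[str, ...]:
        return self.diploid_members + self.dh_members

    @property
    def n_diploid(self) -> int:
        return len(self.diploid_members)

    @classmethod
    def from_yaml(cls, path: str) -> "PanelConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            diploid_members=tuple(raw["diploid_members"]),
            dh_members=tuple(raw["dh_members"]),
            reduced_weight_members=tuple(raw.get("reduced_weight_members", ())),
        )


@dataclass(frozen=True, slots=True)
class GeneticMapPoint:
    marker_id: str
    chrom: str
    genetic_pos: float  # cM
    physical_pos: int  # bp


@dataclass
class Genome:
    """Uppercased chromosome sequences with soft-mask annotation retained."""

    sequences: dict[str, str]
    soft_masked: dict[str, np.ndarray]  # bool per base, True = was lowercase

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


# ---------------------------------------------------------------------------
# Readers


def read_variants(
    path: str,
    panel: PanelConfig,
    info_keys: dict[str, str] | None = None,
) -> list[VariantRecord]:
    """Read a VCF into :class:`VariantRecord` objects, sorted by (chrom, pos).

    Multi-allelic sites are preserved un-split; missing genotypes stay
    missing. Every panel sample must be present in the VCF header.
    """
    keys = dict(DEFAULT_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    records: list[VariantRecord] = []
    with pysam.VariantFile(path) as vf:
        header_samples = set(vf.header.samples)
        for sample in panel.all_samples:
            if sample not in header_samples:
                raise ValueError(f"panel sample {sample!r} absent from VCF header")
        for rec in vf:
            per_sample: dict[str, GenotypeCall] = {}
            depth_sum = 0
            for sample in panel.all_samples:
                sd = rec.samples[sample]
                gt = sd.get("GT")
                if gt is None or any(a is None for a in gt):
                    indices = None
                else:
                    indices = (int(gt[0]), int(gt[1]))
                depth = int(sd.get("DP") or 0)
                depth_sum += depth
                per_sample[sample] = GenotypeCall(allele_indices=indices, depth=depth)
            annotations: dict[str, float] = {}
            for name, key in keys.items():
                if key in rec.info:
                    annotations[name] = float(rec.info[key])
            combined = int(rec.info["DP"]) if "DP" in rec.info else depth_sum
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_alleles=tuple(rec.alts or ()),
                    site_quality=float(rec.qual if rec.qual is not None else 0.0),
                    combined_depth=combined,
                    per_sample=per_sample,
                    annotations=annotations,
                    snp_id=rec.id or f"{rec.chrom}_{rec.pos}",
                )
            )
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


def write_variants(
    records: list[VariantRecord],
    panel: PanelConfig,
    path: str,
    contigs: dict[str, int] | None = None,
    info_keys: dict[str, str] | None = None,
) -> None:
    """Write records as an uncompressed VCF 4.2 file (GT:DP per sample)."""
    keys = dict(DEFAULT_INFO_KEYS)
    if info_keys:
        keys.update(info_keys)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for chrom, length in contigs.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in sorted({r.chrom for r in records}):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined depth">\n')
        fh.write(f'##INFO=<ID={keys["strand_bias_p"]},Number=1,Type=Float,Description="Strand bias p-value">\n')
        fh.write(f'##INFO=<ID={keys["tail_bias_p"]},Number=1,Type=Float,Description="Tail distance bias p-value">\n')
        fh.write(f'##INFO=<ID={keys["design_score"]},Number=1,Type=Float,Description="Probe design score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.all_samples) + "\n")
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            info_parts = [f"DP={rec.combined_depth}"]
            for name, key in keys.items():
                if name in rec.annotations:
                    info_parts.append(f"{key}={rec.annotations[name]:g}")
            fields = [
                rec.chrom,
                str(rec.pos),
                rec.snp_id,
                rec.ref_allele,
                ",".join(rec.alt_alleles),
                f"{rec.site_quality:g}",
                ".",
                ";".join(info_parts),
                "GT:DP",
            ]
            for sample in panel.all_samples:
                call = rec.per_sample[sample]
                gt = "./." if call.is_missing else f"{call.allele_indices[0]}/{call.allele_indices[1]}"
                fields.append(f"{gt}:{call.depth}")
            fh.write("\t".join(fields) + "\n")


def read_genome(path: str) -> Genome:
    """Read a FASTA into uppercase sequences; chrom id is the first header token.

    Lowercase (soft-masked) stretches are retained as a boolean annotation.
    Ambiguity codes are preserved in the sequence.
    """
    sequences: dict[str, str] = {}
    masked: dict[str, np.ndarray] = {}
    for seq_rec in SeqIO.parse(path, "fasta"):
        chrom = seq_rec.id
        if chrom in sequences:
            raise ValueError(f"duplicate FASTA header {chrom!r}")
        raw = str(seq_rec.seq)
        arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
        masked[chrom] = (arr >= ord("a")) & (arr <= ord("z"))
        sequences[chrom] = raw.upper()
    return Genome(sequences=sequences, soft_masked=masked)


def write_genome(genome: Genome | dict[str, str], path: str, width: int = 80) -> None:
    sequences = genome.sequences if isinstance(genome, Genome) else genome
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genetic_map(path: str) -> list[GeneticMapPoint]:
    """Read a TSV genetic map (columns marker, chrom, cM, bp).

    Rows are sorted by cM within each chromosome; rows that break physical
    monotonicity along increasing cM are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker", "chrom", "cM", "bp"}
    if not required <= set(df.columns):
        raise ValueError(f"genetic map must have columns {sorted(required)}, got {list(df.columns)}")
    points: list[GeneticMapPoint] = []
    for idx, row in df.iterrows():
        try:
            cm = float(row["cM"])
            bp = int(float(row["bp"]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"unparsable cM/bp in genetic map row {idx + 2}") from exc
        points.append(GeneticMapPoint(str(row["marker"]), str(row["chrom"]), cm, bp))
    out: list[GeneticMapPoint] = []
    for chrom in sorted({p.chrom for p in points}):
        rows = sorted((p for p in points if p.chrom == chrom), key=lambda p: (p.genetic_pos, p.physical_pos))
        last_bp = -1
        for p in rows:
            if p.physical_pos <= last_bp:
                logger.warning(
                    "dropping map marker %s (%s: %.3f cM, %d bp): physical position not increasing",
                    p.marker_id, p.chrom, p.genetic_pos, p.physical_pos,
                )
                continue
            out.append(p)
            last_bp = p.physical_pos
    return out


def read_mask(path: str) -> dict[str, IntervalTree]:
    """Read a BED mask (0-based half-open) into per-chromosome interval trees.

    Queries elsewhere use 1-based positions; the half-open BED interval
    [start, end) covers 1-based positions start+1 .. end, which maps
    directly onto an IntervalTree query at ``pos - 1``.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                continue
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def position_masked(mask: dict[str, IntervalTree] | None, chrom: str, pos: int) -> bool:
    if not mask or chrom not in mask:
        return False
    return bool(mask[chrom].overlap(pos - 1, pos))


def read_scores(path: str) -> dict[str, float]:
    """Read a TSV of per-SNP design scores (columns snp_id, score)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str})
    if "snp_id" not in df.columns or "score" not in df.columns:
        raise ValueError("score table must have columns snp_id, score")
    return dict(zip(df["snp_id"], df["score"].astype(float)))


def read_legacy(path: str) -> pd.DataFrame:
    """Read a legacy/anchor marker list (TSV: snp_id, chrom, pos [, ref, alt])."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"legacy marker table missing column {col!r}")
    df["pos"] = df["pos"].astype(int)
    return df


def read_array_report(path: str) -> pd.DataFrame:
    """Read a forward-strand array genotype report (CSV: snp_id, sample, allele1, allele2)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("snp_id", "sample", "allele1", "allele2"):
        if col not in df.columns:
            raise ValueError(f"array report missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# Manifest

MANIFEST_COLUMNS = [
    "snp_id", "chrom", "pos", "ref", "alt",
    "focal_point_id", "tier", "source", "het_count", "design_score",
]


def write_manifest(manifest: pd.DataFrame, path: str) -> None:
    """Write the array manifest CSV; byte-deterministic for a given frame."""
    out = manifest.copy()
    for col in MANIFEST_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out = out[MANIFEST_COLUMNS]

    def _fmt_score(v: object) -> str:
        if v is None or v == "" or (isinstance(v, float) and np.isnan(v)):
            return ""
        return f"{float(v):.4g}"

    out["design_score"] = out["design_score"].map(_fmt_score)
    out["het_count"] = out["het_count"].map(lambda v: "" if v == "" or pd.isna(v) else str(int(v)))
    out["pos"] = out["pos"].astype(int)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for row in out.itertuples(index=False):
            writer.writerow(list(row))


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != MANIFEST_COLUMNS:
        raise ValueError("not a manifest file")
    df["pos"] = df["pos"].astype(int)
    df["het_count"] = df["het_count"].map(lambda v: None if v == "" else int(v))
    df["design_score"] = df["design_score"].map(lambda v: None if v == "" else float(v))
    return df


def mask_low_depth_call(call: GenotypeCall) -> GenotypeCall:
    return replace(call, allele_indices=None)
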