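"""Synthetic discovery panels with planted, labeled artifact classes.

The generator emulates the data structure of a re-sequenced SNP discovery
panel — 14 diploid members (one a reduced-weight crab-apple-like outgroup)
plus two double haploids — over a small multi-chromosome genome, so that
every filter and the selection algorithm are testable without any download.

Each planted variant violates exactly one filter (or none, for the clean
class), which makes per-filter recall and false-removal rates exactly
assertable. Real data overlaps failure classes; orthogonal construction is
what keeps the test surface sharp. Clean variants draw heterozygosity
profiles spanning all selection tiers; per-sample depths follow a clipped
normal around the target mean coverage (defaults emulate 30–45x short-read
panels). The array genotype report is derived from the true genotypes with
genotype flips at a configurable discordance rate; probe-site mechanisms of
real discordance are reported by the pipeline, not simulated here.

Everything is a deterministic function of ``SimulationSpec.seed``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import (
    GeneticMapPoint,
    Genome,
    GenotypeCall,
    PanelConfig,
    VariantRecord,
    write_genome,
    write_variants,
)

CLASS_LABELS = (
    "clean", "dh_het_paralog", "low_qual", "high_depth", "low_support",
    "af_one", "indel", "at_cg", "triallelic", "near_snp", "repeat_flank",
    "low_score",
)

#: which pipeline removal reason each planted class must trigger (clean: none)
CLASS_REASON = {
    "dh_het_paralog": "dh_het",
    "low_qual": "low_qual",
    "high_depth": "high_depth",
    "low_support": "low_support",
    "af_one": "af_one",
    "indel": "indel",
    "at_cg": "at_cg",
    "triallelic": "triallelic",
    "near_snp": "near_snp",
    "repeat_flank": "flank_repeat",
    "low_score": "low_score",
}

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSION_SAME_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}
_TRIALLELIC_ALTS = {"A": ("G", "C"), "G": ("A", "T"), "C": ("T", "A"), "T": ("C", "G")}


def _default_class_counts() -> dict[str, int]:
    counts = {label: 50 for label in CLASS_LABELS}
    counts["clean"] = 1450
    return counts


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic panel.

    Defaults: 4 chromosomes of 500 kb, ~2,000 variants (1,450 clean + 50
    per artifact class), 14 diploids + 2 DHs, ~35x mean depth, genetic-map
    markers every 0.5 cM at 440 kb/cM, 5% array discordance.
    """

    seed: int = 1
    n_chrom: int = 4
    chrom_length: int = 500_000
    n_diploid: int = 14
    n_dh: int = 2
    class_counts: dict[str, int] = field(default_factory=_default_class_counts)
    mean_depth: float = 35.0
    depth_sd: float = 8.0
    map_cm_spacing: float = 0.5
    map_offset_bp: int = 10_000
    kb_per_cm: int = 440_000
    discordance_rate: float = 0.05
    dense_fp_extra: int = 14  # extra clean SNPs packed into the first FP window per chromosome

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be non-negative")
        unknown = set(self.class_counts) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown variant classes: {sorted(unknown)}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1:02d}" for i in range(self.n_chrom)]


def default_panel(spec: SimulationSpec | None = None) -> PanelConfig:
    spec = spec or SimulationSpec()
    diploids = tuple(f"cv{i + 1:02d}" for i in range(spec.n_diploid - 1)) + ("outgroup",)
    dhs = tuple(f"dh{i + 1}" for i in range(spec.n_dh))
    return PanelConfig(diploid_members=diploids, dh_members=dhs,
                       reduced_weight_members=("outgroup",))


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated panel."""

    labels: dict[str, str]  # snp_id -> class label
    intended_tier: dict[str, int]  # snp_id -> planted heterozygote count (clean only)
    fp_layout: dict[str, list[int]]  # chrom -> anchored FP centers implied by the map
    duplications: list[dict]  # planted 24-mer copies

    def ids_of(self, label: str) -> set[str]:
        return {sid for sid, lab in self.labels.items() if lab == label}


@dataclass
class _Plan:
    positions: list[tuple[str, int, str]]  # (chrom, pos, label) sorted
    duplications: list[dict]
    fp_layout: dict[str, list[int]]
    map_rows: list[GeneticMapPoint]


def _map_cms(spec: SimulationSpec) -> list[float]:
    cms = []
    c = 0.0
    while spec.map_offset_bp + c * spec.kb_per_cm <= spec.chrom_length - spec.map_offset_bp:
        cms.append(round(c, 6))
        c += spec.map_cm_spacing
    return cms


def _plan(spec: SimulationSpec) -> _Plan:
    """Deterministic placement of variant positions, classes, map and repeats.

    Positions keep >= 60 bp of clearance from each other (near-SNP pairs
    excepted, by design) and >= 100 bp from chromosome ends; a reserved
    region at the end of the first chromosome receives the planted 24-mer
    duplications and carries no variants.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.chrom_length
    chroms = spec.chrom_names
    dump_chrom = chroms[0]
    n_repeat = spec.class_counts.get("repeat_flank", 0)
    dump_lo = L - 60 * (n_repeat + 2) - 100
    taken: dict[str, list[int]] = {c: [] for c in chroms}

    def clear(chrom: str, pos: int, margin: int = 60) -> bool:
        if pos < 100 or pos > L - 100:
            return False
        if chrom == dump_chrom and pos > dump_lo - 100:
            return False
        return all(abs(pos - q) >= margin for q in taken[chrom])

    placements: list[tuple[str, int, str]] = []

    def place(label: str, chrom: str | None = None, margin: int = 60) -> tuple[str, int]:
        for _ in range(10_000):
            c = chrom if chrom is not None else chroms[int(rng.integers(len(chroms)))]
            pos = int(rng.integers(100, L - 100))
            if clear(c, pos, margin):
                taken[c].append(pos)
                placements.append((c, pos, label))
                return c, pos
        raise RuntimeError(f"could not place a {label} variant; lower the class counts")

    # genetic map and implied anchored FP centers
    cms = _map_cms(spec)
    map_rows: list[GeneticMapPoint] = []
    fp_layout: dict[str, list[int]] = {}
    for chrom in chroms:
        for i, cm in enumerate(cms):
            bp = spec.map_offset_bp + int(cm * spec.kb_per_cm)
            map_rows.append(GeneticMapPoint(f"M_{chrom}_{i}", chrom, cm, bp))
        max_cm = int(np.floor(cms[-1])) if cms else 0
        fp_layout[chrom] = [spec.map_offset_bp + i * spec.kb_per_cm for i in range(max_cm + 1)]

    # dense clean SNPs inside the first anchored FP window of each chromosome
    n_clean = spec.class_counts.get("clean", 0)
    n_dense_total = 0
    for chrom in chroms:
        if not fp_layout[chrom] or n_dense_total + spec.dense_fp_extra > n_clean:
            break
        center = fp_layout[chrom][0]
        start = max(100, center - 4000)
        for j in range(spec.dense_fp_extra):
            pos = start + j * 550
            if pos <= center + 4500 and clear(chrom, pos):
                taken[chrom].append(pos)
                placements.append((chrom, pos, "clean"))
                n_dense_total += 1

    for _ in range(n_clean - n_dense_total):
        place("clean")

    for label in ("dh_het_paralog", "low_qual", "high_depth", "low_support",
                  "af_one", "indel", "at_cg", "triallelic", "low_score"):
        for _ in range(spec.class_counts.get(label, 0)):
            place(label)

    # near-SNP pairs: two otherwise-clean survivors 10-40 bp apart
    n_near = spec.class_counts.get("near_snp", 0)
    for _ in range(n_near // 2):
        chrom, pos = place("near_snp", margin=150)
        delta = int(rng.integers(10, 41))
        taken[chrom].append(pos + delta)
        placements.append((chrom, pos + delta, "near_snp"))
    if n_near % 2:
        # odd count: pair the last one anyway, label only one (kept even in defaults)
        chrom, pos = place("near_snp", margin=150)
        taken[chrom].append(pos + 20)
        placements.append((chrom, pos + 20, "near_snp"))

    # repeat-flank variants: upstream 24-mer duplicated into the dump region
    duplications: list[dict] = []
    for j in range(n_repeat):
        chrom, pos = place("repeat_flank")
        dest = dump_lo + 60 * j
        duplications.append({
            "src_chrom": chrom, "src_start": pos - 25, "k": 24,
            "dest_chrom": dump_chrom, "dest_start": dest,
        })

    placements.sort(key=lambda t: (t[0], t[1]))
    return _Plan(placements, duplications, fp_layout, map_rows)


def generate_genome(spec: SimulationSpec) -> tuple[Genome, SyntheticTruth]:
    """Random i.i.d. nucleotide genome with planted 24-mer duplications.

    Returns the genome plus a truth skeleton (labels, FP layout, planted
    duplications); genotype-level truth is added by
    :func:`generate_panel_variants`.
    """
    plan = _plan(spec)
    rng = np.random.default_rng(spec.seed + 10_000)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs: dict[str, np.ndarray] = {
        chrom: bases[rng.integers(0, 4, size=spec.chrom_length)]
        for chrom in spec.chrom_names
    }
    for dup in plan.duplications:
        src = seqs[dup["src_chrom"]][dup["src_start"] : dup["src_start"] + dup["k"]]
        seqs[dup["dest_chrom"]][dup["dest_start"] : dup["dest_start"] + dup["k"]] = src
    sequences = {c: s.tobytes().decode("ascii") for c, s in seqs.items()}
    genome = Genome(
        sequences=sequences,
        soft_masked={c: np.zeros(len(s), dtype=bool) for c, s in sequences.items()},
    )
    labels = {f"{c}_{p}": lab for c, p, lab in plan.positions}
    truth = SyntheticTruth(labels=labels, intended_tier={},
                           fp_layout=plan.fp_layout, duplications=plan.duplications)
    return genome, truth


def _depths(rng: np.random.Generator, n: int, mean: float, sd: float,
            floor: int = 11) -> np.ndarray:
    return np.maximum(np.round(rng.normal(mean, sd, size=n)).astype(int), floor)


def _draw_het_count(rng: np.random.Generator) -> int:
    # spans all tiers: single-member, 2-4, 5-8, and a 9-member filler slice
    counts = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9])
    weights = np.array([0.15, 0.10, 0.10, 0.10, 0.12, 0.12, 0.11, 0.10, 0.10])
    return int(rng.choice(counts, p=weights / weights.sum()))


@dataclass
class SyntheticDataset:
    spec: SimulationSpec
    panel: PanelConfig
    genome: Genome
    records: list[VariantRecord]
    truth: SyntheticTruth
    map_points: list[GeneticMapPoint]
    scores: dict[str, float]
    array_report: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.genome.lengths


def generate_panel_variants(
    genome: Genome,
    spec: SimulationSpec,
    truth: SyntheticTruth | None = None,
) -> SyntheticDataset:
    """Generate genotypes, depths, annotations, map, scores and array report.

    Each artifact class is constructed to violate exactly its own filter;
    clean variants pass everything. Call with the genome (and optionally the
    truth skeleton) from :func:`generate_genome` built from the same spec.
    """
    plan = _plan(spec)
    if truth is None:
        truth = SyntheticTruth(
            labels={f"{c}_{p}": lab for c, p, lab in plan.positions},
            intended_tier={}, fp_layout=plan.fp_layout, duplications=plan.duplications,
        )
    panel = default_panel(spec)
    rng = np.random.default_rng(spec.seed + 20_000)
    P = panel.n_diploid
    n_samples = P + len(panel.dh_members)
    records: list[VariantRecord] = []
    scores: dict[str, float] = {}

    for chrom, pos, label in plan.positions:
        snp_id = f"{chrom}_{pos}"
        seq = genome.sequences[chrom]
        ref = seq[pos - 1]
        alt: tuple[str, ...] = (_TRANSITION[ref],)
        qual = float(rng.uniform(40, 220))
        depths = _depths(rng, n_samples, spec.mean_depth, spec.depth_sd)
        score = float(rng.uniform(0.72, 0.99))
        annotations = {
            "strand_bias_p": float(rng.uniform(0.05, 1.0)),
            "tail_bias_p": float(rng.uniform(0.10, 1.0)),
        }

        # diploid genotypes: draw a heterozygote set, others mostly hom-ref
        het_count = _draw_het_count(rng)
        het_members = set(rng.choice(P, size=het_count, replace=False).tolist())
        genotypes: list[tuple[int, int]] = []
        for m in range(P):
            if m in het_members:
                genotypes.append((0, 1))
            elif rng.random() < 0.15:
                genotypes.append((1, 1))
            else:
                genotypes.append((0, 0))
        dh_genotypes = [(0, 0) if rng.random() < 0.7 else (1, 1)
                        for _ in panel.dh_members]

        if label == "dh_het_paralog":
            dh_genotypes[0] = (0, 1)
            if rng.random() < 0.3 and len(dh_genotypes) > 1:
                dh_genotypes[1] = (0, 1)
        elif label == "low_qual":
            qual = float(rng.uniform(4, 19.5))
        elif label == "high_depth":
            depths = _depths(rng, n_samples, 160.0, 20.0)
        elif label == "low_support":
            n_low = P // 2 + 1  # strictly more than half the diploids
            low = rng.choice(P, size=n_low, replace=False)
            depths = depths.copy()
            depths[low] = rng.integers(3, 10, size=n_low)
            good = [m for m in range(P) if m not in set(low.tolist())]
            for m in range(P):
                genotypes[m] = (0, 0)
            genotypes[good[0]] = (0, 1)  # keeps AF < 1 among supported calls
        elif label == "af_one":
            genotypes = [(1, 1)] * P
            dh_genotypes = [(1, 1)] * len(panel.dh_members)
        elif label == "indel":
            ref = seq[pos - 1 : pos + 1]
            alt = (ref[0],)
        elif label == "at_cg":
            alt = (_TRANSVERSION_SAME_PAIR[ref],)
        elif label == "triallelic":
            alt = _TRIALLELIC_ALTS[ref]
            extra = sorted(set(range(P)) - het_members)
            if extra:
                genotypes[extra[0]] = (1, 2)
        elif label == "low_score":
            score = float(rng.uniform(0.30, 0.69))

        if label == "clean":
            truth.intended_tier[snp_id] = het_count

        per_sample: dict[str, GenotypeCall] = {}
        for i, s in enumerate(panel.diploid_members):
            per_sample[s] = GenotypeCall(genotypes[i], int(depths[i]))
        for i, s in enumerate(panel.dh_members):
            per_sample[s] = GenotypeCall(dh_genotypes[i], int(depths[P + i]))

        scores[snp_id] = score
        records.append(
            VariantRecord(
                chrom=chrom, pos=pos, ref_allele=ref, alt_alleles=alt,
                site_quality=qual, combined_depth=int(depths.sum()),
                per_sample=per_sample, annotations=annotations, snp_id=snp_id,
            )
        )

    report = _make_array_report(records, truth, panel, spec, rng)
    return SyntheticDataset(
        spec=spec, panel=panel, genome=genome, records=records, truth=truth,
        map_points=plan.map_rows, scores=scores, array_report=report,
    )


def _make_array_report(
    records: list[VariantRecord],
    truth: SyntheticTruth,
    panel: PanelConfig,
    spec: SimulationSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Forward-strand genotype report for the clean SNPs, with genotype
    flips planted uniformly at the spec's discordance rate."""
    rows = []
    clean = truth.ids_of("clean")
    for rec in records:
        if rec.snp_id not in clean:
            continue
        ref, alt = rec.ref_allele, rec.alt_alleles[0]
        options = [(ref, ref), (ref, alt), (alt, alt)]
        for sample in panel.diploid_members:
            pair = rec.genotype_nucleotides(sample)
            if pair is None:
                continue
            a1, a2 = sorted(pair)
            if rng.random() < spec.discordance_rate:
                others = [o for o in options if tuple(sorted(o)) != (a1, a2)]
                a1, a2 = others[int(rng.integers(len(others)))]
            rows.append({"snp_id": rec.snp_id, "sample": sample, "allele1": a1, "allele2": a2})
    return pd.DataFrame(rows, columns=["snp_id", "sample", "allele1", "allele2"])


def simulate(spec: SimulationSpec | None = None) -> SyntheticDataset:
    """Generate a complete synthetic dataset from one spec (one seed)."""
    spec = spec or SimulationSpec()
    genome, truth = generate_genome(spec)
    return generate_panel_variants(genome, spec, truth)


def write_dataset(ds: SyntheticDataset, outdir: str) -> dict[str, str]:
    """Write the dataset as plain-text files (FASTA, VCF, TSVs, CSV, JSON)."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fasta"),
        "vcf": os.path.join(outdir, "variants.vcf"),
        "map": os.path.join(outdir, "genetic_map.tsv"),
        "scores": os.path.join(outdir, "design_scores.tsv"),
        "array_report": os.path.join(outdir, "array_report.csv"),
        "truth": os.path.join(outdir, "truth.json"),
        "panel": os.path.join(outdir, "panel.yaml"),
    }
    write_genome(ds.genome, paths["genome"])
    write_variants(ds.records, ds.panel, paths["vcf"], contigs=ds.chrom_lengths)
    pd.DataFrame(
        [{"marker": p.marker_id, "chrom": p.chrom, "cM": p.genetic_pos, "bp": p.physical_pos}
         for p in ds.map_points]
    ).to_csv(paths["map"], sep="\t", index=False)
    pd.DataFrame(
        sorted(ds.scores.items()), columns=["snp_id", "score"]
    ).to_csv(paths["scores"], sep="\t", index=False)
    ds.array_report.to_csv(paths["array_report"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {"labels": ds.truth.labels, "intended_tier": ds.truth.intended_tier,
             "fp_layout": ds.truth.fp_layout, "duplications": ds.truth.duplications},
            fh, indent=1,
        )
    import yaml

    with open(paths["panel"], "w") as fh:
        yaml.safe_dump(
            {"diploid_members": list(ds.panel.diploid_members),
             "dh_members": list(ds.panel.dh_members),
             "reduced_weight_members": list(ds.panel.reduced_weight_members)},
            fh,
        )
    return paths
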