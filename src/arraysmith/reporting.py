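"""Funnel accounting, manifest summary statistics, and array-vs-sequencing
genotype concordance.

The funnel is the staged count of variants surviving each filter, from raw
detection to the final manifest. Conservation (survivors = input − removals,
and stage chaining) is enforced, not merely reported: a violation is a
pipeline bug and raises.

Printed-value conventions: survival percentages are rounded half-even to one
decimal; headline means (SNPs per focal point, SNP density per kb) are also
emitted truncated to one decimal, the convention under which the published
style of summary figure is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .formats import PanelConfig, VariantRecord


@dataclass(frozen=True)
class FunnelStage:
    name: str
    input_count: int
    removals: dict[str, int] = field(default_factory=dict)
    survivor_count: int = 0

    def validate(self) -> None:
        removed = sum(self.removals.values())
        if self.input_count - removed != self.survivor_count:
            raise ValueError(
                f"funnel stage {self.name!r} violates conservation: "
                f"{self.input_count} - {removed} != {self.survivor_count}"
            )


@dataclass(frozen=True)
class FunnelReport:
    stages: tuple[FunnelStage, ...]

    def survival_pct(self, stage: FunnelStage) -> float:
        if stage.input_count == 0:
            return 0.0
        # round half-even to one decimal, the printed convention
        return float(round(100.0 * stage.survivor_count / stage.input_count, 1))

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "input": s.input_count,
                    "removals": dict(sorted(s.removals.items())),
                    "survivors": s.survivor_count,
                    "survival_pct": self.survival_pct(s),
                }
                for s in self.stages
            ]
        }

    def to_text(self) -> str:
        lines = []
        for s in self.stages:
            lines.append(f"{s.name}: {s.input_count:,} -> {s.survivor_count:,} ({self.survival_pct(s)}%)")
            for reason, n in sorted(s.removals.items()):
                lines.append(f"    - {reason}: {n:,}")
        return "\n".join(lines)


def funnel_report(stages: list[FunnelStage]) -> FunnelReport:
    """Validate per-stage and cross-stage conservation and build the report."""
    for stage in stages:
        stage.validate()
    for prev, nxt in zip(stages, stages[1:]):
        if prev.survivor_count != nxt.input_count:
            raise ValueError(
                f"funnel stages {prev.name!r} -> {nxt.name!r} do not chain: "
                f"{prev.survivor_count} != {nxt.input_count}"
            )
    return FunnelReport(stages=tuple(stages))


def truncate1(x: float) -> float:
    """Truncate (not round) to one decimal place."""
    return math.floor(x * 10.0) / 10.0


def summary_stats(
    manifest: pd.DataFrame,
    genome_size_bp: int,
    n_variants_for_density: int | None = None,
) -> dict:
    """Manifest summary: SNPs per FP (min/mean/max), counts by source, density.

    ``n_variants_for_density`` lets the caller report density over the full
    high-quality variant set rather than the manifest; defaults to the
    manifest size. Means are reported at full precision and truncated to one
    decimal.
    """
    in_fp = manifest[manifest["focal_point_id"].astype(str) != ""]
    per_fp = in_fp.groupby("focal_point_id").size() if len(in_fp) else pd.Series(dtype=int)
    n_fp = int(per_fp.shape[0])
    mean_fp = float(per_fp.mean()) if n_fp else 0.0
    n_density = n_variants_for_density if n_variants_for_density is not None else len(manifest)
    density = n_density / (genome_size_bp / 1000.0) if genome_size_bp else 0.0
    return {
        "n_snps": int(len(manifest)),
        "n_in_fp": int(len(in_fp)),
        "n_focal_points": n_fp,
        "snps_per_fp_min": int(per_fp.min()) if n_fp else 0,
        "snps_per_fp_max": int(per_fp.max()) if n_fp else 0,
        "snps_per_fp_mean": mean_fp,
        "snps_per_fp_mean_truncated": truncate1(mean_fp),
        "counts_by_source": manifest["source"].value_counts().to_dict() if len(manifest) else {},
        "snp_density_per_kb": density,
        "snp_density_per_kb_truncated": truncate1(density),
        "empty": len(manifest) == 0,
    }


@dataclass(frozen=True)
class SampleConcordance:
    comparisons: int
    matches: int

    @property
    def concordance(self) -> float | None:
        if self.comparisons == 0:
            return None
        return self.matches / self.comparisons


@dataclass(frozen=True)
class ConcordanceResult:
    per_sample: dict[str, SampleConcordance]
    mean_concordance: float | None
    mean_comparisons: float

    def to_dict(self) -> dict:
        return {
            "per_sample": {
                s: {"comparisons": c.comparisons, "matches": c.matches, "concordance": c.concordance}
                for s, c in sorted(self.per_sample.items())
            },
            "mean_concordance": self.mean_concordance,
            "mean_comparisons": self.mean_comparisons,
        }


_MISSING_ALLELES = {"", "-", ".", "N", "--"}


def concordance(
    array_report: pd.DataFrame,
    seq_calls: list[VariantRecord],
    panel: PanelConfig | None = None,
    min_depth: int = 10,
) -> ConcordanceResult:
    """Compare forward-strand array genotypes against re-sequencing calls.

    A comparison requires a non-missing call on both sides and sequencing
    depth of at least ``min_depth``; a match is an identical *unordered*
    allele pair (AB vs 0/1 at an A/B site matches). Samples with zero
    comparisons have undefined concordance and are excluded from the mean.
    """
    by_id = {rec.snp_id: rec for rec in seq_calls}
    stats: dict[str, list[int]] = {}
    for row in array_report.itertuples(index=False):
        rec = by_id.get(row.snp_id)
        if rec is None:
            continue
        if panel is not None and row.sample not in panel.diploid_members:
            continue
        if row.sample not in rec.per_sample:
            continue
        a1, a2 = str(row.allele1).upper(), str(row.allele2).upper()
        if a1 in _MISSING_ALLELES or a2 in _MISSING_ALLELES:
            continue
        call = rec.per_sample[row.sample]
        if call.is_missing or call.depth < min_depth:
            continue
        seq_pair = rec.genotype_nucleotides(row.sample)
        entry = stats.setdefault(row.sample, [0, 0])
        entry[0] += 1
        if sorted((a1, a2)) == sorted(seq_pair):
            entry[1] += 1
    per_sample = {s: SampleConcordance(c, m) for s, (c, m) in stats.items()}
    defined = [sc.concordance for sc in per_sample.values() if sc.concordance is not None]
    mean_conc = sum(defined) / len(defined) if defined else None
    mean_comp = (
        sum(sc.comparisons for sc in per_sample.values()) / len(per_sample) if per_sample else 0.0
    )
    return ConcordanceResult(per_sample=per_sample, mean_concordance=mean_conc, mean_comparisons=mean_comp)
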