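"""Quality-filter cascade for candidate variants.

The cascade mirrors discovery practice for a highly paralogous genome: a
double-haploid (DH) heterozygosity filter catches collapsed paralogs, then
site quality, combined depth, per-sample support, caller bias annotations
and a low-confidence-region mask, and finally the allele-frequency rule that
discards sites where every called allele differs from the reference (likely
reference errors or reference-private alleles).

Every verdict is a pure function of the record plus configuration, so runs
are reproducible record by record. Funnel accounting attributes each removed
record to the *first* failing reason, evaluated in cascade order, which
makes per-reason removal counts additive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from intervaltree import IntervalTree

from .formats import PanelConfig, VariantRecord, position_masked
from .reporting import FunnelStage

#: cascade order used for first-reason attribution
QUALITY_REASONS = (
    "dh_het", "low_qual", "high_depth", "low_support",
    "strand_bias", "tail_bias", "masked_region", "af_one",
)


@dataclass(frozen=True)
class QualityThresholds:
    """Thresholds of the quality cascade.

    Defaults: phred site quality >= 20 (<1% chance of a wrong alternate
    call); combined depth <= 2000 (paralog pile-ups); per-sample support
    >= 10 reads; a site fails when *more than* half the diploid members are
    under-supported; caller strand-bias p < 0.001 and tail-distance-bias
    p < 0.05 are disqualifying.
    """

    min_site_quality: float = 20.0
    max_combined_depth: int = 2000
    min_sample_depth: int = 10
    max_low_depth_fraction: float = 0.5
    strand_bias_p: float = 0.001
    tail_bias_p: float = 0.05
    min_call_support: int = 10

    def __post_init__(self) -> None:
        if min(self.min_site_quality, self.max_combined_depth, self.min_sample_depth,
               self.strand_bias_p, self.tail_bias_p, self.min_call_support) <= 0:
            raise ValueError("all thresholds must be strictly positive")
        if not 0 < self.max_low_depth_fraction <= 1:
            raise ValueError("max_low_depth_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to an empty reason list")

    @classmethod
    def ok(cls) -> "FilterVerdict":
        return cls(True, ())

    @classmethod
    def fail(cls, *reasons: str) -> "FilterVerdict":
        return cls(False, tuple(reasons))


def mask_unreliable_calls(record: VariantRecord, t: QualityThresholds) -> VariantRecord:
    """Set genotype calls supported by fewer than ``min_call_support`` reads to missing.

    Depths are retained so coverage statistics can still be reported.
    """
    changed = {
        s: replace(c, allele_indices=None)
        for s, c in record.per_sample.items()
        if not c.is_missing and c.depth < t.min_call_support
    }
    if not changed:
        return record
    per_sample = dict(record.per_sample)
    per_sample.update(changed)
    return replace(record, per_sample=per_sample)


def dh_paralog_filter(record: VariantRecord, panel: PanelConfig) -> FilterVerdict:
    """Fail a site heterozygous in any double haploid.

    DH accessions are homozygous genome-wide, so an apparent heterozygote
    there is evidence of paralogous sequences co-aligned to one locus, not
    of variation. A missing DH call does not count as heterozygous: the
    filter acts on observed heterozygosity only.
    """
    for dh in panel.dh_members:
        if record.per_sample[dh].is_het:
            return FilterVerdict.fail("dh_het")
    return FilterVerdict.ok()


def site_quality_filter(
    record: VariantRecord, panel: PanelConfig, t: QualityThresholds
) -> FilterVerdict:
    """Site quality, combined depth, and per-sample support checks.

    The support rule is strict: the site fails only when *more than*
    ``max_low_depth_fraction`` of the diploid members have depth below
    ``min_sample_depth``; exactly half passes.
    """
    reasons: list[str] = []
    if record.site_quality < t.min_site_quality:
        reasons.append("low_qual")
    if record.combined_depth > t.max_combined_depth:
        reasons.append("high_depth")
    n_low = sum(
        1 for s in panel.diploid_members if record.per_sample[s].depth < t.min_sample_depth
    )
    if n_low / panel.n_diploid > t.max_low_depth_fraction:
        reasons.append("low_support")
    return FilterVerdict(not reasons, tuple(reasons))


def bias_and_mask_filter(
    record: VariantRecord,
    mask: dict[str, IntervalTree] | None,
    t: QualityThresholds,
) -> FilterVerdict:
    """Caller bias annotations and low-mapping-confidence mask.

    Absent annotations are treated as non-significant — the pipeline
    consumes caller-provided tests, it does not recompute them from reads.
    """
    reasons: list[str] = []
    sb = record.annotations.get("strand_bias_p")
    if sb is not None and sb < t.strand_bias_p:
        reasons.append("strand_bias")
    tb = record.annotations.get("tail_bias_p")
    if tb is not None and tb < t.tail_bias_p:
        reasons.append("tail_bias")
    if position_masked(mask, record.chrom, record.pos):
        reasons.append("masked_region")
    return FilterVerdict(not reasons, tuple(reasons))


def allele_frequency_filter(record: VariantRecord, panel: PanelConfig) -> FilterVerdict:
    """Discard sites where every called diploid allele is non-reference (AF = 1).

    Such sites indicate a reference-sequence error or a reference-private
    rare allele rather than useful polymorphism. Frequency is computed over
    non-missing diploid calls only; DHs are paralogy instruments, not part
    of the diversity panel. With every call missing the site is
    unassessable and fails with ``low_support``.
    """
    alt = 0
    total = 0
    for s in panel.diploid_members:
        call = record.per_sample[s]
        if call.is_missing:
            continue
        for a in call.allele_indices:
            total += 1
            if a != 0:
                alt += 1
    if total == 0:
        return FilterVerdict.fail("low_support")
    if alt == total:
        return FilterVerdict.fail("af_one")
    return FilterVerdict.ok()


def quality_verdict(
    record: VariantRecord,
    panel: PanelConfig,
    mask: dict[str, IntervalTree] | None,
    t: QualityThresholds,
) -> tuple[VariantRecord, FilterVerdict]:
    """Run the full cascade on one record (after low-support call masking)."""
    masked_rec = mask_unreliable_calls(record, t)
    reasons: list[str] = []
    for verdict in (
        dh_paralog_filter(masked_rec, panel),
        site_quality_filter(masked_rec, panel, t),
        bias_and_mask_filter(masked_rec, mask, t),
        allele_frequency_filter(masked_rec, panel),
    ):
        reasons.extend(verdict.reasons)
    reasons.sort(key=QUALITY_REASONS.index)
    return masked_rec, FilterVerdict(not reasons, tuple(reasons))


def apply_quality_stage(
    records: list[VariantRecord],
    panel: PanelConfig,
    mask: dict[str, IntervalTree] | None = None,
    t: QualityThresholds | None = None,
) -> tuple[list[VariantRecord], FunnelStage]:
    """Apply the cascade to a sorted record list.

    Returns survivors (with unreliable calls masked) and a funnel stage in
    which each removed record is attributed to its first failing reason.
    """
    t = t or QualityThresholds()
    survivors: list[VariantRecord] = []
    removals: dict[str, int] = {}
    for record in records:
        masked_rec, verdict = quality_verdict(record, panel, mask, t)
        if verdict.passed:
            survivors.append(masked_rec)
        else:
            first = verdict.reasons[0]
            removals[first] = removals.get(first, 0) + 1
    stage = FunnelStage(
        name="quality_filtering",
        input_count=len(records),
        removals=removals,
        survivor_count=len(survivors),
    )
    return survivors, stage
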