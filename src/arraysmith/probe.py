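"""Infinium II probe-compatibility filtering.

Single-bead Infinium II assays interrogate one bi-allelic substitution via a
50-mer probe ending immediately beside the variant, which imposes four
design constraints implemented here:

* only single-nucleotide, bi-allelic substitutions are designable, and A/T
  or C/G pairs would need two bead types, so both are excluded;
* another high-quality SNP within 50 bp of the target destabilizes probe
  hybridization;
* a probe whose directly flanking 24 bp occurs elsewhere in the genome can
  hybridize to paralogous loci — flank uniqueness is checked against a
  canonical (strand-collapsed) k-mer index of the whole genome, since
  probes bind either strand;
* an external per-SNP convertibility score below 0.7 predicts assay
  failure.

Whether one repeated flank disqualifies a SNP, or both must repeat, is
configurable (``uniqueness_mode``); the stricter "either" is the default,
matching the goal of avoiding paralog-binding probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats import Genome, VariantRecord
from .quality import FilterVerdict
from .reporting import FunnelStage

logger = logging.getLogger(__name__)

PROBE_REASONS = (
    "indel", "triallelic", "at_cg", "near_snp", "near_end", "flank_repeat", "low_score",
)


@dataclass(frozen=True)
class ProbeRules:
    flank_snp_window: int = 50
    flank_kmer: int = 24
    min_design_score: float = 0.7
    uniqueness_mode: str = "either"  # "either" | "both"

    def __post_init__(self) -> None:
        if self.flank_kmer > self.flank_snp_window:
            raise ValueError("flank_kmer must not exceed flank_snp_window")
        if not 0 <= self.min_design_score <= 1:
            raise ValueError("min_design_score must be in [0, 1]")
        if self.uniqueness_mode not in ("either", "both"):
            raise ValueError("uniqueness_mode must be 'either' or 'both'")


_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i


def _rolling_codes(codes4: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit packed codes for every k-window plus a validity mask.

    Windows containing any non-ACGT base are flagged invalid.
    """
    n = codes4.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    invalid = (codes4 == 255).astype(np.int64)
    csum = np.concatenate(([0], np.cumsum(invalid)))
    valid = (csum[k:] - csum[:-k]) == 0
    safe = np.where(codes4 == 255, 0, codes4).astype(np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out |= safe[j : j + n] << np.uint64(2 * (k - 1 - j))
    return out, valid


def _canonical_codes(seq: str, k: int) -> tuple[np.ndarray, int]:
    """Canonical (min of forward and reverse-complement) codes of all valid
    k-windows of ``seq``, plus the count of ambiguous windows."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes4 = _BASE_CODE[arr]
    fwd, valid = _rolling_codes(codes4, k)
    rc4 = np.where(codes4 == 255, np.uint8(255), 3 - codes4)[::-1]
    rc_windows, _ = _rolling_codes(rc4, k)
    rc = rc_windows[::-1]  # rc[i] = revcomp of window starting at i
    canonical = np.minimum(fwd, rc)
    return canonical[valid], int((~valid).sum())


@dataclass
class KmerIndex:
    """Whole-genome canonical k-mer occurrence counts.

    Ambiguous windows are tallied under a sentinel and always treated as
    non-unique. Lookup uses binary search on the sorted code array.
    """

    k: int
    codes: np.ndarray  # sorted uint64
    counts: np.ndarray  # aligned int64
    ambiguous_windows: int
    total_positions: int

    def encode(self, kmer: str) -> int | None:
        """Canonical integer code of a k-mer, or None if ambiguous."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        arr = _BASE_CODE[np.frombuffer(kmer.upper().encode("ascii"), dtype=np.uint8)]
        if (arr == 255).any():
            return None
        fwd = 0
        rc = 0
        for j in range(self.k):
            fwd = (fwd << 2) | int(arr[j])
            rc = (rc << 2) | int(3 - arr[self.k - 1 - j])
        return min(fwd, rc)

    def count(self, kmer: str) -> int | None:
        """Genome-wide canonical occurrence count; None for ambiguous k-mers."""
        code = self.encode(kmer)
        if code is None:
            return None
        i = int(np.searchsorted(self.codes, np.uint64(code)))
        if i < self.codes.size and self.codes[i] == np.uint64(code):
            return int(self.counts[i])
        return 0

    def is_unique(self, kmer: str) -> bool:
        c = self.count(kmer)
        return c is not None and c <= 1


def build_kmer_index(genome: Genome | dict[str, str], k: int = 24) -> KmerIndex:
    """Index canonical k-mer counts over every chromosome of the genome."""
    sequences = genome.sequences if isinstance(genome, Genome) else genome
    chunks: list[np.ndarray] = []
    ambiguous = 0
    total = 0
    for chrom, seq in sequences.items():
        if len(seq) < k:
            logger.warning("chromosome %s shorter than k=%d; skipped", chrom, k)
            continue
        total += len(seq) - k + 1
        canon, n_amb = _canonical_codes(seq, k)
        ambiguous += n_amb
        chunks.append(canon)
    if chunks:
        codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    else:
        codes, counts = np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    return KmerIndex(k=k, codes=codes, counts=counts, ambiguous_windows=ambiguous, total_positions=total)


def snp_type_filter(record: VariantRecord) -> FilterVerdict:
    """Reject indels, tri-allelic sites, and A/T or C/G transversions."""
    if len(record.ref_allele) != 1 or any(len(a) != 1 for a in record.alt_alleles):
        return FilterVerdict.fail("indel")
    if len(record.alt_alleles) > 1:
        return FilterVerdict.fail("triallelic")
    pair = {record.ref_allele.upper(), record.alt_alleles[0].upper()}
    if pair in ({"A", "T"}, {"C", "G"}):
        return FilterVerdict.fail("at_cg")
    return FilterVerdict.ok()


def flank_snp_filter(
    record: VariantRecord,
    hq_positions: dict[str, np.ndarray],
    rules: ProbeRules | None = None,
) -> FilterVerdict:
    """Fail a SNP with another high-quality SNP within the flank window.

    ``hq_positions`` holds, per chromosome, the sorted positions of the
    quality-stage survivors. The rule is symmetric: both members of a close
    pair fail.
    """
    rules = rules or ProbeRules()
    positions = hq_positions.get(record.chrom)
    if positions is None or positions.size == 0:
        return FilterVerdict.ok()
    w = rules.flank_snp_window
    lo = int(np.searchsorted(positions, record.pos - w, side="left"))
    hi = int(np.searchsorted(positions, record.pos + w, side="right"))
    n_in_window = hi - lo
    n_self = int(np.searchsorted(positions, record.pos, side="right")) - int(
        np.searchsorted(positions, record.pos, side="left")
    )
    if n_in_window - n_self > 0:
        return FilterVerdict.fail("near_snp")
    return FilterVerdict.ok()


def flank_uniqueness_filter(
    record: VariantRecord,
    genome: Genome | dict[str, str],
    index: KmerIndex,
    rules: ProbeRules | None = None,
) -> FilterVerdict:
    """Check genome-wide uniqueness of the k-mers directly flanking the SNP."""
    rules = rules or ProbeRules()
    sequences = genome.sequences if isinstance(genome, Genome) else genome
    seq = sequences[record.chrom]
    k = rules.flank_kmer
    p = record.pos  # 1-based
    if p - 1 < k or len(seq) - p < k:
        return FilterVerdict.fail("near_end")
    upstream = seq[p - 1 - k : p - 1]
    downstream = seq[p : p + k]
    up_repeat = not index.is_unique(upstream)
    down_repeat = not index.is_unique(downstream)
    if rules.uniqueness_mode == "either":
        bad = up_repeat or down_repeat
    else:
        bad = up_repeat and down_repeat
    return FilterVerdict.fail("flank_repeat") if bad else FilterVerdict.ok()


def score_gate(
    record: VariantRecord,
    scores: dict[str, float] | None,
    rules: ProbeRules | None = None,
) -> FilterVerdict:
    """Gate on the external probe-convertibility score (fail below 0.7).

    An absent score passes with a notice: scores come from an external
    design tool and may not cover every candidate.
    """
    rules = rules or ProbeRules()
    score = None
    if scores is not None:
        score = scores.get(record.snp_id)
    if score is None:
        score = record.annotations.get("design_score")
    if score is None:
        logger.debug("no design score for %s; passing score gate", record.snp_id)
        return FilterVerdict.ok()
    if score < rules.min_design_score:
        return FilterVerdict.fail("low_score")
    return FilterVerdict.ok()


def hq_position_arrays(records: list[VariantRecord]) -> dict[str, np.ndarray]:
    """Sorted per-chromosome position arrays for the flank-SNP rule."""
    by_chrom: dict[str, list[int]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec.pos)
    return {c: np.asarray(sorted(v), dtype=np.int64) for c, v in by_chrom.items()}


def apply_probe_stage(
    records: list[VariantRecord],
    genome: Genome | dict[str, str],
    index: KmerIndex | None = None,
    scores: dict[str, float] | None = None,
    rules: ProbeRules | None = None,
    hq_positions: dict[str, np.ndarray] | None = None,
) -> tuple[list[VariantRecord], FunnelStage]:
    """Run variant-type, flank-SNP, flank-uniqueness and score filters.

    ``records`` are the quality-stage survivors and also define the
    high-quality positions for the 50 bp rule unless ``hq_positions``
    overrides them. Funnel attribution is first-failing-reason in the order
    type → near_snp → near_end/flank_repeat → low_score.
    """
    rules = rules or ProbeRules()
    if index is None:
        index = build_kmer_index(genome, rules.flank_kmer)
    if hq_positions is None:
        hq_positions = hq_position_arrays(records)
    survivors: list[VariantRecord] = []
    removals: dict[str, int] = {}
    if scores is None:
        logger.info("no design-score table supplied; score gate passes all candidates")
    for rec in records:
        reasons: list[str] = []
        for verdict in (
            snp_type_filter(rec),
            flank_snp_filter(rec, hq_positions, rules),
        ):
            reasons.extend(verdict.reasons)
        # only well-formed SNPs have meaningful single-base flanks
        if not reasons or reasons[0] not in ("indel",):
            reasons.extend(flank_uniqueness_filter(rec, genome, index, rules).reasons)
        reasons.extend(score_gate(rec, scores, rules).reasons)
        reasons.sort(key=PROBE_REASONS.index)
        if reasons:
            removals[reasons[0]] = removals.get(reasons[0], 0) + 1
        else:
            survivors.append(rec)
    stage = FunnelStage(
        name="probe_filtering",
        input_count=len(records),
        removals=removals,
        survivor_count=len(survivors),
    )
    return survivors, stage
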