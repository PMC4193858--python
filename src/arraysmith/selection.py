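"""Tiered, complementarity-balancing SNP selection within focal points.

Within each focal point (FP) up to ``max_per_fp`` SNPs are chosen so that
the selected set is maximally informative for haploblock construction
across the discovery panel:

* duplicate genotype profiles are collapsed first — two SNPs with identical
  calls across the panel are almost certainly the same haplotype;
* SNPs heterozygous in more than ``het_cap`` (65%) of the members are
  excluded outright as probable paralogy;
* when more than ``max_per_fp`` candidates remain, a step-wise greedy picks
  up to ``max_tier1`` widely polymorphic SNPs (het fraction 0.35–0.60,
  5–8 of 14 members), then mid-frequency SNPs (0.10–0.35, 2–4 members),
  then single-member SNPs (at most one per member, reduced-weight members
  such as a crab-apple outgroup filled last), then any remaining eligible
  profiles by descending heterozygote count.

Complementarity is operationalized as a concave marginal gain: a candidate
scores sum over its heterozygous members m of 1 / (1 + c(m)), where c(m) is
the number of already-selected SNPs heterozygous in m. Under-covered members
therefore attract the next pick, which balances member representation.

After per-FP selection, adjacent FPs are scrutinized so that two nearby FPs
do not both rely on a single-member SNP for the same member, and previously
validated legacy markers are merged in (exempt from the per-FP cap).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .focal import FocalPoint
from .formats import PanelConfig, VariantRecord

logger = logging.getLogger(__name__)


class Tier(Enum):
    TIER1 = "tier1"  # het fraction in [0.35, 0.60] — widely polymorphic
    TIER2 = "tier2"  # het fraction in [0.10, 0.35) — mid frequency
    TIER3 = "tier3"  # exactly one heterozygous member
    FILLER = "filler"  # eligible but outside the named strata
    EXCLUDED = "excluded"  # no heterozygote, or above the paralogy cap


@dataclass(frozen=True)
class SelectionConfig:
    max_per_fp: int = 11
    max_tier1: int = 5
    het_cap: float = 0.65
    tier1_range: tuple[float, float] = (0.35, 0.60)  # inclusive both ends
    tier2_range: tuple[float, float] = (0.10, 0.35)  # [lo, hi)
    reduced_weight_policy: str = "fill-last"

    def __post_init__(self) -> None:
        if self.max_tier1 > self.max_per_fp:
            raise ValueError("max_tier1 must not exceed max_per_fp")


@dataclass(frozen=True)
class HetProfile:
    """Per-SNP heterozygosity over the diploid panel members, in panel order.

    A missing call is not heterozygous; ``het_fraction`` uses the number of
    non-missing member calls as its denominator.
    """

    snp_id: str
    het_vector: tuple[bool, ...]
    het_count: int
    het_fraction: float
    n_called: int


def het_profile(record: VariantRecord, panel: PanelConfig) -> HetProfile:
    vec = tuple(record.per_sample[s].is_het for s in panel.diploid_members)
    n_called = sum(1 for s in panel.diploid_members if not record.per_sample[s].is_missing)
    count = sum(vec)
    frac = count / n_called if n_called else 0.0
    return HetProfile(record.snp_id, vec, count, frac, n_called)


def tier_of(profile: HetProfile, config: SelectionConfig | None = None) -> Tier:
    config = config or SelectionConfig()
    if profile.het_count == 0 or profile.het_fraction > config.het_cap:
        return Tier.EXCLUDED
    if profile.het_count == 1:
        return Tier.TIER3
    lo1, hi1 = config.tier1_range
    if lo1 <= profile.het_fraction <= hi1:
        return Tier.TIER1
    lo2, hi2 = config.tier2_range
    if lo2 <= profile.het_fraction < hi2:
        return Tier.TIER2
    return Tier.FILLER


@dataclass
class Candidate:
    """A probe-stage survivor annotated for selection within one FP."""

    record: VariantRecord
    profile: HetProfile
    score: float | None
    tier: Tier

    @property
    def snp_id(self) -> str:
        return self.record.snp_id

    @property
    def pos(self) -> int:
        return self.record.pos

    def genotype_key(self, panel: PanelConfig) -> tuple:
        return tuple(self.record.per_sample[s].allele_indices for s in panel.diploid_members)

    def sort_score(self) -> float:
        return self.score if self.score is not None else -1.0


def make_candidate(
    record: VariantRecord,
    panel: PanelConfig,
    scores: dict[str, float] | None = None,
    config: SelectionConfig | None = None,
) -> Candidate:
    profile = het_profile(record, panel)
    score = None
    if scores is not None:
        score = scores.get(record.snp_id)
    if score is None:
        score = record.annotations.get("design_score")
    return Candidate(record, profile, score, tier_of(profile, config))


def dedupe_profiles(
    candidates: list[Candidate], panel: PanelConfig
) -> tuple[list[Candidate], list[tuple[str, str]]]:
    """Collapse identical full genotype profiles within one FP.

    Among duplicates the highest-scoring SNP is kept (tie: smallest
    position); the removal log pairs each removed id with the kept
    representative's id.
    """
    groups: dict[tuple, list[Candidate]] = {}
    for cand in candidates:
        groups.setdefault(cand.genotype_key(panel), []).append(cand)
    kept: list[Candidate] = []
    removed: list[tuple[str, str]] = []
    for group in groups.values():
        group.sort(key=lambda c: (-c.sort_score(), c.pos, c.snp_id))
        kept.append(group[0])
        removed.extend((c.snp_id, group[0].snp_id) for c in group[1:])
    kept.sort(key=lambda c: (c.pos, c.snp_id))
    return kept, removed


def _greedy_pick(
    pool: list[Candidate],
    selected: list[Candidate],
    coverage: dict[int, int],
    budget: int,
) -> None:
    """Greedy complementarity picks from ``pool`` into ``selected`` in place.

    Marginal gain of a candidate: sum over its het members m of
    1 / (1 + coverage[m]); ties break to higher design score, then smaller
    position, then snp_id (canonical, order-independent).
    """
    pool = list(pool)
    while pool and budget > 0:
        best = min(
            pool,
            key=lambda c: (
                -sum(1.0 / (1 + coverage.get(m, 0)) for m, h in enumerate(c.profile.het_vector) if h),
                -c.sort_score(),
                c.pos,
                c.snp_id,
            ),
        )
        pool.remove(best)
        selected.append(best)
        budget -= 1
        for m, h in enumerate(best.profile.het_vector):
            if h:
                coverage[m] = coverage.get(m, 0) + 1


def select_within_fp(
    candidates: list[Candidate],
    panel: PanelConfig,
    config: SelectionConfig | None = None,
) -> list[Candidate]:
    """Select up to ``max_per_fp`` SNPs from one FP's deduped candidates.

    Candidates must already be deduped; EXCLUDED profiles are dropped
    defensively. With ``max_per_fp`` or fewer candidates everything is
    selected; otherwise the step-wise tiered greedy runs. The result is
    invariant to input order (candidates are canonically sorted first).
    """
    config = config or SelectionConfig()
    cands = sorted(
        (c for c in candidates if c.tier is not Tier.EXCLUDED),
        key=lambda c: (c.pos, c.snp_id),
    )
    if len(cands) <= config.max_per_fp:
        return list(cands)

    reduced_idx = {panel.diploid_members.index(s) for s in panel.reduced_weight_members}
    selected: list[Candidate] = []
    coverage: dict[int, int] = {}

    tier1 = [c for c in cands if c.tier is Tier.TIER1]
    _greedy_pick(tier1, selected, coverage, min(config.max_tier1, config.max_per_fp))

    tier2 = [c for c in cands if c.tier is Tier.TIER2]
    _greedy_pick(tier2, selected, coverage, config.max_per_fp - len(selected))

    # single-member SNPs: at most one per member, uncovered members first,
    # reduced-weight members only if slots remain after all others
    tier3 = [c for c in cands if c.tier is Tier.TIER3]
    used_members: set[int] = set()
    tier3.sort(
        key=lambda c: (
            c.profile.het_vector.index(True) in reduced_idx,
            coverage.get(c.profile.het_vector.index(True), 0) > 0,
            -c.sort_score(),
            c.pos,
            c.snp_id,
        )
    )
    for cand in tier3:
        if len(selected) >= config.max_per_fp:
            break
        member = cand.profile.het_vector.index(True)
        if member in used_members:
            continue
        used_members.add(member)
        selected.append(cand)
        coverage[member] = coverage.get(member, 0) + 1

    filler = [c for c in cands if c.tier is Tier.FILLER]
    filler.sort(key=lambda c: (-c.profile.het_count, -c.sort_score(), c.pos, c.snp_id))
    for cand in filler:
        if len(selected) >= config.max_per_fp:
            break
        selected.append(cand)
        for m, h in enumerate(cand.profile.het_vector):
            if h:
                coverage[m] = coverage.get(m, 0) + 1
    return selected


@dataclass
class FPSelection:
    """One focal point with its candidate pool and current selection."""

    fp: FocalPoint
    candidates: list[Candidate]  # deduped, EXCLUDED removed
    selected: list[Candidate] = field(default_factory=list)

    @property
    def n_alternatives(self) -> int:
        chosen = {c.snp_id for c in self.selected}
        return sum(1 for c in self.candidates if c.snp_id not in chosen)


def _tier3_member(cand: Candidate) -> int:
    return cand.profile.het_vector.index(True)


def _replacement_for(sel: FPSelection, banned_member: int,
                     config: SelectionConfig) -> Candidate | None:
    """Best unselected candidate, re-running the greedy gain against the
    current selection; single-member candidates for ``banned_member`` (or a
    member already carrying a selected single-member SNP) are ineligible."""
    chosen_ids = {c.snp_id for c in sel.selected}
    used_t3 = {_tier3_member(c) for c in sel.selected if c.tier is Tier.TIER3}
    n_tier1 = sum(1 for c in sel.selected if c.tier is Tier.TIER1)
    coverage: dict[int, int] = {}
    for c in sel.selected:
        for m, h in enumerate(c.profile.het_vector):
            if h:
                coverage[m] = coverage.get(m, 0) + 1
    pool = []
    for c in sel.candidates:
        if c.snp_id in chosen_ids:
            continue
        if c.tier is Tier.TIER3 and (_tier3_member(c) == banned_member or _tier3_member(c) in used_t3):
            continue
        if c.tier is Tier.TIER1 and n_tier1 >= config.max_tier1:
            continue
        pool.append(c)
    if not pool:
        return None
    tier_rank = {Tier.TIER1: 0, Tier.TIER2: 1, Tier.TIER3: 2, Tier.FILLER: 3}
    return min(
        pool,
        key=lambda c: (
            tier_rank[c.tier],
            -sum(1.0 / (1 + coverage.get(m, 0)) for m, h in enumerate(c.profile.het_vector) if h),
            -c.sort_score(),
            c.pos,
            c.snp_id,
        ),
    )


def cross_fp_scrutiny(
    selections: list[FPSelection],
    panel: PanelConfig,
    config: SelectionConfig | None = None,
) -> list[FPSelection]:
    """Resolve same-member single-heterozygote SNPs in adjacent FPs.

    For each pair of FPs adjacent on a chromosome both carrying a selected
    single-member (tier-3) SNP for the same member, the FP with more
    unselected alternatives swaps its copy for the best replacement, or
    drops it when no replacement exists. Scan order is (chrom, center), so
    the adjustment is deterministic.
    """
    config = config or SelectionConfig()
    ordered = sorted(selections, key=lambda s: (s.fp.chrom, s.fp.center))
    for left, right in zip(ordered, ordered[1:]):
        if left.fp.chrom != right.fp.chrom:
            continue
        left_t3 = {_tier3_member(c): c for c in left.selected if c.tier is Tier.TIER3}
        right_t3 = {_tier3_member(c): c for c in right.selected if c.tier is Tier.TIER3}
        for member in sorted(set(left_t3) & set(right_t3)):
            # the FP with more room to maneuver gives up its copy
            victim = left if left.n_alternatives > right.n_alternatives else right
            cand = left_t3[member] if victim is left else right_t3[member]
            victim.selected = [c for c in victim.selected if c.snp_id != cand.snp_id]
            repl = _replacement_for(victim, member, config)
            if repl is not None:
                victim.selected.append(repl)
            else:
                logger.info(
                    "scrutiny dropped %s (member %s) from %s with no replacement",
                    cand.snp_id, panel.diploid_members[member], victim.fp.fp_id,
                )
    return ordered


def merge_legacy(
    selections: list[FPSelection],
    legacy: pd.DataFrame | None,
    fps: list[FocalPoint],
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Build the manifest, merging validated legacy markers into FP windows.

    Legacy SNPs inside an FP window are appended to that FP exempt from the
    per-FP cap; others are carried outside any FP. A legacy marker at the
    same (chrom, pos) as a newly selected SNP collapses to the legacy entry.
    """
    rows: list[dict] = []
    new_by_locus: dict[tuple[str, int], dict] = {}
    for sel in selections:
        for cand in sel.selected:
            row = {
                "snp_id": cand.snp_id,
                "chrom": cand.record.chrom,
                "pos": cand.record.pos,
                "ref": cand.record.ref_allele,
                "alt": ",".join(cand.record.alt_alleles),
                "focal_point_id": sel.fp.fp_id,
                "tier": cand.tier.value,
                "source": "new",
                "het_count": cand.profile.het_count,
                "design_score": cand.score,
            }
            rows.append(row)
            new_by_locus[(row["chrom"], row["pos"])] = row

    if legacy is not None and len(legacy):
        sorted_fps = sorted(fps, key=lambda f: (f.chrom, f.center))
        for rec in legacy.itertuples(index=False):
            chrom, pos = str(rec.chrom), int(rec.pos)
            length = chrom_lengths.get(chrom)
            if length is not None and pos > length:
                raise ValueError(f"legacy marker {rec.snp_id} at {chrom}:{pos} beyond chromosome length {length}")
            containing = [fp for fp in sorted_fps if fp.chrom == chrom and fp.contains(pos)]
            if containing:
                best = min(containing, key=lambda fp: (abs(pos - fp.center), fp.fp_id))
                fp_id = best.fp_id
            else:
                fp_id = ""
            existing = new_by_locus.get((chrom, pos))
            if existing is not None:
                existing["snp_id"] = str(rec.snp_id)
                existing["source"] = "legacy"
                continue
            rows.append({
                "snp_id": str(rec.snp_id), "chrom": chrom, "pos": pos,
                "ref": str(getattr(rec, "ref", "")), "alt": str(getattr(rec, "alt", "")),
                "focal_point_id": fp_id, "tier": "", "source": "legacy",
                "het_count": "", "design_score": None,
            })

    manifest = pd.DataFrame(
        rows,
        columns=["snp_id", "chrom", "pos", "ref", "alt", "focal_point_id",
                 "tier", "source", "het_count", "design_score"],
    )
    if len(manifest):
        manifest = manifest.sort_values(["chrom", "pos", "snp_id"], kind="mergesort").reset_index(drop=True)
    return manifest
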