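"""End-to-end array design: quality → probe → focal points → selection →
manifest, with funnel accounting throughout.

The selection funnel stage attributes each probe-stage survivor to exactly
one outcome: outside any FP window, excluded by the heterozygosity cap,
removed as a duplicate profile, passed over by the tiered greedy, or
selected. Conservation of these counts is validated by the funnel report.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .focal import FocalPoint, FocalPointParams, assign_candidates, place_focal_points
from .formats import GeneticMapPoint, Genome, PanelConfig, VariantRecord
from .probe import KmerIndex, ProbeRules, apply_probe_stage, build_kmer_index
from .quality import QualityThresholds, apply_quality_stage
from .reporting import FunnelReport, FunnelStage, funnel_report
from .selection import (
    FPSelection,
    SelectionConfig,
    Tier,
    cross_fp_scrutiny,
    dedupe_profiles,
    make_candidate,
    merge_legacy,
    select_within_fp,
)


@dataclass
class PipelineResult:
    funnel: FunnelReport
    manifest: pd.DataFrame
    fps: list[FocalPoint]
    selections: list[FPSelection]
    quality_survivors: list[VariantRecord]
    probe_survivors: list[VariantRecord]


def run_pipeline(
    records: list[VariantRecord],
    genome: Genome,
    panel: PanelConfig,
    map_points: list[GeneticMapPoint],
    scores: dict[str, float] | None = None,
    legacy: pd.DataFrame | None = None,
    mask: dict[str, IntervalTree] | None = None,
    thresholds: QualityThresholds | None = None,
    probe_rules: ProbeRules | None = None,
    fp_params: FocalPointParams | None = None,
    selection_config: SelectionConfig | None = None,
    kmer_index: KmerIndex | None = None,
) -> PipelineResult:
    """Run the full design cascade and return manifest plus funnel."""
    thresholds = thresholds or QualityThresholds()
    probe_rules = probe_rules or ProbeRules()
    fp_params = fp_params or FocalPointParams()
    selection_config = selection_config or SelectionConfig()
    chrom_lengths = genome.lengths

    records = sorted(records, key=lambda r: (r.chrom, r.pos))
    detection = FunnelStage("detection", len(records), {}, len(records))

    q_survivors, q_stage = apply_quality_stage(records, panel, mask, thresholds)

    if kmer_index is None:
        kmer_index = build_kmer_index(genome, probe_rules.flank_kmer)
    p_survivors, p_stage = apply_probe_stage(
        q_survivors, genome, kmer_index, scores, probe_rules
    )

    fps = place_focal_points(map_points, chrom_lengths, fp_params)
    fps, outside = assign_candidates(fps, p_survivors)

    by_id = {rec.snp_id: rec for rec in p_survivors}
    removals = {"outside_fp": len(outside)}
    selections: list[FPSelection] = []
    n_excluded = 0
    n_dup = 0
    for fp in fps:
        if not fp.candidates:
            continue
        cands = [make_candidate(by_id[sid], panel, scores, selection_config)
                 for sid in fp.candidates]
        eligible = [c for c in cands if c.tier is not Tier.EXCLUDED]
        n_excluded += len(cands) - len(eligible)
        deduped, dup_log = dedupe_profiles(eligible, panel)
        n_dup += len(dup_log)
        chosen = select_within_fp(deduped, panel, selection_config)
        selections.append(FPSelection(fp=fp, candidates=deduped, selected=chosen))
    selections = cross_fp_scrutiny(selections, panel, selection_config)

    n_selected = sum(len(s.selected) for s in selections)
    removals["excluded_het"] = n_excluded
    removals["duplicate_profile"] = n_dup
    removals["not_selected"] = len(p_survivors) - len(outside) - n_excluded - n_dup - n_selected
    s_stage = FunnelStage("snp_selection", len(p_survivors), removals, n_selected)

    funnel = funnel_report([detection, q_stage, p_stage, s_stage])
    manifest = merge_legacy(selections, legacy, fps, chrom_lengths)
    return PipelineResult(
        funnel=funnel, manifest=manifest, fps=fps, selections=selections,
        quality_survivors=q_survivors, probe_survivors=p_survivors,
    )


def end_to_end_fixture(spec=None):
    """Run the full pipeline on a synthetic dataset and assert planted truth.

    Every planted artifact class must be removed by exactly its own filter
    (100% recall, zero clean removals), and all FP/selection invariants
    must hold. Returns ``(dataset, PipelineResult)``; an assertion failure
    means a pipeline bug.
    """
    from .synth import CLASS_REASON, SimulationSpec, simulate

    spec = spec or SimulationSpec()
    ds = simulate(spec)
    result = run_pipeline(
        ds.records, ds.genome, ds.panel, ds.map_points, scores=ds.scores
    )
    q_ids = {r.snp_id for r in result.quality_survivors}
    p_ids = {r.snp_id for r in result.probe_survivors}
    for label, reason in CLASS_REASON.items():
        planted = ds.truth.ids_of(label)
        surviving_pool = q_ids if reason in (
            "dh_het", "low_qual", "high_depth", "low_support", "af_one"
        ) else p_ids
        leaked = planted & surviving_pool
        assert not leaked, f"{label} variants leaked past their filter: {sorted(leaked)[:5]}"
    clean = ds.truth.ids_of("clean")
    assert clean <= p_ids, "clean variants were falsely removed"
    for sel in result.selections:
        new = [c for c in sel.selected]
        assert 1 <= len(new) <= 11, f"{sel.fp.fp_id} holds {len(new)} SNPs"
        assert all(c.profile.het_fraction <= 0.65 for c in new)
    return ds, result
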