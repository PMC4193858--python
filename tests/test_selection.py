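"""Tiered selection: profiles, dedupe, greedy complementarity, scrutiny, legacy."""

import random

import pandas as pd
import pytest

import arraysmith as ars
from arraysmith import Tier
from arraysmith.focal import FocalPointParams, _make_fp, number_focal_points
from arraysmith.selection import FPSelection
from helpers import coverage_of, make_candidate, make_record, oracle_best_coverage

CFG = ars.SelectionConfig()


class TestHetProfileAndTiers:
    @pytest.mark.parametrize("n_het,expected", [
        (6, Tier.TIER1),   # 6/14 = 0.429
        (5, Tier.TIER1),   # 0.357, lower inclusive bound region
        (8, Tier.TIER1),   # 0.571
        (2, Tier.TIER2),   # 0.143
        (4, Tier.TIER2),   # 0.286
        (1, Tier.TIER3),
        (9, Tier.FILLER),  # 0.643, between tier1 top and the 65% cap
        (10, Tier.EXCLUDED),  # 0.714 > 0.65
        (0, Tier.EXCLUDED),
    ])
    def test_member_counts_map_to_tiers_at_p14(self, panel14, n_het, expected):
        gts = {s: (0, 1) for s in panel14.diploid_members[:n_het]}
        rec = make_record(panel14, genotypes=gts)
        profile = ars.het_profile(rec, panel14)
        assert profile.het_count == n_het
        assert ars.tier_of(profile) is expected

    def test_missing_calls_shrink_the_denominator(self, panel14):
        gts = {s: (0, 1) for s in panel14.diploid_members[:6]}
        gts.update({s: None for s in panel14.diploid_members[12:]})
        profile = ars.het_profile(make_record(panel14, genotypes=gts), panel14)
        assert profile.n_called == 12
        assert profile.het_fraction == pytest.approx(0.5)


class TestDedupe:
    def test_identical_profiles_collapse_to_best_score(self, panel14):
        a = make_candidate(panel14, 100, (0, 1, 2), score=0.8, snp_id="a")
        b = make_candidate(panel14, 200, (0, 1, 2), score=0.95, snp_id="b")
        kept, removed = ars.dedupe_profiles([a, b], panel14)
        assert [c.snp_id for c in kept] == ["b"]
        assert removed == [("a", "b")]

    def test_distinct_profiles_untouched(self, panel14):
        a = make_candidate(panel14, 100, (0, 1), snp_id="a")
        b = make_candidate(panel14, 200, (0, 1), hom_alt_members=(5,), snp_id="b")
        kept, removed = ars.dedupe_profiles([a, b], panel14)
        assert len(kept) == 2 and removed == []

    def test_score_tie_keeps_smaller_position(self, panel14):
        cands = [
            make_candidate(panel14, 300, (0, 1, 2), score=0.8, snp_id="c"),
            make_candidate(panel14, 200, (0, 1, 2), score=0.9, snp_id="b"),
            make_candidate(panel14, 100, (0, 1, 2), score=0.9, snp_id="a"),
        ]
        kept, removed = ars.dedupe_profiles(cands, panel14)
        assert [c.snp_id for c in kept] == ["a"]
        assert dict(removed) == {"b": "a", "c": "a"}


class TestSelectWithinFP:
    def test_eleven_or_fewer_all_selected(self, panel14):
        cands = [make_candidate(panel14, 100 + i, (i % 14,), snp_id=f"s{i}") for i in range(9)]
        chosen = ars.select_within_fp(cands, panel14, CFG)
        assert len(chosen) == 9

    def test_tier1_capped_at_five_when_oversubscribed(self, panel14):
        cands = [make_candidate(panel14, 100 + i, tuple(range(i, i + 6)), snp_id=f"t1_{i}")
                 for i in range(8)]  # 8 tier-1 candidates
        cands += [make_candidate(panel14, 300 + i, (i % 14, (i + 1) % 14), snp_id=f"t2_{i}")
                  for i in range(8)]  # 8 tier-2
        assert len(cands) > CFG.max_per_fp
        chosen = ars.select_within_fp(cands, panel14, CFG)
        assert len(chosen) == 11
        assert sum(1 for c in chosen if c.tier is Tier.TIER1) == 5

    def test_selection_invariant_to_input_order(self, panel14):
        cands = [make_candidate(panel14, 100 + 7 * i, tuple((i + j) % 14 for j in range(1 + i % 8)),
                                score=0.7 + 0.02 * (i % 10), snp_id=f"c{i}") for i in range(18)]
        chosen_a = [c.snp_id for c in ars.select_within_fp(cands, panel14, CFG)]
        shuffled = list(cands)
        random.Random(5).shuffle(shuffled)
        chosen_b = [c.snp_id for c in ars.select_within_fp(shuffled, panel14, CFG)]
        assert sorted(chosen_a) == sorted(chosen_b)

    def test_single_member_snps_at_most_one_per_member_outgroup_last(self, panel14):
        # 20 single-member candidates: members 0..5 twice each, the
        # reduced-weight outgroup (index 13) eight times
        cands = []
        i = 0
        for m in range(6):
            for _ in range(2):
                cands.append(make_candidate(panel14, 100 + 10 * i, (m,), snp_id=f"m{m}_{i}"))
                i += 1
        for _ in range(8):
            cands.append(make_candidate(panel14, 100 + 10 * i, (13,), snp_id=f"out_{i}"))
            i += 1
        chosen = ars.select_within_fp(cands, panel14, CFG)
        members = [c.profile.het_vector.index(True) for c in chosen]
        assert len(members) == len(set(members)), "one single-member SNP per member"
        assert members.count(13) <= 1
        # the outgroup is only served after every other represented member
        assert set(range(6)) <= set(members)

    def test_greedy_matches_exhaustive_coverage_on_fixed_instance(self, panel14):
        profiles = [
            (0, 1, 2, 3, 4, 5), (4, 5, 6, 7, 8), (0, 1, 2, 3, 4),
            (8, 9, 10, 11, 12), (2, 3), (6, 7), (9, 10), (12, 13),
            (0,), (5,), (11,), (13,), (1, 2, 3), (7, 8, 9, 10),
        ]
        cands = [make_candidate(panel14, 100 + 11 * i, p, snp_id=f"f{i}")
                 for i, p in enumerate(profiles)]
        chosen = ars.select_within_fp(cands, panel14, CFG)
        assert len(chosen) == 11
        assert coverage_of(chosen) == oracle_best_coverage(cands, panel14, CFG)

    def test_member_balance_when_candidates_cover_everyone(self, panel14):
        # 14 tier-1/2 candidates jointly covering all members
        cands = [make_candidate(panel14, 100 + 13 * i, (i, (i + 1) % 14, (i + 2) % 14),
                                snp_id=f"b{i}") for i in range(14)]
        chosen = ars.select_within_fp(cands, panel14, CFG)
        covered = {m for c in chosen for m, h in enumerate(c.profile.het_vector) if h}
        assert covered == set(range(14))


def _fp(chrom, center, fp_id):
    fp = _make_fp(chrom, center, "anchored", FocalPointParams(), 1_000_000)
    fp.fp_id = fp_id
    return fp


class TestCrossFPScrutiny:
    def _selection(self, panel, fp, cands, selected):
        return FPSelection(fp=fp, candidates=cands, selected=selected)

    def test_adjacent_same_member_singleton_swapped_where_spare_exists(self, panel14):
        t3_a = make_candidate(panel14, 100, (3,), snp_id="a_t3")
        spare = make_candidate(panel14, 110, (5, 6), snp_id="a_spare")
        t3_b = make_candidate(panel14, 20_100, (3,), snp_id="b_t3")
        sel_a = self._selection(panel14, _fp("c", 1_000, "FP1"), [t3_a, spare], [t3_a])
        sel_b = self._selection(panel14, _fp("c", 11_000, "FP2"), [t3_b], [t3_b])
        out = ars.cross_fp_scrutiny([sel_a, sel_b], panel14)
        ids_a = {c.snp_id for c in out[0].selected}
        ids_b = {c.snp_id for c in out[1].selected}
        assert ids_a == {"a_spare"}, "FP with the alternative swaps"
        assert ids_b == {"b_t3"}
        assert coverage_of(out[0].selected) >= 1

    def test_no_replacement_means_drop(self, panel14):
        t3_a = make_candidate(panel14, 100, (3,), snp_id="a_t3")
        t3_b = make_candidate(panel14, 20_100, (3,), snp_id="b_t3")
        sel_a = self._selection(panel14, _fp("c", 1_000, "FP1"), [t3_a], [t3_a])
        sel_b = self._selection(panel14, _fp("c", 11_000, "FP2"), [t3_b], [t3_b])
        out = ars.cross_fp_scrutiny([sel_a, sel_b], panel14)
        total = sum(len(s.selected) for s in out)
        assert total == 1, "one of the conflicting singletons is dropped"

    def test_non_adjacent_fps_untouched(self, panel14):
        t3_a = make_candidate(panel14, 100, (3,), snp_id="a_t3")
        mid = make_candidate(panel14, 50_000, (1, 2), snp_id="mid")
        t3_b = make_candidate(panel14, 100_100, (3,), snp_id="b_t3")
        sels = [
            self._selection(panel14, _fp("c", 1_000, "FP1"), [t3_a], [t3_a]),
            self._selection(panel14, _fp("c", 50_000, "FP2"), [mid], [mid]),
            self._selection(panel14, _fp("c", 100_000, "FP3"), [t3_b], [t3_b]),
        ]
        out = ars.cross_fp_scrutiny(sels, panel14)
        assert {c.snp_id for s in out for c in s.selected} == {"a_t3", "mid", "b_t3"}

    def test_no_singletons_is_identity(self, panel14):
        a = make_candidate(panel14, 100, (1, 2), snp_id="a")
        b = make_candidate(panel14, 20_100, (3, 4), snp_id="b")
        sels = [
            self._selection(panel14, _fp("c", 1_000, "FP1"), [a], [a]),
            self._selection(panel14, _fp("c", 11_000, "FP2"), [b], [b]),
        ]
        out = ars.cross_fp_scrutiny(sels, panel14)
        assert {c.snp_id for s in out for c in s.selected} == {"a", "b"}


class TestMergeLegacy:
    def _one_fp_selection(self, panel):
        fp = _fp("c", 10_000, "FP1")
        cands = [make_candidate(panel, 6_000 + 60 * i, (i % 14, (i + 3) % 14),
                                chrom="c", snp_id=f"n{i}")
                 for i in range(11)]
        return FPSelection(fp=fp, candidates=cands, selected=cands), fp

    def test_legacy_inside_full_fp_exceeds_cap(self, panel14):
        sel, fp = self._one_fp_selection(panel14)
        legacy = pd.DataFrame([{"snp_id": "old1", "chrom": "c", "pos": 9_000}])
        manifest = ars.merge_legacy([sel], legacy, [fp], {"c": 1_000_000})
        in_fp = manifest[manifest["focal_point_id"] == "FP1"]
        assert len(in_fp) == 12
        assert (in_fp["source"] == "legacy").sum() == 1

    def test_legacy_outside_any_fp_goes_to_pool(self, panel14):
        sel, fp = self._one_fp_selection(panel14)
        legacy = pd.DataFrame([{"snp_id": "old1", "chrom": "c", "pos": 500_000}])
        manifest = ars.merge_legacy([sel], legacy, [fp], {"c": 1_000_000})
        row = manifest[manifest["snp_id"] == "old1"].iloc[0]
        assert row["focal_point_id"] == "" and row["source"] == "legacy"

    def test_same_locus_collapses_to_legacy(self, panel14):
        sel, fp = self._one_fp_selection(panel14)
        pos = sel.selected[0].pos
        legacy = pd.DataFrame([{"snp_id": "old1", "chrom": "c", "pos": pos}])
        manifest = ars.merge_legacy([sel], legacy, [fp], {"c": 1_000_000})
        at_locus = manifest[manifest["pos"] == pos]
        assert len(at_locus) == 1
        assert at_locus.iloc[0]["snp_id"] == "old1"
        assert at_locus.iloc[0]["source"] == "legacy"

    def test_legacy_beyond_chromosome_end_is_an_error(self, panel14):
        sel, fp = self._one_fp_selection(panel14)
        legacy = pd.DataFrame([{"snp_id": "old1", "chrom": "c", "pos": 2_000_000}])
        with pytest.raises(ValueError, match="beyond"):
            ars.merge_legacy([sel], legacy, [fp], {"c": 1_000_000})
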