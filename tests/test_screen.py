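"""Homozygote shared-diagnosis screen: eligibility, lists, filter, testing."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from revphewas.screen import (
    ScreenConfig,
    SharedList,
    eligible_variants,
    global_frequency_filter,
    screen_variants,
    shared_diagnosis_lists,
)
from revphewas.simulate import PlantedEffect, SimConfig, simulate_cohort

from conftest import build_cohort


def _eligibility_fixture():
    """5 variants with hand-countable eligibility at min_minor_hz=2.

    200 subjects, ancestry alternating EA (even index) / AA (odd), so each
    ancestry holds 100 subjects and 200 alleles.

    rs_ok:      10 minor HZ + 12 het, split evenly -> MAF 16/200 = 0.08 in
                both ancestries -> eligible
    rs_fewhz:   1 minor HZ -> excluded by the homozygote floor
    rs_highEA:  MAF 24/200 = 0.12 in EA, 10/200 = 0.05 in AA -> excluded
                (the ceiling applies in every ancestry)
    rs_allmiss: no calls -> excluded with a warning
    rs_ok2:     2 minor HZ, MAF 0.01 -> eligible
    """
    n = 200
    rs_ok = [0.0] * n
    for i in range(10):
        rs_ok[i] = 2.0
    for i in range(10, 22):
        rs_ok[i] = 1.0
    rs_fewhz = [0.0] * n
    rs_fewhz[0] = 2.0
    for i in range(1, 11):
        rs_fewhz[i] = 1.0
    rs_highEA = [0.0] * n
    for i in [0, 2, 4, 6]:          # 4 EA homozygotes
        rs_highEA[i] = 2.0
    for i in range(8, 40, 2):       # 16 EA heterozygotes -> EA dosage 24
        rs_highEA[i] = 1.0
    rs_highEA[1] = 2.0              # 1 AA homozygote
    for i in range(3, 19, 2):       # 8 AA heterozygotes -> AA dosage 10
        rs_highEA[i] = 1.0
    rs_ok2 = [0.0] * n
    rs_ok2[0] = rs_ok2[1] = 2.0
    geno = {
        "rs_ok": rs_ok,
        "rs_fewhz": rs_fewhz,
        "rs_highEA": rs_highEA,
        "rs_allmiss": [np.nan] * n,
        "rs_ok2": rs_ok2,
    }
    groups = {"G1": [True] * 6 + [False] * (n - 6), "G2": [False] * n}
    return build_cohort(geno, groups, ancestry=["EA", "AA"] * 100)


class TestEligibility:
    def test_fixture_eligible_subset_matches_hand_count(self):
        cohort = _eligibility_fixture()
        cfg = ScreenConfig(min_minor_hz=2)
        assert eligible_variants(cohort, cfg) == ["rs_ok", "rs_ok2"]

    def test_homozygote_floor_is_inclusive(self):
        cohort = _eligibility_fixture()
        # rs_ok has exactly 10 minor HZ: kept at the default floor of 10,
        # excluded at 11 (the "more than 10" reading)
        assert "rs_ok" in eligible_variants(cohort, ScreenConfig(min_minor_hz=10))
        assert "rs_ok" not in eligible_variants(cohort, ScreenConfig(min_minor_hz=11))

    def test_maf_ceiling_applies_in_every_ancestry(self):
        cohort = _eligibility_fixture()
        cfg = ScreenConfig(min_minor_hz=2, maf_max=0.10)
        assert "rs_highEA" not in eligible_variants(cohort, cfg)

    def test_all_missing_variant_excluded_with_warning(self, caplog):
        cohort = _eligibility_fixture()
        with caplog.at_level("WARNING"):
            out = eligible_variants(cohort, ScreenConfig(min_minor_hz=1))
        assert "rs_allmiss" not in out
        assert "rs_allmiss" in caplog.text


class TestSharedLists:
    def test_groups_below_sharer_floor_are_absent(self):
        cohort = build_cohort(
            genotypes={"rs1": [2, 2, 2, 0, 0, 0]},
            groups={
                "G_two": [True, True, False, False, False, False],
                "G_one": [True, False, False, True, True, False],
                "G_zero": [False, False, False, True, True, True],
            },
        )
        (sl,) = shared_diagnosis_lists(cohort, ["rs1"], ScreenConfig())
        assert sl.entries["group"].tolist() == ["G_two"]
        assert sl.entries["n_sharing"].tolist() == [2]

    def test_planted_group_appears_on_causal_variant_list(self):
        eff = PlantedEffect("rs100001", "G0003", "recessive", 8.0)
        cfg = SimConfig(n_subjects=4000, n_variants=5, n_groups=8,
                        planted_effects=(eff,), planted_maf=0.09,
                        planted_prevalence=0.10, missing_rate=0.0, seed=13)
        cohort, _ = simulate_cohort(cfg)
        lists = shared_diagnosis_lists(cohort, ["rs100001"], ScreenConfig())
        assert "G0003" in set(lists[0].entries["group"])


class TestGlobalFrequencyFilter:
    @staticmethod
    def _lists(appearances: dict[str, int], n_lists: int) -> list[SharedList]:
        lists = []
        for i in range(n_lists):
            grps = [g for g, cnt in appearances.items() if i < cnt]
            entries = pd.DataFrame({"group": grps, "n_sharing": [2] * len(grps)})
            lists.append(SharedList(f"v{i}", entries))
        return lists

    def test_six_percent_excluded_five_percent_kept(self):
        lists = self._lists({"G_6": 6, "G_5": 5, "pad": 100}, 100)
        kept, excluded = global_frequency_filter(lists, ScreenConfig())
        assert "G_6" in excluded
        assert "G_5" not in excluded  # strictly-greater-than rule

    def test_denominator_counts_only_nonempty_lists(self):
        # group on 2 of 20 non-empty lists = 10% > 5% -> excluded even
        # though 2/40 of all lists would pass
        lists = self._lists({"G": 2, "pad": 20}, 20) + self._lists({}, 20)
        _, excluded = global_frequency_filter(lists, ScreenConfig())
        assert "G" in excluded

    def test_exclusion_set_matches_brute_force(self):
        rng = np.random.default_rng(17)
        groups = [f"G{i}" for i in range(12)]
        lists = []
        for i in range(20):
            grps = [g for g in groups if rng.random() < 0.3]
            lists.append(SharedList(f"v{i}", pd.DataFrame({"group": grps, "n_sharing": 2})))
        kept, excluded = global_frequency_filter(lists, ScreenConfig(list_freq_max=0.25))
        nonempty = [sl for sl in lists if len(sl.entries)]
        expected = {
            g for g in groups
            if sum(g in set(sl.entries["group"]) for sl in nonempty) > 0.25 * len(nonempty)
        }
        assert excluded == expected
        for sl in kept:
            assert not (set(sl.entries["group"]) & excluded)

    def test_zero_lists_give_empty_output(self):
        kept, excluded = global_frequency_filter([], ScreenConfig())
        assert kept == [] and excluded == set()


class TestScreenVariants:
    def test_heterozygotes_never_enter_counts(self):
        # flipping heterozygote disease status must not change the screen
        base = {"rs1": [2] * 4 + [1] * 6 + [0] * 40}
        sick_hets = {"G1": [True] * 4 + [True] * 6 + [True] * 4 + [False] * 36}
        well_hets = {"G1": [True] * 4 + [False] * 6 + [True] * 4 + [False] * 36}
        cfg = ScreenConfig(min_minor_hz=2, maf_max=0.5, list_freq_max=1.0)
        rows = []
        for groups in (sick_hets, well_hets):
            res = screen_variants(build_cohort(dict(base), groups), cfg)
            rows.append(res[0].rows)
        pd.testing.assert_frame_equal(rows[0], rows[1])

    def test_variant_with_empty_shared_list_has_no_rows(self):
        cohort = build_cohort(
            genotypes={"rs1": [2, 2, 0, 0, 0, 0]},
            groups={"G1": [True, False, False, True, False, False]},
        )
        res = screen_variants(cohort, ScreenConfig(min_minor_hz=2, maf_max=0.5))
        assert res[0].n_tested == 0 and len(res[0].rows) == 0

    def test_lowering_alpha_never_adds_rows(self):
        cfg = SimConfig(n_subjects=1500, n_variants=30, n_groups=30, seed=23)
        cohort, _ = simulate_cohort(cfg)
        loose = screen_variants(cohort, ScreenConfig(nominal_alpha=0.05, list_freq_max=1.0))
        tight = screen_variants(cohort, ScreenConfig(nominal_alpha=0.01, list_freq_max=1.0))
        for lo, hi in zip(tight, loose):
            assert set(lo.rows["group"]) <= set(hi.rows["group"])

    def test_planted_effect_detected_with_high_power(self):
        hits = 0
        for seed in range(10):
            eff = PlantedEffect("rs100001", "G0003", "recessive", 5.0)
            cfg = SimConfig(n_subjects=8500, n_variants=10, n_groups=20,
                            planted_effects=(eff,), planted_maf=0.08,
                            planted_prevalence=0.10, seed=40 + seed)
            cohort, _ = simulate_cohort(cfg)
            res = screen_variants(cohort, ScreenConfig(list_freq_max=1.0))
            planted = [r for r in res if r.variant == "rs100001"]
            if planted and "G0003" in set(planted[0].rows["group"]):
                hits += 1
        assert hits >= 8

    def test_null_nominal_yield_is_near_alpha(self):
        # mean fraction of tested diagnoses reaching p < alpha should not
        # exceed alpha by much under the null (discreteness makes it lower)
        rates = []
        for seed in range(10):
            cfg = SimConfig(n_subjects=3000, n_variants=12, n_groups=40,
                            prevalence_range=(0.05, 0.2), block_rr=1.0,
                            missing_rate=0.0, seed=60 + seed)
            cohort, _ = simulate_cohort(cfg)
            res = screen_variants(cohort, ScreenConfig(list_freq_max=1.0))
            tested = sum(r.n_tested for r in res)
            if tested:
                rates.append(sum(len(r.rows) for r in res) / tested)
        assert np.mean(rates) < 0.08
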