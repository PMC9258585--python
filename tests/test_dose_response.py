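"""Dose-response normalization, classification and group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mistrans_sga.io import SpotGrid
from mistrans_sga.dose_response import (
    CATEGORIES,
    LEVELS,
    classify_grid,
    classify_profile,
    normalized_growth,
    profile_strains,
    relative_synthetic_effect,
    welch_bonferroni,
)
from mistrans_sga.simulate import factors_for_rel_synth, simulate_spots

TRIPLE = st.floats(min_value=1.0, max_value=200.0, allow_nan=False)


def _rel(lo, me, hi):
    return {"low": lo, "medium": me, "high": hi}


class TestNormalizedGrowth:
    def test_reduction_to_37_percent(self, spot_frame):
        pct, n_reps, _ = normalized_growth(SpotGrid(spot_frame), "BY4742",
                                           n_boot=0)
        assert pct["high"] == pytest.approx(37.0)
        assert pct["medium"] == pytest.approx(55.0)
        assert pct["low"] == pytest.approx(71.0)
        assert all(n == 3 for n in n_reps.values())

    def test_equal_constructs_give_100(self, spot_frame):
        df = spot_frame.copy()
        df["intensity"] = 100.0
        pct, _, _ = normalized_growth(SpotGrid(df), "BY4742", n_boot=0)
        assert all(v == pytest.approx(100.0) for v in pct.values())

    def test_dead_construct_gives_zero(self, spot_frame):
        df = spot_frame.copy()
        df.loc[df["construct"] == "tS(UGG)", "intensity"] = 0.0
        pct, _, _ = normalized_growth(SpotGrid(df), "BY4742", n_boot=0)
        assert pct["high"] == 0.0

    def test_missing_strain_errors(self, spot_frame):
        with pytest.raises(Exception):
            normalized_growth(SpotGrid(spot_frame), "nope", n_boot=0)


class TestRelativeSyntheticEffect:
    def test_self_reference_is_100(self):
        p = {"low": 71.0, "medium": 55.0, "high": 37.0}
        rel = relative_synthetic_effect(p, p)
        assert all(v == pytest.approx(100.0) for v in rel.values())

    def test_half_of_wild_type(self):
        rel = relative_synthetic_effect(_rel(40, 30, 20), _rel(80, 60, 40))
        assert all(v == pytest.approx(50.0) for v in rel.values())

    def test_zero_wild_type_flagged_nan(self):
        rel = relative_synthetic_effect(_rel(40, 30, 20), _rel(80, 60, 0))
        assert np.isnan(rel["high"])


class TestClassifyProfile:
    @pytest.mark.parametrize("triple, category", [
        ((95, 70, 40), "proportional"),
        ((80, 50, 48), "threshold"),
        ((60, 58, 55), "uniform"),
        ((100, 99, 95), "uniform"),
        ((50, 52, 48), "uniform"),
        ((70, 40, 45), "low_sensitive"),
        ((95, 40, 70), "low_sensitive"),  # non-monotone, none of the shapes
    ])
    def test_representative_profiles(self, triple, category):
        assert classify_profile(_rel(*triple)) == category

    def test_missing_level_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            classify_profile({"low": 90, "medium": 80})

    def test_non_positive_value_is_error(self):
        with pytest.raises(ValueError):
            classify_profile(_rel(90, 0, 40))

    @given(TRIPLE, TRIPLE, TRIPLE)
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_total_and_matches_vectorized(self, lo, me, hi):
        cat = classify_profile(_rel(lo, me, hi))
        assert cat in CATEGORIES
        code = classify_grid(np.array([lo]), np.array([me]), np.array([hi]))
        assert CATEGORIES[code[0]] == cat

    @given(st.floats(75, 89.5), st.floats(1, 74.5), st.floats(1, 74.5),
           st.floats(0.0, 50.0))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_lowering_high_never_turns_threshold_proportional(
            self, lo, me, hi, drop):
        if classify_profile(_rel(lo, me, hi)) != "threshold":
            return
        new_hi = max(hi - drop, 0.5)
        assert classify_profile(_rel(lo, me, new_hi)) != "proportional"


class TestWelchBonferroni:
    def test_identical_groups_p_one(self):
        (t, p, p_adj), = welch_bonferroni([([5, 5, 5], [5, 5, 5])])
        assert p == 1.0 and p_adj == 1.0

    def test_doubling_time_groups_clearly_split(self):
        (t, p, _), = welch_bonferroni([([84, 85, 83, 84], [98, 97, 99, 98])])
        assert p < 0.001
        # cross-check against the Welch statistic computed by hand
        a, b = np.array([84, 85, 83, 84.]), np.array([98, 97, 99, 98.])
        se = np.sqrt(a.var(ddof=1) / 4 + b.var(ddof=1) / 4)
        assert t == pytest.approx((a.mean() - b.mean()) / se, rel=1e-12)

    def test_bonferroni_caps_at_one(self):
        (_, p, p_adj), = welch_bonferroni([([1, 2, 3], [1.1, 2.2, 2.9])], m=3)
        assert p_adj == min(1.0, 3 * p)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_bonferroni([([1.0], [2.0, 3.0])])


class TestCohort:
    def test_planted_categories_recovered(self):
        grid, truth = simulate_spots(
            {"prop": factors_for_rel_synth((95, 70, 40)),
             "thresh": factors_for_rel_synth((80, 50, 48)),
             "unif": factors_for_rel_synth((60, 58, 55))},
            seed=8, noise_sd=0.02)
        profiles = {p.strain_id: p for p in profile_strains(grid, seed=9)}
        assert profiles["prop"].category == "proportional"
        assert profiles["thresh"].category == "threshold"
        assert profiles["unif"].category == "uniform"
        assert profiles["BY4742"].category is None
        wt = profiles["BY4742"].rel_synth
        assert all(v == pytest.approx(100.0) for v in wt.values())

    def test_uniform_interaction_factor(self):
        # a flat 0.5 multiplicative interaction at every level
        grid, _ = simulate_spots(
            {"flat": tuple(0.5 * f for f in factors_for_rel_synth(
                (100, 100, 100)))},
            seed=10, noise_sd=0.02)
        profiles = {p.strain_id: p for p in profile_strains(grid, seed=11)}
        rel = profiles["flat"].rel_synth
        for lv in LEVELS:
            assert rel[lv] == pytest.approx(50.0, abs=5.0)
        assert profiles["flat"].category == "uniform"

    def test_bootstrap_dispersion_reported(self, spot_frame):
        df = spot_frame.copy()
        rng = np.random.default_rng(0)
        df["intensity"] *= np.exp(rng.normal(0, 0.05, len(df)))
        pct, _, sds = normalized_growth(SpotGrid(df), "BY4742", n_boot=500,
                                        seed=1)
        assert set(sds) == set(LEVELS)
        assert all(0 < s < 20 for s in sds.values())
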