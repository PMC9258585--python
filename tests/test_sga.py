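"""Interaction scoring: the multiplicative model, normalization, BH, calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mistrans_sga.io import PlateGrid
from mistrans_sga.sga import (
    FitnessTable,
    bh_adjust,
    call_interactions,
    epsilon,
    fitness_from_block,
    normalize_plate,
    records_to_frame,
    score_alleles,
    score_screen,
)
from mistrans_sga.simulate import plate_border_mask


class TestEpsilon:
    @pytest.mark.parametrize("w_ab, w_a, w_b, expected", [
        (0.72, 0.8, 0.9, 0.0),     # exactly multiplicative
        (0.5, 1.0, 1.0, -0.5),
        (0.52, 0.9, 0.8, -0.2),    # sits exactly on the calling threshold
    ])
    def test_values(self, w_ab, w_a, w_b, expected):
        assert epsilon(w_ab, w_a, w_b) == pytest.approx(expected, abs=1e-15)

    def test_negative_fitness_rejected(self):
        with pytest.raises(ValueError):
            epsilon(-0.1, 0.5, 0.5)


class TestFitnessFromBlock:
    def test_full_block(self):
        np.testing.assert_allclose(
            fitness_from_block([500, 500, 500, 500], 500.0), [1, 1, 1, 1])

    def test_missing_replicate_dropped(self):
        f = fitness_from_block([250, 250, np.nan, 250], 500.0)
        np.testing.assert_allclose(f, [0.5, 0.5, 0.5])

    def test_dead_colonies_are_signal(self):
        np.testing.assert_allclose(
            fitness_from_block([0, 0, 0, 0], 500.0), [0, 0, 0, 0])

    def test_fewer_than_two_replicates_unscorable(self):
        assert fitness_from_block([np.nan, np.nan, np.nan, 300], 500.0) is None


class TestNormalizePlate:
    def test_uniform_plate_rescaled_to_reference(self):
        g = PlateGrid("p", 8, 12, np.full((8, 12), 400.0))
        out = normalize_plate(g, reference=500.0, mode="median")
        np.testing.assert_allclose(out.sizes, 500.0)

    def test_plate_at_reference_unchanged(self, rng):
        sizes = rng.uniform(450, 550, (8, 12))
        sizes *= 500.0 / np.median(sizes)
        g = PlateGrid("p", 8, 12, sizes)
        out = normalize_plate(g, reference=500.0, mode="median")
        np.testing.assert_allclose(out.sizes, sizes, rtol=1e-12)

    def test_column_gradient_inverted(self):
        # multiplicative column gradient 0.8 -> 1.2 on a constant plate
        grad = np.linspace(0.8, 1.2, 48)
        g = PlateGrid("p", 32, 48, 500.0 * np.tile(grad, (32, 1)))
        out = normalize_plate(g, reference=500.0, mode="polish")
        np.testing.assert_allclose(out.sizes, 500.0, rtol=0.01)

    def test_missing_flags_preserved(self):
        sizes = np.full((8, 12), 400.0)
        sizes[2, 3] = np.nan
        g = PlateGrid("p", 8, 12, sizes)
        out = normalize_plate(g, reference=500.0, mode="polish")
        assert out.missing[2, 3] and np.isnan(out.sizes[2, 3])

    def test_all_missing_plate_is_error(self):
        g = PlateGrid("p", 8, 12, np.full((8, 12), np.nan))
        with pytest.raises(Exception, match="missing"):
            normalize_plate(g, mode="median")


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        q = bh_adjust([0.01, 0.02, 0.04, 0.8])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.8],
                                   rtol=1e-12)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0] * 5, ), 1.0)

    def test_single_p_identity(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_independent_step_up(self, pvals):
        """q_i = min_{j>=i} m p_(j)/j, computed by explicit enumeration."""
        q = bh_adjust(pvals)
        m = len(pvals)
        order = sorted(range(m), key=lambda i: pvals[i])
        ps = sorted(pvals)
        qs = [min(1.0, m * p / (k + 1)) for k, p in enumerate(ps)]
        for k in range(m - 2, -1, -1):
            qs[k] = min(qs[k], qs[k + 1])
        for rank, idx in enumerate(order):
            assert q[idx] == pytest.approx(qs[rank], rel=1e-12, abs=1e-15)
        assert np.all(q >= np.asarray(pvals) - 1e-15)  # BH only raises p


class TestScoreAlleles:
    def _brute_force(self, fit):
        """Independent recomputation: plain-Python epsilons + scipy t-test."""
        rows = {}
        for a in fit.w_a:
            eps = [w - fit.w_a[a] * fit.w_b for w in fit.w_ab_reps[a]]
            mean = sum(eps) / len(eps)
            p = stats.ttest_1samp(eps, 0.0).pvalue
            rows[a] = (mean, p)
        return rows

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 11))
            alleles = [f"x{i}" for i in range(n)]
            fit = FitnessTable(
                w_b=float(rng.uniform(0.5, 1.0)),
                w_a={a: float(rng.uniform(0.3, 1.1)) for a in alleles},
                w_ab_reps={a: rng.uniform(0.1, 1.2, size=4) for a in alleles},
            )
            expected = self._brute_force(fit)
            for rec in score_alleles(fit):
                mean, p = expected[rec.allele_id]
                assert rec.eps_mean == pytest.approx(mean, rel=1e-12)
                assert rec.p_raw == pytest.approx(p, rel=1e-12)

    def test_consistent_signal_small_p(self, rng):
        eps = -0.3 + rng.normal(0, 1e-3, 4)
        fit = FitnessTable(w_b=1.0, w_a={"a": 1.0},
                           w_ab_reps={"a": 1.0 + eps})
        rec = score_alleles(fit)[0]
        assert rec.eps_mean == pytest.approx(-0.3, abs=0.01)
        assert rec.p_raw < 1e-4

    def test_null_signal_large_p(self):
        fit = FitnessTable(w_b=1.0, w_a={"a": 1.0},
                           w_ab_reps={"a": 1.0 + np.array([0.01, -0.01,
                                                           0.02, -0.02])})
        rec = score_alleles(fit)[0]
        assert abs(rec.eps_mean) < 1e-12
        assert rec.p_raw > 0.5

    def test_unscorable_allele_flagged(self):
        fit = FitnessTable(w_b=1.0, w_a={"a": 1.0}, w_ab_reps={"a": [1.0] * 4},
                           unscorable=["broken"])
        records = call_interactions(score_alleles(fit))
        rec = {r.allele_id: r for r in records}["broken"]
        assert rec.call == "none" and math.isnan(rec.p_raw)


class TestCallInteractions:
    @pytest.mark.parametrize("eps_mean, p, expected", [
        (-0.25, 0.01, "negative"),
        (-0.25, 0.20, "none"),       # fails FDR gate
        (-0.15, 0.001, "none"),      # fails magnitude gate
        (0.25, 0.01, "positive"),    # mirrored rule
    ])
    def test_joint_gate(self, eps_mean, p, expected):
        # one record => BH is the identity, so p_raw is the adjusted q
        from mistrans_sga.sga import InteractionRecord
        rec = InteractionRecord("a", "G", np.array([eps_mean] * 4),
                                eps_mean, p)
        out = call_interactions([rec])[0]
        assert out.q_bh == pytest.approx(p)
        assert out.call == expected

    def test_positive_threshold_must_be_negative(self):
        with pytest.raises(ValueError):
            call_interactions([], eps_threshold=0.2)


class TestScreenPipeline:
    def test_planted_interactions_recovered(self, small_screen, border_mask):
        sc, sim = small_screen
        records = score_screen(
            sim.double_plates, sim.control_plates, sim.key,
            reference=sim.reference, query_plates=sim.query_plates,
            mode="gradient", border_mask=border_mask,
        )
        df = records_to_frame(records).merge(sim.truth, on="allele")
        planted = df[df["eps_planted"] < 0]
        null = df[df["eps_planted"] == 0]
        assert (planted["call"] == "negative").mean() >= 0.95
        assert planted["eps_mean"].mean() == pytest.approx(-0.4, abs=0.05)
        assert (null["call"] == "negative").sum() == 0

    def test_epsilon_invariant_under_size_rescaling(self, small_screen,
                                                    border_mask):
        # median normalization cancels units: scaling every colony (and the
        # query cross) by the same constant leaves all scores unchanged
        _, sim = small_screen
        def run(scale):
            def scaled(plates):
                out = []
                for g in plates:
                    h = g.copy()
                    h.sizes = h.sizes * scale
                    out.append(h)
                return out
            return records_to_frame(score_screen(
                scaled(sim.double_plates), scaled(sim.control_plates),
                sim.key, reference=sim.reference,
                query_plates=scaled(sim.query_plates),
                mode="median", border_mask=plate_border_mask(),
            ))
        a, b = run(1.0), run(7.3)
        np.testing.assert_allclose(a["eps_mean"], b["eps_mean"], rtol=1e-9)
        assert (a["call"] == b["call"]).all()
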