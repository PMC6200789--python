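"""Summary statistics: BIAS/sqrt(VAR)/RMSE weighting, lapse filter, offset
removal, bootstrap CIs, null predictions, d-prime, signed-rank test."""

import warnings

import numpy as np
import pandas as pd
import pytest

import obsact as oa
from obsact import Transform


class TestSummarize:
    def test_three_four_five_triangle(self, cell_table_factory):
        # per-sample bias 3 and SD 4 exactly -> BIAS 3, sqrt(VAR) 4, RMSE 5
        cells = {c: [c + 3 - 4, c + 3, c + 3 + 4] for c in (700.0, 800.0, 900.0)}
        stats = oa.summarize(cell_table_factory(cells))
        assert stats.bias == pytest.approx(3.0)
        assert stats.sqrt_var == pytest.approx(4.0)
        assert stats.rmse == pytest.approx(5.0)

    def test_perfect_responses_give_zero(self, cell_table_factory):
        cells = {c: [c, c, c] for c in (700.0, 900.0)}
        stats = oa.summarize(cell_table_factory(cells))
        assert (stats.bias, stats.sqrt_var, stats.rmse) == (0.0, 0.0, 0.0)

    def test_trial_count_weighting(self, cell_table_factory):
        # n1=10 with bias 0, n2=30 with bias 2 -> BIAS = sqrt(30*4/40) = sqrt(3)
        cells = {
            700.0: [700.0 + d for d in [-1, 1] * 5],
            900.0: [902.0 + d for d in [-1, 1] * 15],
        }
        stats = oa.summarize(cell_table_factory(cells))
        assert stats.bias == pytest.approx(np.sqrt(3.0))

    def test_sum_of_squares_identity(self, exp1_spec, late_observer):
        for seed in (1, 2, 3):
            table = oa.generate_subject(exp1_spec, "remapped", late_observer, 400, seed=seed)
            s = oa.summarize(table)
            assert s.rmse**2 == pytest.approx(s.bias**2 + s.sqrt_var**2, rel=1e-12)

    def test_single_trial_cell_rejected(self, cell_table_factory):
        table = cell_table_factory({700.0: [700.0], 800.0: [790.0, 810.0]})
        with pytest.raises(ValueError, match="< 2 trials"):
            oa.summarize(table)

    def test_mixed_context_rejected(self, cell_table_factory):
        a = cell_table_factory({700.0: [700.0, 710.0]}, context="identity")
        b = cell_table_factory({700.0: [700.0, 710.0]}, context="remapped")
        with pytest.raises(ValueError, match="single-context"):
            oa.summarize(pd.concat([a, b], ignore_index=True))


class TestLapseFilter:
    def test_gross_outlier_removed(self, cell_table_factory):
        table = cell_table_factory({800.0: [800.0, 800.0, 801.0, 799.0, 10_000.0]})
        out, counts = oa.filter_lapses(table)
        assert counts == {"identity": 1}
        assert (out.loc[out["produced"] == 10_000.0, "excluded_reason"] == "lapse").all()

    def test_identical_responses_nothing_removed(self, cell_table_factory):
        table = cell_table_factory({800.0: [805.0] * 6})
        out, counts = oa.filter_lapses(table)
        assert counts == {}
        assert out["excluded_reason"].isna().all()

    def test_small_cell_skipped_with_warning(self, cell_table_factory):
        table = cell_table_factory({800.0: [1.0, 2.0, 9000.0]})
        with pytest.warns(UserWarning, match="lapse filter skipped"):
            _, counts = oa.filter_lapses(table)
        assert counts == {}

    def test_clean_simulation_removal_matches_gaussian_tail(self, exp1_spec, late_observer):
        """With the raw (unscaled) MAD about the cell mean, 3 x MAD sits at
        ~2.02 SD for Gaussian responses, so a clean simulation loses the
        corresponding two-tail mass, about 4.3% of trials."""
        table = oa.generate_subject(exp1_spec, "identity", late_observer, 10_000, seed=77)
        _, counts = oa.filter_lapses(table)
        frac = counts.get("identity", 0) / len(table)
        assert 0.02 < frac < 0.065

    def test_order_invariant(self, exp1_spec, late_observer):
        table = oa.generate_subject(exp1_spec, "identity", late_observer, 2_000, seed=78)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a, _ = oa.filter_lapses(table)
        b, _ = oa.filter_lapses(shuffled)
        removed_a = set(a.loc[a["excluded_reason"] == "lapse", "produced"].round(9))
        removed_b = set(b.loc[b["excluded_reason"] == "lapse", "produced"].round(9))
        assert removed_a == removed_b


class TestOffsetRemoval:
    def test_constant_shift_recovered_exactly(self, cell_table_factory):
        cells = {c: [c + 30.0, c + 30.0, c + 30.0] for c in (700.0, 900.0)}
        out, offset = oa.remove_offset(cell_table_factory(cells))
        assert offset == pytest.approx(30.0)
        assert oa.summarize(out).bias == pytest.approx(0.0, abs=1e-10)

    def test_zero_mean_error_table_unchanged(self, cell_table_factory):
        cells = {800.0: [790.0, 810.0, 805.0, 795.0]}
        table = cell_table_factory(cells)
        out, offset = oa.remove_offset(table)
        assert offset == pytest.approx(0.0)
        np.testing.assert_allclose(out["produced"], table["produced"])

    def test_prior_regression_bias_survives_offset_removal(self, exp1_spec, late_observer):
        """Regression to the prior mean is antisymmetric about the prior
        center, not a constant: the offset is near zero yet BIAS stays
        clearly positive."""
        table = oa.generate_subject(exp1_spec, "identity", late_observer, 20_000, seed=79)
        out, offset = oa.remove_offset(table)
        stats = oa.summarize(out)
        assert abs(offset) < 0.2 * stats.bias
        assert stats.bias > 10.0  # ms; substantial prior regression at w_pre=0.12

    def test_empty_table_rejected(self, cell_table_factory):
        with pytest.raises(ValueError, match="empty"):
            oa.remove_offset(cell_table_factory({}).iloc[0:0])


class TestBootstrap:
    def test_deterministic_given_seed(self, exp1_spec, late_observer):
        table = oa.generate_subject(exp1_spec, "identity", late_observer, 400, seed=80)
        a = oa.bootstrap_ci(table, "RMSE", 300, seed=5)
        b = oa.bootstrap_ci(table, "RMSE", 300, seed=5)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_zero_noise_degenerate_interval(self, cell_table_factory):
        cells = {c: [c, c, c, c] for c in (700.0, 900.0)}
        ci = oa.bootstrap_ci(cell_table_factory(cells), "RMSE", 200, seed=1)
        assert (ci.point, ci.lower, ci.upper) == (0.0, 0.0, 0.0)

    def test_width_shrinks_with_sample_size(self, exp1_spec, late_observer):
        widths = []
        for n in (100, 1000, 10_000):
            table = oa.generate_subject(exp1_spec, "identity", late_observer, n, seed=81)
            ci = oa.bootstrap_ci(table, "RMSE", 400, seed=2)
            widths.append(ci.upper - ci.lower)
        assert widths[0] > widths[1] > widths[2]

    def test_small_n_boot_warns(self, exp1_spec, late_observer):
        table = oa.generate_subject(exp1_spec, "identity", late_observer, 200, seed=82)
        with pytest.warns(UserWarning, match="small"):
            oa.bootstrap_ci(table, "BIAS", 50, seed=3)

    def test_coverage_of_long_run_rmse(self, exp1_spec, late_observer):
        """95% basic-bootstrap CI for RMSE covers the long-run RMSE in
        roughly 95% of replicate experiments (accept 88-99.5%)."""
        long_run = oa.summarize(
            oa.generate_subject(exp1_spec, "identity", late_observer, 150_000, seed=83)
        ).rmse
        hits = 0
        n_rep = 120
        for rep in range(n_rep):
            table = oa.generate_subject(exp1_spec, "identity", late_observer, 400, seed=[84, rep])
            ci = oa.bootstrap_ci(table, "RMSE", 400, seed=[85, rep])
            hits += ci.lower <= long_run <= ci.upper
        assert 0.88 <= hits / n_rep <= 0.995


class TestNullPrediction:
    def test_identity_gain_is_identity(self, cell_table_factory):
        stats = oa.summarize(cell_table_factory({c: [c + 3 - 4, c + 3, c + 3 + 4] for c in (700.0, 900.0)}))
        pred = oa.predict_h0(stats, Transform("gain", 1.0))
        assert (pred.bias, pred.sqrt_var, pred.rmse) == (stats.bias, stats.sqrt_var, stats.rmse)

    def test_gain_scales_all_three(self, cell_table_factory):
        stats = oa.summarize(cell_table_factory({c: [c + 3 - 4, c + 3, c + 3 + 4] for c in (700.0, 900.0)}))
        pred = oa.predict_h0(stats, Transform("gain", 1.5))
        assert pred.bias == pytest.approx(4.5)
        assert pred.sqrt_var == pytest.approx(6.0)
        assert pred.rmse == pytest.approx(7.5)
        assert pred.rmse**2 == pytest.approx(pred.bias**2 + pred.sqrt_var**2)

    def test_rotation_prediction_unchanged(self, cell_table_factory):
        # additive remapping with additive noise: the no-MTN prediction equals
        # the identity-context statistics (e.g. BIAS 0.72 deg stays 0.72 deg)
        cells = {a: [a + 0.72 + d for d in (-0.5, 0.0, 0.5)] for a in (-10.0, 10.0)}
        stats = oa.summarize(cell_table_factory(cells, units="deg_angle"))
        pred = oa.predict_h0(stats, Transform("offset", 60.0))
        assert pred.bias == pytest.approx(stats.bias)
        assert pred.rmse == pytest.approx(stats.rmse)


class TestExcessBias:
    def test_zero_for_matching_stats(self, cell_table_factory):
        stats = oa.summarize(cell_table_factory({c: [c - 4, c, c + 4] for c in (700.0, 900.0)}))
        ex = oa.excess_bias(stats, stats)
        assert all(v == 0.0 for v in ex.values())

    @pytest.mark.parametrize("strategy", ["late", "early"])
    def test_mtn_signature_by_strategy(self, strategy, interval_prior):
        """Extra MTN shows up as excess BIAS under late inference but as
        excess sqrt(VAR) (with little excess BIAS) under early inference."""
        base_pre, base_post, mtn = 0.10, 0.06, 0.12
        gain = Transform("gain", 1.5)
        if strategy == "late":
            ident = oa.ObserverParams("late", oa.NoiseModel("scalar", base_pre), oa.NoiseModel("scalar", base_post))
            remap = oa.ObserverParams("late", oa.NoiseModel("scalar", base_pre).combined(mtn), oa.NoiseModel("scalar", base_post))
        else:
            ident = oa.ObserverParams("early", oa.NoiseModel("scalar", base_pre), oa.NoiseModel("scalar", base_post))
            remap = oa.ObserverParams("early", oa.NoiseModel("scalar", base_pre), oa.NoiseModel("scalar", base_post).combined(mtn))
        s_ident = oa.summarize(
            oa.simulate_trials(ident, Transform("gain", 1.0), interval_prior, 50_000, seed=86, context="identity")
        )
        s_remap = oa.summarize(
            oa.simulate_trials(remap, gain, interval_prior, 50_000, seed=87, context="identity")
        )
        ex = oa.excess_bias(s_remap, oa.predict_h0(s_ident, gain))
        if strategy == "late":
            assert ex["excess_bias"] > 20.0  # ms
        else:
            assert ex["excess_sqrt_var"] > 20.0
            assert abs(ex["excess_bias"]) < 0.3 * ex["excess_sqrt_var"]


class TestDPrime:
    def test_definitional_value(self, cell_table_factory):
        # means 0 and 1 with pooled SD 1 -> d' = 1
        cells = {600.0: [-1.0, 0.0, 1.0], 1000.0: [0.0, 1.0, 2.0]}
        assert oa.d_prime(cell_table_factory(cells)) == pytest.approx(1.0)

    def test_identical_extreme_distributions(self, cell_table_factory):
        cells = {600.0: [1.0, 2.0, 3.0], 1000.0: [1.0, 2.0, 3.0]}
        assert oa.d_prime(cell_table_factory(cells)) == 0.0

    def test_noise_free_table_diverges(self, cell_table_factory):
        cells = {600.0: [600.0, 600.0], 1000.0: [1000.0, 1000.0]}
        assert oa.d_prime(cell_table_factory(cells)) == np.inf


class TestSignedRank:
    def test_exact_p_for_eleven_consistent_pairs(self):
        pairs = [(i * 10.0, i * 10.0 + 5.0) for i in range(1, 12)]
        res = oa.signed_rank_test(pairs)
        assert res["two_sided_p"] == pytest.approx(2.0 / 2**11, rel=1e-9)

    def test_symmetric_differences_give_p_one(self):
        pairs = [(0.0, 1.0), (0.0, -1.0), (0.0, 2.0), (0.0, -2.0), (0.0, 3.0), (0.0, -3.0)]
        assert oa.signed_rank_test(pairs)["two_sided_p"] == pytest.approx(1.0)

    def test_single_sign_flip_increases_p(self):
        consistent = [(0.0, float(i)) for i in range(1, 9)]
        flipped = consistent[:-1] + [(0.0, -8.0)]
        assert (
            oa.signed_rank_test(flipped)["two_sided_p"]
            > oa.signed_rank_test(consistent)["two_sided_p"]
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            oa.signed_rank_test([(0.0, 1.0)] * 4)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            oa.signed_rank_test([(1.0, 1.0)] * 6)
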