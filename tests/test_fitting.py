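"""Curve fitting, identifiability, metrics and bias compensation."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from timingpriors.fitting import (
    DEFAULT_ONE_PRIOR_INIT,
    DEFAULT_TWO_PRIOR_INIT,
    TwoPriorFit,
    compensate_undershoot,
    eval_metrics,
    fit_one_prior,
    fit_two_prior,
    per_participant_metrics,
    readjust_mu_hat,
)
from timingpriors.observer import DegenerateCurveError, predict_from_ratio
from timingpriors.preprocess import grand_average, preprocess
from timingpriors.pipeline import PipelineConfig, simulate_trials

from conftest import TS_ALL, TS_LONG, TS_SHORT, curve_points

R_TRUE = 237.0 / 0.15


def make_fit(mu_short, mu_long, r_short=R_TRUE, r_long=R_TRUE, w=0.15):
    return TwoPriorFit(
        mu_short=mu_short,
        mu_long=mu_long,
        sigma_short=r_short * w,
        sigma_long=r_long * w,
        w=w,
        r_short=r_short,
        r_long=r_long,
        rss=0.0,
        n_points=10,
        converged=True,
        init=DEFAULT_TWO_PRIOR_INIT,
        at_bound=False,
    )


class TestFitTwoPrior:
    def test_noise_free_recovery(self):
        points = curve_points(750.0, 1500.0, R_TRUE, R_TRUE)
        fit = fit_two_prior(points)
        assert fit.mu_short == pytest.approx(750.0, abs=0.01)
        assert fit.mu_long == pytest.approx(1500.0, abs=0.01)
        assert fit.rss == pytest.approx(0.0, abs=1e-6)
        assert fit.converged

    def test_nests_one_prior_case(self):
        points = curve_points(1125.0, 1125.0, 454.0 / 0.15, 454.0 / 0.15)
        fit = fit_two_prior(points)
        assert fit.mu_short == pytest.approx(1125.0, abs=1.0)
        assert fit.mu_long == pytest.approx(1125.0, abs=1.0)

    def test_init_invariance_of_identified_parameters(self):
        rng = np.random.default_rng(3)
        points = curve_points(780.0, 1450.0, 1400.0, 1700.0, noise=15.0, rng=rng)
        ref = fit_two_prior(points)
        for mu_s0 in (600.0, 900.0):
            for w0 in (0.05, 0.4):
                alt = fit_two_prior(points, init=(mu_s0, 1500.0, 237.0, 237.0, w0))
                assert alt.mu_short == pytest.approx(ref.mu_short, abs=1e-6)
                assert alt.mu_long == pytest.approx(ref.mu_long, abs=1e-6)
                assert alt.rss == pytest.approx(ref.rss, rel=1e-9, abs=1e-9)
        # nominal sigma/w are NOT init-invariant: they rescale with init w
        alt = fit_two_prior(points, init=(750.0, 1500.0, 237.0, 237.0, 0.3))
        assert alt.sigma_short == pytest.approx(2 * ref.sigma_short, rel=1e-9)
        assert alt.w == 0.3

    def test_unity_line_data_not_identifiable(self):
        points = pd.DataFrame(
            {
                "prior_label": ["short"] * 5 + ["long"] * 5,
                "t_s": TS_ALL,
                "t_r_mean": TS_ALL,
            }
        )
        with pytest.raises(DegenerateCurveError):
            fit_two_prior(points)

    def test_requires_two_distinct_ts_per_branch(self):
        points = pd.DataFrame(
            {
                "prior_label": ["short", "short", "long", "long"],
                "t_s": [750.0, 750.0, 1500.0, 1650.0],
                "t_r_mean": [800.0, 820.0, 1400.0, 1500.0],
            }
        )
        with pytest.raises(ValueError, match="distinct"):
            fit_two_prior(points)


class TestFitOnePrior:
    def test_noise_free_recovery(self):
        y = predict_from_ratio(TS_ALL, 1125.0, 454.0 / 0.15)
        points = pd.DataFrame(
            {"prior_label": ["short"] * 5 + ["long"] * 5, "t_s": TS_ALL, "t_r_mean": y}
        )
        fit = fit_one_prior(points)
        assert fit.mu_wide == pytest.approx(1125.0, abs=0.01)
        assert fit.rss == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_nested_models_rss_ordering(self, seed):
        rng = np.random.default_rng(seed)
        points = curve_points(
            rng.uniform(600, 900),
            rng.uniform(1300, 1700),
            rng.uniform(800, 3000),
            rng.uniform(800, 3000),
            noise=rng.uniform(5, 40),
            rng=rng,
        )
        assert fit_one_prior(points).rss >= fit_two_prior(points).rss - 1e-6

    def test_two_prior_data_fits_worse_under_one_prior(self):
        points = curve_points(750.0, 1500.0, R_TRUE, R_TRUE)
        assert fit_one_prior(points).rss > fit_two_prior(points).rss + 1.0


class TestEvalMetrics:
    def test_separated_priors_diverge_at_mpriors(self):
        m = eval_metrics(make_fit(750.0, 1500.0, 1580.0, 1580.0))
        assert m.t_r_at_mpriors_short < m.t_r_at_mpriors_long
        assert m.delta_mu_hat == pytest.approx(750.0)
        # direct curve evaluation at 1125 ms on both branches
        assert m.t_r_at_mpriors_short == pytest.approx(
            float(predict_from_ratio(1125.0, 750.0, 1580.0))
        )
        assert m.t_r_at_mpriors_long == pytest.approx(
            float(predict_from_ratio(1125.0, 1500.0, 1580.0))
        )

    def test_generalized_prior_deltas_vanish(self):
        m = eval_metrics(make_fit(1125.0, 1125.0))
        assert m.delta_t_r_at_mpriors == 0.0
        assert m.delta_mu_hat == 0.0

    def test_wildly_negative_mu_flagged_irregular(self):
        m = eval_metrics(make_fit(-50635.5, 1500.0))
        assert m.irregular_short and not m.irregular_long

    def test_mu_hat_equals_unity_intersection(self):
        from timingpriors.observer import ObserverCurveParams, unity_intersection

        fit = make_fit(812.5, 1433.0)
        m = eval_metrics(fit)
        assert m.mu_hat_short == unity_intersection(
            ObserverCurveParams(fit.mu_short, fit.sigma_short, fit.w)
        )

    def test_requires_converged_fit(self):
        with pytest.raises(ValueError, match="converged"):
            eval_metrics(replace(make_fit(750.0, 1500.0), converged=False))


class TestBiasCompensation:
    def _grand_bin(self, offset=0.0):
        return pd.DataFrame(
            {
                "bin": 1,
                "prior_label": ["short"] * 5 + ["long"] * 5,
                "t_s": TS_ALL,
                "t_r_mean": TS_ALL + offset,
            }
        )

    def test_zero_bias_identity(self):
        comp = compensate_undershoot(self._grand_bin())
        assert comp.bias == pytest.approx(0.0)
        assert np.allclose(comp.adjusted["t_r_mean"], TS_ALL)

    def test_constant_undershoot_recovered(self):
        comp = compensate_undershoot(self._grand_bin(offset=-50.0))
        assert comp.bias == pytest.approx(-50.0)
        assert np.allclose(comp.adjusted["t_r_mean"], TS_ALL)

    def test_simulated_undershoot_cohort(self):
        # cohort generated with a -48 ms constant motor bias; the measured
        # systematic undershoot also contains the curves' central-tendency
        # offset, so compare against a matched cohort without the bias
        from dataclasses import replace as dc_replace

        from timingpriors.cohort import CohortConfig

        base = CohortConfig()
        cfg_bias = PipelineConfig(seed=21, cohort=dc_replace(base, bias=(-48.0, 10.0)))
        cfg_zero = PipelineConfig(seed=21, cohort=base)
        biased, _, _ = simulate_trials(cfg_bias)
        clean, _, _ = simulate_trials(cfg_zero)
        _, _, grand_b = preprocess(biased)
        _, _, grand_c = preprocess(clean)
        measured = compensate_undershoot(grand_b[grand_b["bin"] == 1]).bias
        offset = compensate_undershoot(grand_c[grand_c["bin"] == 1]).bias
        assert measured - offset == pytest.approx(-48.0, abs=10.0)


class TestReadjustMuHat:
    def test_identical_fits_identity(self):
        fit = make_fit(750.0, 1500.0)
        adj_s, adj_l = readjust_mu_hat(fit, fit)
        assert (adj_s, adj_l) == (750.0, 1500.0)

    def test_long_prior_anchored_to_original(self):
        original = make_fit(-300.0, 1450.0)
        subtracted = make_fit(1224.0, 1450.0 + 218.5)
        adj_s, adj_l = readjust_mu_hat(original, subtracted)
        assert adj_l == pytest.approx(original.mu_long)
        assert adj_s == pytest.approx(1224.0 - 218.5)

    def test_known_constant_bias_roundtrip(self):
        # generate curves, shift by a constant bias, fit both versions:
        # the readjusted pair should sit near the generating means
        bias = -48.0
        clean = curve_points(750.0, 1500.0, R_TRUE, R_TRUE)
        shifted = clean.copy()
        shifted["t_r_mean"] += bias
        fit_orig = fit_two_prior(shifted)
        comp = compensate_undershoot(shifted)
        # the estimate includes the curves' own shrinkage offset on top of
        # the added constant
        curve_offset = (clean["t_r_mean"] - clean["t_s"]).mean()
        assert comp.bias == pytest.approx(bias + curve_offset, abs=1e-9)
        fit_sub = fit_two_prior(comp.adjusted)
        adj_s, adj_l = readjust_mu_hat(fit_orig, fit_sub)
        assert adj_l == pytest.approx(fit_orig.mu_long)
        assert abs(adj_s - 750.0) < abs(fit_orig.mu_short - 750.0) + 1e-9

    def test_irregular_long_prior_rejected(self):
        with pytest.raises(ValueError, match="irregular"):
            readjust_mu_hat(make_fit(750.0, 25_000.0), make_fit(750.0, 1500.0))


class TestParameterRecoveryFromSimulation:
    def test_grand_average_fits_recover_generating_means(self, independent_cohort_run):
        _, _, grand = independent_cohort_run
        for b in (1, 2):
            fit = fit_two_prior(grand[grand["bin"] == b])
            assert fit.mu_short == pytest.approx(750.0, abs=50.0)
            assert fit.mu_long == pytest.approx(1500.0, abs=50.0)

    def test_per_participant_metrics_table(self, independent_cohort_run):
        _, binned, _ = independent_cohort_run
        table = per_participant_metrics(binned)
        assert len(table) == 40  # 20 participants x 2 bins
        assert (table["delta_t_r_at_mpriors"] > 0).mean() > 0.9
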