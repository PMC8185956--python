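"""Tests for the Bayesian calibration layer: prior, likelihood, sampler."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, uniform

from baycann.calibrate import (BayesianCalibration, CalibrationTargets,
                               PosteriorDraws, log_likelihood, log_prior,
                               map_estimate, posterior_predictive,
                               posterior_summary, sample_posterior)
from baycann.emulator import AnnEmulator, ScalingSpec, ann_forward


def _targets_from_network(weights, scaling, theta_scaled, sigma):
    """Targets generated by the network itself at a known scaled point."""
    y = scaling.unscale_outputs(ann_forward(weights, theta_scaled))
    return CalibrationTargets.from_arrays(y, np.full(len(y), sigma))


class TestLogPrior:
    def test_interior_boundary_and_outside(self):
        assert log_prior(np.zeros(9)) == 0.0
        edge = np.zeros(9)
        edge[3] = 1.0
        assert log_prior(edge) == 0.0  # closed box includes the boundary
        outside = np.zeros(9)
        outside[3] = 1.0001
        assert log_prior(outside) == -np.inf


class TestLogLikelihood:
    def test_maximum_at_exact_fit(self, tiny_network):
        w, sc = tiny_network
        theta = np.full(9, 0.2)
        tg = _targets_from_network(w, sc, theta, sigma=0.03)
        expected = -np.sum(np.log(tg.sigma * math.sqrt(2 * math.pi)))
        assert log_likelihood(theta, tg, w, sc) == pytest.approx(expected,
                                                                 abs=1e-10)

    def test_one_sigma_miss_drops_half(self, tiny_network):
        w, sc = tiny_network
        theta = np.full(9, -0.1)
        tg = _targets_from_network(w, sc, theta, sigma=0.05)
        at_max = log_likelihood(theta, tg, w, sc)
        tg.table.loc[0, "mean"] += tg.table.loc[0, "se"]  # one-sigma shift
        assert log_likelihood(theta, tg, w, sc) == pytest.approx(
            at_max - 0.5, abs=1e-10)

    def test_matches_naive_per_term_oracle(self, tiny_network):
        w, sc = tiny_network
        rng = np.random.default_rng(4)
        tg = _targets_from_network(w, sc, rng.uniform(-0.5, 0.5, 9), 0.04)
        tg.table["se"] = rng.uniform(0.01, 0.1, len(tg))
        for _ in range(5):
            theta = rng.uniform(-0.9, 0.9, 9)
            phi = sc.unscale_outputs(ann_forward(w, theta))
            naive = sum(
                -0.5 * math.log(2 * math.pi) - math.log(s)
                - 0.5 * ((yv - pv) / s) ** 2
                for yv, pv, s in zip(tg.y, phi, tg.sigma))
            assert log_likelihood(theta, tg, w, sc) == pytest.approx(
                naive, abs=1e-10)

    def test_nonpositive_sigma_rejected(self, tiny_network):
        w, sc = tiny_network
        tg = _targets_from_network(w, sc, np.zeros(9), 0.05)
        tg.table.loc[5, "se"] = 0.0
        with pytest.raises(ValueError):
            CalibrationTargets(tg.table)


class TestTargets:
    def test_reorders_to_canonical_order(self, tiny_network):
        w, sc = tiny_network
        tg = _targets_from_network(w, sc, np.zeros(9), 0.02)
        shuffled = tg.table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        again = CalibrationTargets(shuffled)
        assert np.allclose(again.y, tg.y)

    def test_wrong_row_count_rejected(self, tiny_network):
        w, sc = tiny_network
        tg = _targets_from_network(w, sc, np.zeros(9), 0.02)
        with pytest.raises(ValueError):
            CalibrationTargets(tg.table.iloc[:-1])

    def test_csv_roundtrip(self, tiny_network, tmp_path):
        w, sc = tiny_network
        tg = _targets_from_network(w, sc, np.full(9, 0.3), 0.02)
        tg.to_csv(tmp_path / "t.csv")
        again = CalibrationTargets.from_csv(tmp_path / "t.csv")
        assert np.allclose(again.y, tg.y) and np.allclose(again.sigma, tg.sigma)


class TestSampler:
    def test_flat_likelihood_reproduces_uniform_prior(self, tiny_network, priors):
        """With target uncertainties inflated to irrelevance the posterior
        must collapse to the uniform prior on every natural-unit margin
        (Kolmogorov-Smirnov distance below 0.05), including the log-mapped
        scale parameter whose prior-density correction this exercises."""
        w, _ = tiny_network
        sc = ScalingSpec.fit(priors, np.random.default_rng(0).random((20, 36)))
        sc = ScalingSpec(sc.in_lower, sc.in_upper, np.zeros(36), np.ones(36),
                         sc.in_log)
        assert sc.in_log.any()  # the Weibull scale spans a decade
        tg = _targets_from_network(w, sc, np.zeros(9), sigma=1e6)
        draws = sample_posterior(tg, w, sc, priors, n_draws=10000,
                                 n_chains=2, n_warmup=400, seed=77)
        assert len(draws) == 10000
        X = draws.values
        assert priors.contains(X).all()
        for j, name in enumerate(priors.names):
            lo, hi = priors.bounds[name]
            ks = kstest(X[:, j], uniform(loc=lo, scale=hi - lo).cdf).statistic
            assert ks < 0.05, f"KS({name}) = {ks:.3f}"

    def test_recovers_generating_point_self_consistently(self, tiny_network,
                                                         priors):
        """Targets produced by the emulator at a known interior point must be
        recovered within 3 posterior SDs on every parameter."""
        w, sc = tiny_network
        rng = np.random.default_rng(123)
        theta_star = rng.uniform(-0.6, 0.6, 9)
        tg = _targets_from_network(w, sc, theta_star, sigma=0.01)
        draws = sample_posterior(tg, w, sc, priors, n_draws=2000,
                                 n_chains=2, n_warmup=400, seed=9)
        Z = sc.scale_inputs(draws.values)
        dist = np.abs(Z.mean(axis=0) - theta_star) / Z.std(axis=0)
        assert np.all(dist < 3.0)
        assert draws.diagnostics is not None
        assert "rhat" in draws.diagnostics

    def test_same_seed_gives_identical_draws(self, tiny_network, priors):
        w, sc = tiny_network
        tg = _targets_from_network(w, sc, np.zeros(9), sigma=0.1)
        a = sample_posterior(tg, w, sc, priors, n_draws=200, n_chains=2,
                             n_warmup=100, seed=31)
        b = sample_posterior(tg, w, sc, priors, n_draws=200, n_chains=2,
                             n_warmup=100, seed=31)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.log_posterior, b.log_posterior)


class TestMapAndSummary:
    def _draws(self, lp):
        n = len(lp)
        X = pd.DataFrame(np.arange(n * 2, dtype=float).reshape(n, 2),
                         columns=["a", "b"])
        return PosteriorDraws(X, np.asarray(lp, dtype=float),
                              np.zeros(n, dtype=int), np.arange(n))

    def test_map_is_bruteforce_argmax(self):
        rng = np.random.default_rng(6)
        lp = rng.normal(size=50)
        draws = self._draws(lp)
        best = max(range(50), key=lambda i: lp[i])  # linear-scan oracle
        assert draws.map_index == best
        assert np.array_equal(map_estimate(draws), draws.values[best])

    def test_single_draw_and_tie_rules(self):
        assert self._draws([1.5]).map_index == 0
        tied = self._draws([2.0, 1.0, 2.0])
        assert tied.map_index == 0  # first of two equal maxima

    def test_draws_csv_roundtrip_preserves_method_tag(self, tmp_path):
        draws = self._draws([0.5, 1.5, -1.0])
        draws.method = "imis"
        draws.to_csv(tmp_path / "d.csv")
        again = PosteriorDraws.from_csv(tmp_path / "d.csv")
        assert again.method == "imis"
        assert np.array_equal(again.values, draws.values)
        assert np.array_equal(again.log_posterior, draws.log_posterior)

    def test_degenerate_draws_give_zero_width_covered_intervals(self):
        X = pd.DataFrame(np.tile([1.0, 2.0], (10, 1)), columns=["a", "b"])
        draws = PosteriorDraws(X, np.zeros(10), np.zeros(10, dtype=int),
                               np.arange(10))
        summary, corr = posterior_summary(draws, truth=np.array([1.0, 2.0]))
        assert np.allclose(summary["ci_lo"], summary["ci_hi"])
        assert summary["covered"].all()
        assert np.allclose(corr, corr.T) and np.allclose(np.diag(corr), 1.0)

    def test_correlation_matrix_properties(self, tiny_network, priors):
        w, sc = tiny_network
        tg = _targets_from_network(w, sc, np.full(9, 0.1), sigma=0.05)
        draws = sample_posterior(tg, w, sc, priors, n_draws=500, n_chains=2,
                                 n_warmup=200, seed=2)
        _, corr = posterior_summary(draws)
        C = corr.to_numpy()
        assert np.allclose(C, C.T) and np.allclose(np.diag(C), 1.0)
        off = np.abs(C[np.triu_indices(9, 1)])
        assert off.max() <= 1.0


class TestPosteriorPredictive:
    def test_single_draw_has_zero_width(self, tiny_network, priors):
        w, sc = tiny_network
        theta = np.full(9, 0.25)
        tg = _targets_from_network(w, sc, theta, 0.05)
        X = pd.DataFrame(sc.unscale_inputs(theta)[None, :],
                         columns=priors.names)
        draws = PosteriorDraws(X, np.zeros(1), np.zeros(1, dtype=int),
                               np.zeros(1, dtype=int))
        pp = posterior_predictive(draws, w, sc, n_use=1)
        assert np.allclose(pp["pred_lo"], pp["pred_hi"])
        assert np.allclose(pp["pred_mean"], tg.y, atol=1e-10)

    def test_inflated_target_noise_widens_predictive_intervals(
            self, tiny_network, priors):
        w, sc = tiny_network
        theta_star = np.full(9, -0.2)
        widths = {}
        for label, sigma in (("tight", 0.01), ("loose", 0.3)):
            tg = _targets_from_network(w, sc, theta_star, sigma)
            draws = sample_posterior(tg, w, sc, priors, n_draws=600,
                                     n_chains=2, n_warmup=250, seed=17)
            pp = posterior_predictive(draws, w, sc, n_use=500)
            widths[label] = (pp["pred_hi"] - pp["pred_lo"]).median()
        assert widths["loose"] > widths["tight"]


class TestModelResultsApi:
    def test_fit_returns_results_with_summary(self, tiny_network, priors):
        w, sc = tiny_network
        tg = _targets_from_network(w, sc, np.full(9, 0.1), 0.05)
        emulator = AnnEmulator(w, sc)
        model = BayesianCalibration(tg, emulator, priors)
        res = model.fit(n_draws=400, n_chains=2, n_warmup=150, seed=3)
        table = res.summary(truth=sc.unscale_inputs(np.full(9, 0.1)))
        assert set(["mean", "ci_lo", "ci_hi", "map", "covered"]) <= set(table.columns)
        assert len(res.map_estimate) == 9
        assert model.log_posterior(np.full(9, 2.0)) == -np.inf
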