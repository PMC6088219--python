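import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import linprog

from latentq.qsem import (
    McmcSettings,
    QSemSpec,
    _sample_invgauss,
    fit_all_quantiles,
    gibbs_fit,
)


def lp_quantile_regression(design: np.ndarray, y: np.ndarray, tau: float) -> np.ndarray:
    """Exact check-loss minimizer via linear programming (oracle)."""
    n, k = design.shape
    c = np.concatenate([np.zeros(2 * k), tau * np.ones(n), (1 - tau) * np.ones(n)])
    a_eq = np.hstack([design, -design, np.eye(n), -np.eye(n)])
    res = linprog(
        c, A_eq=a_eq, b_eq=y, bounds=[(0, None)] * (2 * k + 2 * n), method="highs"
    )
    assert res.status == 0
    return res.x[:k] - res.x[k : 2 * k]


class TestSpecValidation:
    def test_bad_quantile_rejected(self):
        with pytest.raises(ValueError):
            QSemSpec(["a"], ["b"], ["c"], quantiles=(0.0, 0.5))

    def test_empty_factor_rejected(self):
        with pytest.raises(ValueError):
            QSemSpec([], ["b"], ["c"])

    def test_anchor_rows(self):
        spec = QSemSpec(["a", "b"], ["c", "d", "e"], ["f"])
        assert spec.anchor_rows.tolist() == [0, 2, 5]
        assert spec.factor_of.tolist() == [0, 0, 1, 1, 1, 2]

    def test_burn_in_validation(self):
        with pytest.raises(ValueError):
            McmcSettings(iterations=100, burn_in=100)

    def test_bad_tau_rejected(self, data_small, latent_spec):
        ind, cov, _ = data_small
        with pytest.raises(ValueError):
            gibbs_fit(ind, cov, latent_spec, 1.2)

    def test_missing_columns_rejected(self, latent_spec):
        with pytest.raises(ValueError, match="absent"):
            gibbs_fit(pd.DataFrame({"x": [1.0]}), None, latent_spec, 0.5)


class TestInverseGaussianSampler:
    @pytest.mark.parametrize("mu,lam", [(0.5, 1.0), (2.0, 3.0), (1.0, 0.2)])
    def test_moments(self, mu, lam, rng):
        draws = _sample_invgauss(np.full(200000, mu), lam, rng)
        assert draws.mean() == pytest.approx(mu, rel=0.02)
        assert draws.var() == pytest.approx(mu**3 / lam, rel=0.05)

    def test_distribution_matches_scipy(self, rng):
        mu, lam = 1.3, 2.1
        draws = _sample_invgauss(np.full(50000, mu), lam, rng)
        ks = stats.kstest(draws, stats.invgauss(mu / lam, scale=lam).cdf)
        assert ks.pvalue > 0.001


class TestObservedModeQuantileRegression:
    """Degenerate measurement model = Bayesian quantile regression."""

    @pytest.mark.parametrize("tau", [0.25, 0.5, 0.75])
    def test_posterior_median_matches_lp_oracle(self, observed_qr_data, tau):
        ind, cov, design, y = observed_qr_data
        spec = QSemSpec(
            ["eta_obs"],
            ["xi1_obs"],
            ["xi2_obs"],
            covariates=["const", "x1", "x2"],
            observed_factors=True,
            standardize=False,
        )
        fit = gibbs_fit(
            ind,
            cov,
            spec,
            tau,
            McmcSettings(chains=2, iterations=3000, burn_in=1000, seed=5),
        )
        beta_lp = lp_quantile_regression(design, y, tau)
        names = ["gamma_socioeconomic", "gamma_personal", "b_const", "b_x1", "b_x2"]
        post_median = fit.summary.loc[names, "median"].to_numpy()
        assert np.max(np.abs(post_median - beta_lp)) < 0.06

    def test_residual_fraction_tracks_tau(self, observed_qr_data):
        ind, cov, _, _ = observed_qr_data
        spec = QSemSpec(
            ["eta_obs"],
            ["xi1_obs"],
            ["xi2_obs"],
            covariates=["const", "x1", "x2"],
            observed_factors=True,
            standardize=False,
        )
        fit = gibbs_fit(
            ind, cov, spec, 0.25,
            McmcSettings(chains=1, iterations=1500, burn_in=500, seed=8),
        )
        assert fit.resid_negative_fraction == pytest.approx(0.25, abs=0.04)


class TestGibbsLatent:
    def test_determinism_same_seed(self, data_small, latent_spec):
        ind, cov, _ = data_small
        mcmc = McmcSettings(chains=1, iterations=250, burn_in=100, seed=17)
        a = gibbs_fit(ind.head(150), cov.head(150), latent_spec, 0.5, mcmc)
        b = gibbs_fit(ind.head(150), cov.head(150), latent_spec, 0.5, mcmc)
        for key in a.draws:
            assert np.array_equal(a.draws[key], b.draws[key])
        c = gibbs_fit(
            ind.head(150), cov.head(150), latent_spec, 0.5,
            dataclasses.replace(mcmc, seed=18),
        )
        assert not np.array_equal(a.draws["gamma"], c.draws["gamma"])

    def test_gamma_recovery_and_anchor_scale(self, median_fit, truth_small):
        g = median_fit.summary.loc[
            ["gamma_socioeconomic", "gamma_personal"], "mean"
        ].to_numpy()
        assert np.max(np.abs(g - truth_small.gamma)) < 0.2
        # anchors reported on the raw indicator scale are exactly 1
        lam_draws = median_fit.draws["lambda"]
        anchors = median_fit.spec.anchor_rows
        assert np.allclose(lam_draws[:, :, anchors], 1.0)

    def test_profile_loadings_positive_sign(self, median_fit):
        lam = median_fit.summary.loc[
            [f"lambda_{c}" for c in median_fit.spec.eta_indicators], "mean"
        ]
        assert (lam > 0).all()

    def test_residual_fraction_near_tau(self, median_fit):
        assert median_fit.resid_negative_fraction == pytest.approx(0.5, abs=0.03)

    def test_significance_flag_matches_interval(self, median_fit):
        s = median_fit.summary
        expected = (s["ci_2.5"] > 0) | (s["ci_97.5"] < 0)
        assert (s["significant"] == expected).all()

    def test_psi_and_phi_positive(self, median_fit):
        assert (median_fit.draws["psi"] > 0).all()
        phi = median_fit.draws["phi"]
        assert (phi[:, :, 0] > 0).all() and (phi[:, :, 2] > 0).all()

    def test_fix_gamma_holds_values(self, data_small):
        ind, cov, _ = data_small
        spec = QSemSpec(
            ["ghq12_distress", "hads_anxiety", "hads_depression"],
            ["financial", "social_relations", "personal_conflict", "job_conflicts",
             "educational", "job_security", "daily_life"],
            ["home_life", "loss_and_separation", "sexual_life", "health_concerns"],
            covariates=list(cov.columns),
            fix_gamma=(0.0, 0.0),
        )
        fit = gibbs_fit(
            ind.head(300), cov.head(300), spec, 0.5,
            McmcSettings(chains=1, iterations=300, burn_in=100, seed=4),
        )
        assert np.all(fit.draws["gamma"] == 0.0)


class TestFitAllQuantiles:
    def test_single_tau_consistent_with_gibbs_fit(self, data_small, latent_spec):
        ind, cov, _ = data_small
        spec = dataclasses.replace(latent_spec, quantiles=(0.5,))
        mcmc = McmcSettings(chains=1, iterations=400, burn_in=150, seed=31)
        grid = fit_all_quantiles(ind.head(250), cov.head(250), spec, mcmc)
        single = gibbs_fit(ind.head(250), cov.head(250), spec, 0.5, mcmc)
        pd.testing.assert_frame_equal(
            grid.fits[0.5].summary, single.summary
        )
        assert set(grid.coefficient_grid["tau"]) == {0.5}

    def test_location_shift_truth_gives_flat_gamma(self):
        """With symmetric iid structural errors the quantile coefficient
        path is flat; estimates at the three quartile levels agree."""
        from latentq.synthetic import default_truth, generate_dataset

        t = default_truth(n=1200, seed=55, error_family="normal")
        ind, cov, _ = generate_dataset(t)
        spec = QSemSpec(
            ["ghq12_distress", "hads_anxiety", "hads_depression"],
            ["financial", "social_relations", "personal_conflict", "job_conflicts",
             "educational", "job_security", "daily_life"],
            ["home_life", "loss_and_separation", "sexual_life", "health_concerns"],
            covariates=list(cov.columns),
            quantiles=(0.25, 0.5, 0.75),
        )
        mcmc = McmcSettings(chains=1, iterations=1200, burn_in=500, seed=77)
        grid = fit_all_quantiles(ind, cov, spec, mcmc)
        g = grid.coefficient_grid
        for name in ("gamma_socioeconomic", "gamma_personal"):
            means = g.loc[g["parameter"] == name, "mean"].to_numpy()
            assert means.max() - means.min() < 0.25
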