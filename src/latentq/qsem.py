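"""Bayesian quantile structural equation model via Gibbs sampling.

Model.  For participant i with indicator vector y_i (p = 14 by default)
and fixed covariates x_i:

    measurement:  y_i = mu + Lambda omega_i + eps_i,  eps_i ~ N(0, Psi)
    structural:   eta_i = b' x_i + gamma' xi_i + delta_i,
                  delta_i ~ ALD(tau, sigma)

with omega_i = (eta_i, xi_i1, xi_i2), block-sparse loadings Lambda whose
first indicator per factor is anchored at 1, diagonal Psi, and latent
predictor covariance xi_i ~ N(0, Phi).  Because the asymmetric Laplace
density has its tau-quantile at zero, the structural part is a quantile
regression of the latent response on the latent predictors.

Sampling.  The ALD is augmented as delta = k1 e + k2 sqrt(sigma e) z
with e ~ Exponential(mean sigma), which makes every full conditional
standard: e_i is generalized inverse Gaussian (lambda = 1/2, sampled
exactly through the reciprocal inverse-Gaussian identity), omega_i is
trivariate normal, measurement rows and structural coefficients are
conjugate normal, Psi_jj and sigma are inverse gamma, Phi is inverse
Wishart.  Each quantile level is fitted independently; crossing of
fitted quantile curves is reported as a diagnostic, not prevented.

Indicators (and covariates) are standardized internally to stabilize
the weakly informative priors; all reported parameters are rescaled
back to the original indicator scale, on which the anchor loadings are
again exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from latentq.ald import AldParams

__all__ = [
    "PriorSpec",
    "McmcSettings",
    "QSemSpec",
    "QSemFit",
    "QuantileGrid",
    "gibbs_fit",
    "fit_all_quantiles",
]


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative defaults; the source analysis states none."""

    loading_var: float = 100.0  # N(0, 10^2) on free loadings and intercepts
    coef_var: float = 100.0  # N(0, 10^2) on gamma and b
    psi_a: float = 0.01
    psi_b: float = 0.01
    sigma_a: float = 0.01
    sigma_b: float = 0.01
    phi_df: float = 4.0
    phi_scale: float = 1.0  # Inverse-Wishart(phi_scale * I, phi_df)


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 2
    iterations: int = 6000
    burn_in: int = 2000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")


@dataclass
class QSemSpec:
    """Indicator map, covariates, quantile levels and priors.

    The first indicator listed for each factor is its anchor (loading
    fixed at 1).  With ``observed_factors=True`` the three factors are
    read directly from their anchor columns (the degenerate Psi -> 0
    measurement model) and the sampler reduces to Bayesian quantile
    regression of the observed response on observed predictors plus
    covariates; no standardization is applied in that mode.
    """

    eta_indicators: Sequence[str]
    xi1_indicators: Sequence[str]
    xi2_indicators: Sequence[str]
    covariates: Sequence[str] = ()
    quantiles: Sequence[float] = (0.05, 0.25, 0.50, 0.75, 0.95)
    priors: PriorSpec = field(default_factory=PriorSpec)
    standardize: bool = True
    observed_factors: bool = False
    #: hold gamma fixed at these values instead of sampling it (used for
    #: misspecification experiments, e.g. forcing gamma = 0)
    fix_gamma: Sequence[float] | None = None

    def __post_init__(self) -> None:
        for tau in self.quantiles:
            if not (0.0 < tau < 1.0):
                raise ValueError(f"quantile level {tau} must lie strictly in (0, 1)")
        for name, lst in (
            ("eta", self.eta_indicators),
            ("xi1", self.xi1_indicators),
            ("xi2", self.xi2_indicators),
        ):
            if len(lst) < 1:
                raise ValueError(f"factor {name} needs at least one (anchor) indicator")

    @property
    def indicator_names(self) -> list[str]:
        return list(self.eta_indicators) + list(self.xi1_indicators) + list(
            self.xi2_indicators
        )

    @property
    def factor_of(self) -> np.ndarray:
        return np.array(
            [0] * len(self.eta_indicators)
            + [1] * len(self.xi1_indicators)
            + [2] * len(self.xi2_indicators)
        )

    @property
    def anchor_rows(self) -> np.ndarray:
        n_eta, n_x1 = len(self.eta_indicators), len(self.xi1_indicators)
        return np.array([0, n_eta, n_eta + n_x1])


def _sample_invgauss(mu: np.ndarray, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Vectorized inverse-Gaussian draws (Michael-Schucany-Haas)."""
    nu = rng.standard_normal(mu.shape) ** 2
    x = mu + mu**2 * nu / (2.0 * lam) - mu / (2.0 * lam) * np.sqrt(
        4.0 * mu * lam * nu + (mu * nu) ** 2
    )
    x = np.maximum(x, 1e-300)
    u = rng.random(mu.shape)
    return np.where(u <= mu / (mu + x), x, mu**2 / x)


def _split_rhat(chains: np.ndarray) -> float:
    """Split-R-hat over an array shaped (chains, draws)."""
    m, n = chains.shape
    half = n // 2
    if half < 2:
        return np.nan
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    means = segs.mean(axis=1)
    variances = segs.var(axis=1, ddof=1)
    w = variances.mean()
    b = half * means.var(ddof=1)
    if w <= 0:
        return np.nan
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def _ess(chains: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    m, n = chains.shape
    if n < 4:
        return np.nan
    centered = chains - chains.mean(axis=1, keepdims=True)
    acov = np.empty((m, n))
    for c in range(m):
        fft = np.fft.rfft(np.concatenate([centered[c], np.zeros(n)]))
        ac = np.fft.irfft(fft * np.conj(fft))[:n] / n
        acov[c] = ac
    var = acov[:, 0].mean()
    if var <= 0:
        return np.nan
    rho = acov.mean(axis=0) / var
    total, t = 0.0, 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        total += pair
        t += 2
    ess = m * n / (1.0 + 2.0 * total)
    return float(min(ess, m * n))


@dataclass
class QSemFit:
    """Posterior draws and summaries for one quantile level."""

    tau: float
    draws: dict  # raw-scale draws, arrays shaped (chains, kept[, dim])
    summary: pd.DataFrame
    latent_mean: pd.DataFrame  # posterior mean of (eta, xi1, xi2) per case
    #: posterior expectation of the per-draw fraction of negative
    #: structural residuals; approximately tau when the model fits
    resid_negative_fraction: float
    #: fraction of posterior-MEAN residuals below zero (plug-in variant;
    #: latent-state shrinkage biases this away from tau off the median)
    plugin_resid_negative_fraction: float
    spec: QSemSpec
    mcmc: McmcSettings
    scales: dict  # standardization metadata (m, s, x_mean, x_sd)
    draws_std: dict  # internal-scale draws, reused by predictive checks

    @property
    def structural_names(self) -> list[str]:
        return [n for n in self.summary.index if n.startswith(("gamma_", "b_"))]

    def coefficient_table(self) -> pd.DataFrame:
        tab = self.summary.loc[self.structural_names + ["sigma"]].copy()
        tab.insert(0, "tau", self.tau)
        return tab


def _prepare(indicators: pd.DataFrame, covariates: pd.DataFrame | None, spec: QSemSpec):
    cols = spec.indicator_names
    missing = [c for c in cols if c not in indicators.columns]
    if missing:
        raise ValueError(f"indicator columns absent from data: {missing}")
    y = indicators[cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("indicator table must be complete cases")
    if spec.covariates:
        if covariates is None:
            raise ValueError("spec lists covariates but none were provided")
        x = covariates[list(spec.covariates)].to_numpy(dtype=float)
    else:
        x = np.zeros((y.shape[0], 0))
    if spec.standardize and not spec.observed_factors:
        m, s = y.mean(axis=0), y.std(axis=0)
        if np.any(s == 0):
            raise ValueError("constant indicator column cannot be modelled")
        y = (y - m) / s
        x_mean, x_sd = x.mean(axis=0), x.std(axis=0)
        x_sd = np.where(x_sd == 0, 1.0, x_sd)
        keep_mean = x.std(axis=0) == 0  # leave constants untouched
        x_mean = np.where(keep_mean, 0.0, x_mean)
        x = (x - x_mean) / x_sd
    else:
        m, s = np.zeros(y.shape[1]), np.ones(y.shape[1])
        x_mean, x_sd = np.zeros(x.shape[1]), np.ones(x.shape[1])
    return y, x, {"m": m, "s": s, "x_mean": x_mean, "x_sd": x_sd}


def _run_chain(
    y: np.ndarray,
    x: np.ndarray,
    spec: QSemSpec,
    tau: float,
    mcmc: McmcSettings,
    chain: int,
):
    n, p = y.shape
    q = x.shape[1]
    pri = spec.priors
    params = AldParams(tau, 1.0)
    k1, k2sq = params.k1, params.k2_sq
    rng = np.random.default_rng([mcmc.seed, chain, int(round(tau * 1_000_000))])

    factor_of = spec.factor_of
    anchors = spec.anchor_rows
    is_anchor = np.zeros(p, dtype=bool)
    is_anchor[anchors] = True

    observed = spec.observed_factors
    # --- initial state ---
    if observed:
        omega = y[:, anchors].copy()
    else:
        omega = np.column_stack(
            [y[:, factor_of == f].mean(axis=1) for f in range(3)]
        ) + 0.01 * rng.standard_normal((n, 3))
    mu_vec = y.mean(axis=0).copy()
    lam_col = np.ones(p)  # loading of row j on its own factor
    psi = np.full(p, 0.5 * y.var(axis=0).mean())
    gamma = np.zeros(2)
    b = np.zeros(q)
    sigma = 1.0
    phi = np.eye(2)
    e = rng.exponential(scale=sigma, size=n)

    kept = (mcmc.iterations - mcmc.burn_in) // mcmc.thin
    out = {
        "gamma": np.empty((kept, 2)),
        "b": np.empty((kept, q)),
        "sigma": np.empty(kept),
        "mu": np.empty((kept, p)),
        "lambda": np.empty((kept, p)),
        "psi": np.empty((kept, p)),
        "phi": np.empty((kept, 3)),
    }
    omega_sum = np.zeros((n, 3))
    delta_sum = np.zeros(n)
    sign_frac_sum = 0.0
    n_acc = 0
    eye_coef = np.eye(2 + q) / pri.coef_var

    for it in range(mcmc.iterations):
        eta, xi = omega[:, 0], omega[:, 1:]
        delta = eta - x @ b - xi @ gamma

        # (1) mixing variable e_i | rest : GIG(1/2, chi_i, psi_g)
        chi = np.maximum(delta**2, 1e-12) / (k2sq * sigma)
        psi_g = 1.0 / (2.0 * tau * (1.0 - tau) * sigma)
        v = _sample_invgauss(np.sqrt(psi_g / chi), psi_g, rng)
        e = np.maximum(1.0 / v, 1e-12)
        s2 = k2sq * sigma * e
        c_struct = x @ b + k1 * e

        if not observed:
            # (2) latent states omega_i | rest : trivariate normal
            lam_mat = np.zeros((p, 3))
            lam_mat[np.arange(p), factor_of] = lam_col
            a_mat = lam_mat.T @ (lam_mat / psi[:, None])
            c0 = a_mat.copy()
            phi_inv = np.linalg.inv(phi)
            c0[1:, 1:] += phi_inv
            v_vec = np.array([1.0, -gamma[0], -gamma[1]])
            h = (y - mu_vec) / psi @ lam_mat + (c_struct / s2)[:, None] * v_vec
            q_mat = c0[None, :, :] + (1.0 / s2)[:, None, None] * np.outer(v_vec, v_vec)
            cov = np.linalg.inv(q_mat)
            mean = np.einsum("nij,nj->ni", cov, h)
            chol = np.linalg.cholesky(cov)
            omega = mean + np.einsum(
                "nij,nj->ni", chol, rng.standard_normal((n, 3))
            )
            eta, xi = omega[:, 0], omega[:, 1:]

            # (3) measurement intercepts and free loadings | rest
            for j in range(p):
                t = omega[:, factor_of[j]]
                if is_anchor[j]:
                    resid = y[:, j] - t
                    prec = n / psi[j] + 1.0 / pri.loading_var
                    mean_j = resid.sum() / psi[j] / prec
                    mu_vec[j] = mean_j + rng.standard_normal() / np.sqrt(prec)
                    lam_col[j] = 1.0
                else:
                    st, stt = t.sum(), t @ t
                    prec22 = (
                        np.array([[n, st], [st, stt]]) / psi[j]
                        + np.eye(2) / pri.loading_var
                    )
                    rhs = np.array([y[:, j].sum(), t @ y[:, j]]) / psi[j]
                    chol22 = np.linalg.cholesky(prec22)
                    mean2 = np.linalg.solve(prec22, rhs)
                    draw = mean2 + np.linalg.solve(
                        chol22.T, rng.standard_normal(2)
                    )
                    mu_vec[j], lam_col[j] = draw

            # (4) unique variances Psi_jj | rest
            lam_mat[np.arange(p), factor_of] = lam_col
            resid = y - mu_vec - omega @ lam_mat.T
            ss = (resid**2).sum(axis=0)
            psi = (pri.psi_b + 0.5 * ss) / rng.gamma(pri.psi_a + 0.5 * n, size=p)

        # (5) structural coefficients (gamma, b) | rest
        w = 1.0 / s2
        r_vec = eta - k1 * e
        if spec.fix_gamma is not None:
            gamma = np.asarray(spec.fix_gamma, dtype=float)
            if q:
                r_adj = r_vec - xi @ gamma
                prec = x.T @ (x * w[:, None]) + np.eye(q) / pri.coef_var
                rhs = x.T @ (r_adj * w)
                cholp = np.linalg.cholesky(prec)
                mean_c = np.linalg.solve(prec, rhs)
                b = mean_c + np.linalg.solve(cholp.T, rng.standard_normal(q))
        else:
            z_mat = np.column_stack([xi, x])
            prec = z_mat.T @ (z_mat * w[:, None]) + eye_coef
            rhs = z_mat.T @ (r_vec * w)
            cholp = np.linalg.cholesky(prec)
            mean_c = np.linalg.solve(prec, rhs)
            coef = mean_c + np.linalg.solve(cholp.T, rng.standard_normal(2 + q))
            gamma, b = coef[:2], coef[2:]

        # (6) ALD scale sigma | rest
        delta = eta - x @ b - xi @ gamma
        b_post = (
            pri.sigma_b
            + e.sum()
            + ((delta - k1 * e) ** 2 / (2.0 * k2sq * e)).sum()
        )
        sigma = b_post / rng.gamma(pri.sigma_a + 1.5 * n)

        if not observed:
            # (7) latent-predictor covariance Phi | rest
            scale = pri.phi_scale * np.eye(2) + xi.T @ xi
            phi = stats.invwishart.rvs(
                df=pri.phi_df + n, scale=scale, random_state=rng
            )
            phi = np.atleast_2d(phi)

        if not np.isfinite(sigma) or not np.all(np.isfinite(gamma)):
            raise RuntimeError(f"chain {chain} diverged at iteration {it}")

        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            idx = (it - mcmc.burn_in) // mcmc.thin
            out["gamma"][idx] = gamma
            out["b"][idx] = b
            out["sigma"][idx] = sigma
            out["mu"][idx] = mu_vec
            out["lambda"][idx] = lam_col
            out["psi"][idx] = psi
            out["phi"][idx] = phi[[0, 0, 1], [0, 1, 1]]
            omega_sum += omega
            delta_sum += delta
            sign_frac_sum += np.mean(delta < 0)
            n_acc += 1

    return out, omega_sum / n_acc, delta_sum / n_acc, sign_frac_sum / n_acc


def _to_raw_scale(draws_std: dict, spec: QSemSpec, scales: dict) -> dict:
    """Map standardized-scale draws back to the original indicator scale."""
    s, m = scales["s"], scales["m"]
    anchors = spec.anchor_rows
    factor_of = spec.factor_of
    s_anchor = s[anchors]  # scale of each factor's anchor indicator
    x_sd = scales["x_sd"]
    raw = {}
    raw["lambda"] = draws_std["lambda"] * s[None, None, :] / s_anchor[factor_of][None, None, :]
    raw["mu"] = m[None, None, :] + s[None, None, :] * draws_std["mu"]
    raw["psi"] = draws_std["psi"] * (s**2)[None, None, :]
    raw["gamma"] = draws_std["gamma"] * s_anchor[0] / s_anchor[1:][None, None, :]
    raw["b"] = draws_std["b"] * s_anchor[0] / x_sd[None, None, :]
    raw["sigma"] = draws_std["sigma"] * s_anchor[0]
    pair = s_anchor[[1, 1, 2]] * s_anchor[[1, 2, 2]]
    raw["phi"] = draws_std["phi"] * pair[None, None, :]
    return raw


def _summarize(draws: dict, spec: QSemSpec) -> pd.DataFrame:
    names, arrays = [], []
    ind = spec.indicator_names
    cov = list(spec.covariates)

    def add(name, arr):
        names.append(name)
        arrays.append(arr)

    add("gamma_socioeconomic", draws["gamma"][:, :, 0])
    add("gamma_personal", draws["gamma"][:, :, 1])
    for j, c in enumerate(cov):
        add(f"b_{c}", draws["b"][:, :, j])
    add("sigma", draws["sigma"])
    for j, c in enumerate(ind):
        add(f"mu_{c}", draws["mu"][:, :, j])
        add(f"lambda_{c}", draws["lambda"][:, :, j])
        add(f"psi_{c}", draws["psi"][:, :, j])
    for k, lab in enumerate(["phi_xi_11", "phi_xi_12", "phi_xi_22"]):
        add(lab, draws["phi"][:, :, k])

    rows = []
    for name, arr in zip(names, arrays):
        flat = arr.reshape(-1)
        lo, hi = np.percentile(flat, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "mean": flat.mean(),
                "median": np.median(flat),
                "sd": flat.std(ddof=1),
                "ci_2.5": lo,
                "ci_97.5": hi,
                "significant": bool(lo > 0 or hi < 0),
                "rhat": _split_rhat(arr),
                "ess": _ess(arr),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def gibbs_fit(
    indicators: pd.DataFrame,
    covariates: pd.DataFrame | None,
    spec: QSemSpec,
    tau: float,
    mcmc: McmcSettings | None = None,
) -> QSemFit:
    """Fit the quantile SEM at one quantile level.

    Returns posterior draws (original indicator scale), an equal-tailed
    95 % credible-interval summary with significance flags (interval
    excluding zero), split-R-hat and effective sample sizes, posterior
    mean latent states, and the fraction of posterior-mean structural
    residuals below zero (which should approximate tau).
    """
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must lie strictly in (0, 1), got {tau}")
    mcmc = mcmc or McmcSettings()
    y, x, scales = _prepare(indicators, covariates, spec)

    chain_draws, omega_means, delta_means, sign_fracs = [], [], [], []
    for chain in range(mcmc.chains):
        out, omega_mean, delta_mean, sign_frac = _run_chain(y, x, spec, tau, mcmc, chain)
        chain_draws.append(out)
        omega_means.append(omega_mean)
        delta_means.append(delta_mean)
        sign_fracs.append(sign_frac)

    draws_std = {
        key: np.stack([c[key] for c in chain_draws]) for key in chain_draws[0]
    }
    draws_raw = (
        _to_raw_scale(draws_std, spec, scales)
        if (spec.standardize and not spec.observed_factors)
        else {k: v.copy() for k, v in draws_std.items()}
    )
    summary = _summarize(draws_raw, spec)

    omega_mean = np.mean(omega_means, axis=0)
    delta_mean = np.mean(delta_means, axis=0)
    latent = pd.DataFrame(omega_mean, index=indicators.index, columns=["eta", "xi1", "xi2"])
    return QSemFit(
        tau=tau,
        draws=draws_raw,
        summary=summary,
        latent_mean=latent,
        resid_negative_fraction=float(np.mean(sign_fracs)),
        plugin_resid_negative_fraction=float(np.mean(delta_mean < 0)),
        spec=spec,
        mcmc=mcmc,
        scales=scales,
        draws_std=draws_std,
    )


@dataclass
class QuantileGrid:
    """Fits at several quantile levels plus the long-format grid."""

    fits: dict[float, QSemFit]
    coefficient_grid: pd.DataFrame

    def crossing_diagnostic(self) -> pd.DataFrame:
        """Flag parameters whose posterior-mean path is non-monotone in
        a way that suggests quantile crossing (informational only)."""
        wide = self.coefficient_grid.pivot_table(
            index="parameter", columns="tau", values="mean"
        )
        return wide


def fit_all_quantiles(
    indicators: pd.DataFrame,
    covariates: pd.DataFrame | None,
    spec: QSemSpec,
    mcmc: McmcSettings | None = None,
) -> QuantileGrid:
    """Run :func:`gibbs_fit` at every quantile level in the spec and
    stack the structural-coefficient summaries into a long table
    (tau, parameter, mean, 2.5 %, 97.5 %, significant)."""
    fits = {}
    tables = []
    for tau in spec.quantiles:
        fit = gibbs_fit(indicators, covariates, spec, tau, mcmc)
        fits[tau] = fit
        tab = fit.coefficient_table().reset_index()
        tables.append(tab)
    grid = pd.concat(tables, ignore_index=True)[
        ["tau", "parameter", "mean", "median", "ci_2.5", "ci_97.5", "significant", "rhat", "ess"]
    ]
    return QuantileGrid(fits=fits, coefficient_grid=grid)
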