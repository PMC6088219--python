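"""Measurement constructs: profile extraction, stressor EFA, descriptives.

The latent "psychological problems profile" is the dominant factor of
the 3 x 3 correlation matrix of distress, anxiety and depression scores;
the two stressor domains come from an exploratory factor analysis of the
11 stressful-life-event domain scores (correlation matrix, eigenvalue
extraction, varimax rotation).  Extraction is principal-component style
(eigendecomposition of the correlation matrix) so "% of total variance
explained" is the PCA quantity; principal-axis iteration is available
as an option.  Factor scores use the regression method on standardized
indicators, and the profile factor's sign is fixed so all loadings are
positive (higher score = worse mental health).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorSolution",
    "extract_profile",
    "efa_stressors",
    "varimax",
    "quartile_descriptives",
]


@dataclass
class FactorSolution:
    eigenvalues: np.ndarray
    n_factors: int
    loadings: pd.DataFrame  # indicators x factors, rotated where applicable
    variance_explained: float  # percent of total variance
    communalities: pd.Series
    factor_scores: pd.DataFrame  # n x factors
    assignment: dict[str, int]  # indicator -> factor index


def _standardize(df: pd.DataFrame) -> np.ndarray:
    x = df.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        zero = list(df.columns[sd == 0])
        raise ValueError(f"constant columns cannot be factor-analysed: {zero}")
    return (x - x.mean(axis=0)) / sd


def extract_profile(psych_indicators: pd.DataFrame) -> FactorSolution:
    """Extract the single-factor psychological problems profile.

    Standardizes the three columns (distress, anxiety, depression),
    eigendecomposes their correlation matrix and returns the dominant
    factor.  Scores have sample mean 0 and variance 1; variance
    explained is 100 * lambda_1 / 3.  For equicorrelated columns with
    correlation r this equals 100 * (1 + 2 r) / 3.
    """
    if psych_indicators.shape[1] < 3:
        raise ValueError("profile extraction needs the 3 psychological indicators")
    data = psych_indicators.dropna()
    if data.shape[0] < 3:
        raise ValueError("too few complete cases for profile extraction")
    z = _standardize(data)
    r = np.corrcoef(z, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(r)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    v1 = eigvecs[:, 0]
    if v1.sum() < 0:
        v1 = -v1
    loadings = v1 * np.sqrt(eigvals[0])
    scores = z @ v1
    scores = (scores - scores.mean()) / scores.std()
    p = z.shape[1]
    return FactorSolution(
        eigenvalues=eigvals,
        n_factors=1,
        loadings=pd.DataFrame(
            loadings, index=list(data.columns), columns=["profile"]
        ),
        variance_explained=100.0 * eigvals[0] / p,
        communalities=pd.Series(loadings**2, index=list(data.columns)),
        factor_scores=pd.DataFrame(scores, index=data.index, columns=["profile"]),
        assignment={c: 0 for c in data.columns},
    )


def varimax(
    loadings: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix).

    Maximizes the varimax criterion (sum over factors of the variance of
    squared loadings) over orthogonal rotations by cyclic pairwise plane
    rotations with the closed-form optimal angle (Kaiser's algorithm);
    row normalization is on by default.  The rotation matrix is a
    product of plane rotations and hence orthonormal to machine
    precision.
    """
    lam = np.asarray(loadings, dtype=float)
    if lam.ndim != 2 or lam.shape[1] < 2:
        raise ValueError("varimax needs at least 2 factors")
    p, k = lam.shape
    if normalize:
        h = np.sqrt((lam**2).sum(axis=1))
        h[h == 0] = 1.0
        x = lam / h[:, None]
    else:
        x = lam.copy()
    rot = np.eye(k)
    crit = varimax_criterion(x)
    converged = False
    for _ in range(max_iter):
        for i in range(k - 1):
            for j in range(i + 1, k):
                a_col, b_col = x[:, i], x[:, j]
                u = a_col**2 - b_col**2
                v = 2.0 * a_col * b_col
                num = 2.0 * (u @ v - u.sum() * v.sum() / p)
                den = (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2) / p
                angle = 0.25 * np.arctan2(num, den)
                if abs(angle) < 1e-15:
                    continue
                c, s_ = np.cos(angle), np.sin(angle)
                g = np.array([[c, -s_], [s_, c]])
                x[:, [i, j]] = x[:, [i, j]] @ g
                rot[:, [i, j]] = rot[:, [i, j]] @ g
        new_crit = varimax_criterion(x)
        if new_crit - crit <= tol * max(crit, 1e-12):
            crit = new_crit
            converged = True
            break
        crit = new_crit
    if not converged:
        warnings.warn(
            f"varimax did not converge in {max_iter} sweeps "
            f"(criterion ended at {crit:.6g})",
            RuntimeWarning,
        )
    out = x
    if normalize:
        out = out * h[:, None]
    return out, rot


def varimax_criterion(loadings: np.ndarray) -> float:
    """The raw varimax objective: sum over factors of Var(loading^2)."""
    sq = np.asarray(loadings, dtype=float) ** 2
    return float(np.sum(sq.var(axis=0)))


def efa_stressors(
    domain_scores: pd.DataFrame,
    n_factors: int | str = "auto",
    extraction: str = "pca",
) -> FactorSolution:
    """Exploratory factor analysis of the 11 stressor domain scores.

    Correlation-matrix eigendecomposition, ``n_factors`` components
    (``'auto'`` keeps eigenvalues > 1; the full eigenvalue vector is the
    scree report), varimax rotation, and assignment of each domain to
    the factor with the larger absolute rotated loading.  Variance
    explained is the cumulative percentage over retained factors and is
    invariant to column scaling.  ``extraction='paf'`` runs principal-
    axis iteration on communalities instead of PCA.
    """
    data = domain_scores.dropna()
    z = _standardize(data)
    r = np.corrcoef(z, rowvar=False)
    cond = np.linalg.cond(r)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            f"correlation matrix is numerically singular (condition number {cond:.3g})"
        )
    eigvals, eigvecs = np.linalg.eigh(r)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    p = r.shape[0]

    if n_factors == "auto":
        k = int(np.sum(eigvals > 1.0))
        if k < 2:
            warnings.warn(
                "eigenvalue>1 rule selected fewer than 2 factors "
                f"(eigenvalues: {np.round(eigvals, 3)})",
                RuntimeWarning,
            )
            k = max(k, 1)
    else:
        k = int(n_factors)

    if extraction == "pca":
        unrotated = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    elif extraction == "paf":
        unrotated = _principal_axis(r, k)
    else:
        raise ValueError(f"unknown extraction {extraction!r}")

    if k >= 2:
        rotated, _ = varimax(unrotated)
        # order factors by explained variance, largest first
        ssq = (rotated**2).sum(axis=0)
        rotated = rotated[:, np.argsort(ssq)[::-1]]
        rotated = rotated * np.sign(rotated.sum(axis=0) + 1e-300)
    else:
        rotated = unrotated * np.sign(unrotated.sum(axis=0) + 1e-300)

    cols = [f"factor{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(rotated, index=list(data.columns), columns=cols)
    assignment = {
        name: int(np.argmax(np.abs(rotated[i]))) for i, name in enumerate(data.columns)
    }
    # regression-method factor scores, standardized
    scores = z @ np.linalg.solve(r, rotated)
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    return FactorSolution(
        eigenvalues=eigvals,
        n_factors=k,
        loadings=loadings,
        variance_explained=100.0 * eigvals[:k].sum() / p,
        communalities=pd.Series((rotated**2).sum(axis=1), index=list(data.columns)),
        factor_scores=pd.DataFrame(scores, index=data.index, columns=cols),
        assignment=assignment,
    )


def _principal_axis(r: np.ndarray, k: int, max_iter: int = 200, tol: float = 1e-7):
    """Principal-axis factoring: iterate communalities on the diagonal."""
    rr = r.copy()
    comm = 1.0 - 1.0 / np.diag(np.linalg.inv(r))  # SMC start
    for _ in range(max_iter):
        np.fill_diagonal(rr, comm)
        eigvals, eigvecs = np.linalg.eigh(rr)
        order = np.argsort(eigvals)[::-1][:k]
        lam = eigvecs[:, order] * np.sqrt(np.clip(eigvals[order], 0, None))
        new_comm = (lam**2).sum(axis=1)
        if np.max(np.abs(new_comm - comm)) < tol:
            comm = new_comm
            break
        comm = new_comm
    return lam


def assign_quartiles(profile_scores: pd.Series | np.ndarray) -> np.ndarray:
    """Quartile labels 1-4 at the sample quartiles; ties go to the lower
    quartile."""
    scores = np.asarray(profile_scores, dtype=float)
    qs = np.quantile(scores, [0.25, 0.5, 0.75])
    return np.searchsorted(qs, scores, side="left") + 1


def quartile_descriptives(
    scored: pd.DataFrame,
    profile_scores: pd.Series | np.ndarray,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Table-1 style descriptives across profile-score quartiles.

    Quantitative variables get mean +/- SD per quartile and a one-way
    ANOVA p-value; categorical variables get counts (%) and a chi-square
    p-value (with a zero-cell warning flag when some category is absent
    from a quartile).  Constant variables are reported not-applicable.
    """
    scores = np.asarray(profile_scores, dtype=float)
    if len(scores) != len(scored):
        raise ValueError("profile scores must align with the scored table")
    if np.any(~np.isfinite(scores)):
        raise ValueError("profile scores must be complete")
    quartile = assign_quartiles(scores)

    if categorical is None:
        categorical = [
            c
            for c in scored.columns
            if scored[c].dtype == object or scored[c].nunique(dropna=True) <= 5
        ]

    rows = []
    for col in scored.columns:
        series = scored[col]
        row: dict = {"variable": col}
        if col in categorical:
            table = pd.crosstab(series, quartile)
            for q in (1, 2, 3, 4):
                counts = table[q] if q in table.columns else pd.Series(dtype=int)
                total = counts.sum()
                row[f"Q{q}"] = "; ".join(
                    f"{lvl}: {cnt} ({100 * cnt / total:.1f}%)"
                    for lvl, cnt in counts.items()
                )
            if table.shape[0] < 2:
                row.update(test="chi-square", p_value=np.nan, note="constant variable")
            else:
                zero_cells = (table.to_numpy() == 0).any()
                chi2, p, _, _ = stats.chi2_contingency(table.to_numpy())
                row.update(
                    test="chi-square",
                    p_value=p,
                    note="zero cell in some quartile" if zero_cells else "",
                )
        else:
            vals = pd.to_numeric(series, errors="coerce")
            groups = [vals[quartile == q].dropna().to_numpy() for q in (1, 2, 3, 4)]
            for q, g in zip((1, 2, 3, 4), groups):
                row[f"Q{q}"] = f"{g.mean():.2f} ± {g.std(ddof=1):.2f}" if g.size else ""
            if vals.nunique() <= 1:
                row.update(test="anova", p_value=np.nan, note="constant variable")
            else:
                _, p = stats.f_oneway(*[g for g in groups if g.size > 1])
                row.update(test="anova", p_value=p, note="")
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
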