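"""End-to-end orchestration: score -> factors -> fit -> eval -> report.

Also houses the Cochran single-proportion sample-size formula used at
the study-design stage.  All randomness derives from a single top-level
seed split per stage; every artifact carries the configuration hash so
reruns with unchanged configuration can skip completed stages.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import latentq
from latentq import factors as _factors
from latentq import synthetic as _synthetic
from latentq.classical import fit_indices, fit_mean_sem, posterior_predictive_pvalue
from latentq.qsem import McmcSettings, QSemSpec, fit_all_quantiles

__all__ = ["cochran_sample_size", "RunConfig", "run_pipeline"]


def cochran_sample_size(
    p: float, alpha: float = 0.05, d: float = 0.01, round_to: int = 1
) -> int:
    """Cochran sample size z^2 p (1-p) / d^2, rounded up to a multiple.

    With prevalence p = 0.1, alpha = 0.05 and margin d = 0.01 the raw
    value is 3457.3, which rounds up to 3500 at round_to = 100.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"proportion p must lie in (0, 1), got {p}")
    if not (0.0 < d < 1.0):
        raise ValueError(f"margin d must lie in (0, 1), got {d}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if round_to < 1:
        raise ValueError("round_to must be a positive integer")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    n_raw = z**2 * p * (1.0 - p) / d**2
    return int(math.ceil(n_raw / round_to) * round_to)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Exactly one of ``scored_csv`` (pre-scored data) or ``simulate``
    (synthetic-data generation with the default truth) feeds the
    factor/fit stages; ``stages`` toggles later stages off.
    """

    output_dir: str
    scored_csv: str | None = None
    simulate: bool = False
    n: int = 2000
    seed: int = 0
    quantiles: tuple = (0.05, 0.25, 0.50, 0.75, 0.95)
    covariates: tuple = tuple(_synthetic.DEFAULT_COVARIATES)
    stages: tuple = ("data", "factors", "fit", "eval", "report")
    chains: int = 2
    iterations: int = 3000
    burn_in: int = 1000

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage_done(outdir: Path, stage: str, chash: str) -> bool:
    marker = outdir / f".{stage}.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == chash
    except json.JSONDecodeError:
        return False


def _mark_stage(outdir: Path, stage: str, chash: str, **info) -> None:
    (outdir / f".{stage}.json").write_text(
        json.dumps({"config_hash": chash, **info}, indent=2, default=str)
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline stages in order and write the report bundle.

    Returns a dictionary with the per-stage outputs; artifacts (CSV
    tables, report.md, report.json) are written under
    ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    result: dict = {"config_hash": chash}

    # ---- data stage -------------------------------------------------
    scored_path = outdir / "scored.csv"
    if "data" in config.stages and not _stage_done(outdir, "data", chash):
        if config.simulate:
            truth = _synthetic.default_truth(n=config.n, seed=int(seeds[0].generate_state(1)[0] % 2**31))
            ind, cov, _lat = _synthetic.generate_dataset(truth)
            scored = pd.concat([ind, cov], axis=1)
        elif config.scored_csv:
            scored = pd.read_csv(config.scored_csv)
        else:
            raise ValueError("config must set scored_csv or simulate=True")
        scored.to_csv(scored_path, index=False)
        _mark_stage(outdir, "data", chash, rows=len(scored))
    scored = pd.read_csv(scored_path)
    result["scored"] = scored

    psych_cols = _synthetic.PSYCH_INDICATORS
    domain_cols = _synthetic.SOCIOECONOMIC_DOMAINS + _synthetic.PERSONAL_DOMAINS
    cov_cols = [c for c in config.covariates if c in scored.columns]

    # ---- factor stage -----------------------------------------------
    if "factors" in config.stages:
        profile = _factors.extract_profile(scored[psych_cols])
        efa = _factors.efa_stressors(scored[domain_cols])
        desc = _factors.quartile_descriptives(
            scored[cov_cols], profile.factor_scores["profile"]
        )
        profile.loadings.to_csv(outdir / "profile_loadings.csv")
        efa.loadings.to_csv(outdir / "stressor_loadings.csv")
        pd.DataFrame({"eigenvalue": efa.eigenvalues}).to_csv(
            outdir / "scree.csv", index=False
        )
        desc.to_csv(outdir / "quartile_descriptives.csv")
        _mark_stage(
            outdir,
            "factors",
            chash,
            profile_variance_explained=profile.variance_explained,
            efa_variance_explained=efa.variance_explained,
        )
        result["profile"] = profile
        result["efa"] = efa
        result["descriptives"] = desc

    # ---- fit stage --------------------------------------------------
    spec = QSemSpec(
        eta_indicators=psych_cols,
        xi1_indicators=_synthetic.SOCIOECONOMIC_DOMAINS,
        xi2_indicators=_synthetic.PERSONAL_DOMAINS,
        covariates=cov_cols,
        quantiles=config.quantiles,
    )
    mcmc = McmcSettings(
        chains=config.chains,
        iterations=config.iterations,
        burn_in=config.burn_in,
        seed=int(seeds[2].generate_state(1)[0] % 2**31),
    )
    if "fit" in config.stages:
        grid = fit_all_quantiles(scored[domain_cols + psych_cols], scored[cov_cols], spec, mcmc)
        grid.coefficient_grid.to_csv(outdir / "coefficient_grid.csv", index=False)
        result["grid"] = grid

    # ---- eval stage -------------------------------------------------
    if "eval" in config.stages and "fit" in config.stages:
        classical = fit_mean_sem(scored[domain_cols + psych_cols], scored[cov_cols], spec)
        indices = fit_indices(classical)
        median_fit = result["grid"].fits.get(0.5) or next(
            iter(result["grid"].fits.values())
        )
        ppc = posterior_predictive_pvalue(
            median_fit,
            scored[domain_cols + psych_cols],
            scored[cov_cols],
            seed=int(seeds[3].generate_state(1)[0] % 2**31),
        )
        eval_report = {
            "cfi": indices.cfi,
            "tli": indices.tli,
            "rmsea": indices.rmsea,
            "acceptable": indices.acceptable,
            "chi2": classical.chi2,
            "df": classical.df,
            "pp_pvalue": ppc.p_value,
            "gamma_mean_model": classical.estimates["gamma"].tolist(),
        }
        (outdir / "fit_report.json").write_text(json.dumps(eval_report, indent=2))
        pd.DataFrame(
            {"d_observed": ppc.d_observed, "d_replicate": ppc.d_replicate}
        ).to_csv(outdir / "ppc_trace.csv", index=False)
        result["classical"] = classical
        result["indices"] = indices
        result["ppc"] = ppc

    # ---- report stage ----------------------------------------------
    if "report" in config.stages:
        lines = [
            "# latentq pipeline report",
            "",
            f"- configuration hash: `{chash}`",
            f"- seed: {config.seed}",
            f"- package version: {latentq.__version__}",
            f"- n (analysed rows): {len(scored)}",
            "",
        ]
        report_json: dict = {
            "config_hash": chash,
            "seed": config.seed,
            "version": latentq.__version__,
            "n": len(scored),
        }
        if "profile" in result:
            lines += [
                "## Measurement constructs",
                "",
                f"- profile variance explained: "
                f"{result['profile'].variance_explained:.2f} %",
                f"- stressor EFA ({result['efa'].n_factors} factors) variance "
                f"explained: {result['efa'].variance_explained:.2f} %",
                "",
            ]
            report_json["profile_variance_explained"] = result[
                "profile"
            ].variance_explained
            report_json["efa_variance_explained"] = result["efa"].variance_explained
        if "grid" in result:
            gam = result["grid"].coefficient_grid
            gam = gam[gam["parameter"].str.startswith("gamma_")]
            lines += ["## Structural coefficients by quantile", ""]
            lines.append(gam.to_string(index=False))
            lines.append("")
            report_json["coefficient_grid"] = gam.to_dict(orient="records")
        if "indices" in result:
            lines += [
                "## Goodness of fit",
                "",
                f"- CFI {result['indices'].cfi:.3f}, TLI {result['indices'].tli:.3f}, "
                f"RMSEA {result['indices'].rmsea:.3f} "
                f"({'acceptable' if result['indices'].acceptable else 'poor'})",
                f"- posterior predictive p-value: {result['ppc'].p_value:.3f}",
                "",
            ]
            report_json["fit_indices"] = {
                "cfi": result["indices"].cfi,
                "tli": result["indices"].tli,
                "rmsea": result["indices"].rmsea,
            }
            report_json["pp_pvalue"] = result["ppc"].p_value
        (outdir / "report.md").write_text("\n".join(lines))
        (outdir / "report.json").write_text(
            json.dumps(report_json, indent=2, default=float)
        )
        _mark_stage(outdir, "report", chash)
    return result
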