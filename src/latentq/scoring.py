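"""Questionnaire scoring: raw item responses -> derived analysis scores.

Instruments handled:

* GHQ-12 — 12 items on a 4-point response scale; the distress score uses
  bimodal (0-0-1-1) recoding by default, giving a 0-12 total.
* HADS — two 7-item subscales (anxiety, depression), items 0-3, plain
  sums 0-21 with caseness at a score >= 8.
* SLE — 46 stressful-life-event items rated 0-5 by perceived intensity,
  partitioned into 11 named domains; each domain is scored as the item
  mean so domains with different item counts stay comparable on the
  common 0-5 scale (sums are available as an option).
* ERI — effort-reward imbalance, the adjusted ratio of the effort sum to
  the reward sum; values above 1 indicate mismatch.
* IPAQ — total physical activity as the sum of the vigorous, moderate
  and walking/sitting MET.h/week components.

Records missing more than 10 % of instrument items are flagged excluded;
smaller gaps are filled by prorated within-instrument mean imputation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SLE_DOMAINS",
    "Codebook",
    "score_ghq12",
    "score_hads",
    "score_sle_domains",
    "score_eri",
    "score_ipaq",
    "score_table",
    "default_codebook",
]

#: Domain name -> number of items, in the instrument's published order.
SLE_DOMAINS: dict[str, int] = {
    "home_life": 7,
    "financial": 5,
    "social_relations": 4,
    "personal_conflict": 5,
    "job_conflicts": 4,
    "educational": 4,
    "job_security": 5,
    "loss_and_separation": 4,
    "sexual_life": 4,
    "daily_life": 2,
    "health_concerns": 2,
}

MISSING_EXCLUSION_FRACTION = 0.10


class ScoringError(ValueError):
    """Raised on out-of-range responses or malformed item vectors."""


def _check_items(items: Sequence, n: int, lo: int, hi: int, name: str) -> np.ndarray:
    arr = np.asarray(items, dtype=float)
    if arr.shape != (n,):
        raise ScoringError(f"{name}: expected {n} items, got shape {arr.shape}")
    bad = np.where((arr < lo) | (arr > hi) | (arr != np.floor(arr)))[0]
    if bad.size:
        raise ScoringError(
            f"{name}: item {bad[0]} has out-of-range response {arr[bad[0]]!r} "
            f"(allowed integers {lo}..{hi})"
        )
    return arr.astype(int)


def score_ghq12(items: Sequence[int], method: str = "bimodal") -> int:
    """Score the 12-item General Health Questionnaire.

    ``method='bimodal'`` recodes each 0-3 response as {0,1}->0, {2,3}->1
    and sums, giving the conventional 0-12 distress score.
    ``method='likert'`` returns the plain 0-36 sum.
    """
    arr = _check_items(items, 12, 0, 3, "GHQ-12")
    if method == "bimodal":
        return int(np.sum(arr >= 2))
    if method == "likert":
        return int(arr.sum())
    raise ScoringError(f"unknown GHQ-12 scoring method {method!r}")


def score_hads(items: Sequence[int], cutoff: int = 8) -> tuple[int, bool]:
    """Score one HADS subscale: (sum 0-21, caseness flag at >= cutoff)."""
    arr = _check_items(items, 7, 0, 3, "HADS subscale")
    total = int(arr.sum())
    return total, total >= cutoff


def score_sle_domains(
    items: Sequence[int],
    codebook: Mapping[str, Sequence[int]] | None = None,
    aggregate: str = "mean",
) -> dict[str, float]:
    """Score the 46 SLE items into 11 domain scores on the 0-5 scale.

    ``codebook`` maps domain name -> 0-based item indices and must
    partition ``range(46)``; the default uses the instrument's published
    item order. ``aggregate`` is ``'mean'`` (default, 0-5 scale) or
    ``'sum'``.
    """
    if codebook is None:
        codebook = _default_sle_map()
    idx_all = sorted(i for idxs in codebook.values() for i in idxs)
    if idx_all != list(range(46)):
        raise ScoringError("SLE codebook does not partition the 46 items")
    arr = _check_items(items, 46, 0, 5, "SLE")
    if aggregate not in ("mean", "sum"):
        raise ScoringError(f"unknown SLE aggregate {aggregate!r}")
    out: dict[str, float] = {}
    for domain, idxs in codebook.items():
        vals = arr[list(idxs)]
        out[domain] = float(vals.mean() if aggregate == "mean" else vals.sum())
    return out


def score_eri(
    effort_items: Sequence[float],
    reward_items: Sequence[float],
    correction: float = 6.0 / 11.0,
) -> float:
    """Effort-reward imbalance ratio sum(effort)/(c*sum(reward)).

    The default correction c = 6/11 (number of effort items over number
    of reward items) puts a balanced questionnaire at exactly 1; values
    above 1 indicate an effort-reward mismatch.
    """
    effort = float(np.sum(effort_items))
    reward = float(np.sum(reward_items))
    if reward <= 0:
        raise ScoringError("ERI: reward item sum must be strictly positive")
    if effort <= 0:
        raise ScoringError("ERI: effort item sum must be strictly positive")
    if correction <= 0:
        raise ScoringError("ERI: correction factor must be positive")
    return effort / (correction * reward)


def score_ipaq(vigorous_met: float, moderate_met: float, walk_sit_met: float) -> float:
    """Total physical activity (MET.h/week) as the sum of three components."""
    comps = np.asarray([vigorous_met, moderate_met, walk_sit_met], dtype=float)
    if np.any(comps < 0) or np.any(~np.isfinite(comps)):
        raise ScoringError("IPAQ: components must be finite and nonnegative")
    return float(comps.sum())


def _default_sle_map() -> dict[str, list[int]]:
    out, start = {}, 0
    for domain, count in SLE_DOMAINS.items():
        out[domain] = list(range(start, start + count))
        start += count
    return out


@dataclass
class Codebook:
    """Binding of instrument items to table columns.

    Column-name conventions (all overridable via JSON):
    ``ghq12``: 12 columns, ``hads_anxiety``/``hads_depression``: 7 each,
    ``sle``: domain -> columns, ``eri_effort``/``eri_reward``: item
    columns, ``ipaq``: 3 MET component columns, ``covariates``: carried
    through unchanged.
    """

    ghq12: list[str]
    hads_anxiety: list[str]
    hads_depression: list[str]
    sle: dict[str, list[str]]
    eri_effort: list[str]
    eri_reward: list[str]
    ipaq: list[str]
    covariates: list[str] = field(default_factory=list)
    id_column: str = "participant_id"
    eri_correction: float = 6.0 / 11.0
    ghq12_method: str = "bimodal"
    sle_aggregate: str = "mean"

    def __post_init__(self) -> None:
        if len(self.ghq12) != 12:
            raise ScoringError("codebook: ghq12 must list 12 columns")
        if len(self.hads_anxiety) != 7 or len(self.hads_depression) != 7:
            raise ScoringError("codebook: HADS subscales must list 7 columns each")
        counts = {d: len(cols) for d, cols in self.sle.items()}
        if counts != SLE_DOMAINS:
            raise ScoringError(
                f"codebook: SLE domains must have item counts {SLE_DOMAINS}, got {counts}"
            )
        if len(self.ipaq) != 3:
            raise ScoringError("codebook: ipaq must list 3 MET component columns")

    @classmethod
    def from_json(cls, path) -> "Codebook":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @property
    def item_columns(self) -> list[str]:
        cols = list(self.ghq12) + list(self.hads_anxiety) + list(self.hads_depression)
        for d in SLE_DOMAINS:
            cols += list(self.sle[d])
        cols += list(self.eri_effort) + list(self.eri_reward) + list(self.ipaq)
        return cols


def default_codebook(covariates: Sequence[str] = ()) -> Codebook:
    """Codebook for the generic column layout ghq_1.., hadsa_1.., sle_1.. etc."""
    sle_map = {}
    k = 1
    for domain, count in SLE_DOMAINS.items():
        sle_map[domain] = [f"sle_{k + j}" for j in range(count)]
        k += count
    return Codebook(
        ghq12=[f"ghq_{i}" for i in range(1, 13)],
        hads_anxiety=[f"hadsa_{i}" for i in range(1, 8)],
        hads_depression=[f"hadsd_{i}" for i in range(1, 8)],
        sle=sle_map,
        eri_effort=[f"eri_e_{i}" for i in range(1, 7)],
        eri_reward=[f"eri_r_{i}" for i in range(1, 12)],
        ipaq=["ipaq_vigorous", "ipaq_moderate", "ipaq_walk_sit"],
        covariates=list(covariates),
    )


def _impute_instrument(block: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Prorated mean imputation within an instrument, per record."""
    filled = block.copy().astype(float)
    n_imputed = 0
    means = filled.mean(axis=1)
    for col in filled.columns:
        miss = filled[col].isna()
        if miss.any():
            filled.loc[miss, col] = np.round(means[miss])
            n_imputed += int(miss.sum())
    return filled, n_imputed


def score_table(raw: pd.DataFrame, codebook: Codebook) -> pd.DataFrame:
    """Score a raw participant table into the analysis-ready table.

    Returns one row per participant with the 3 psychological indicators,
    11 SLE domain scores, ERI ratio, IPAQ total, covariates carried
    through, plus ``missing_fraction`` and an ``excluded`` flag for
    records missing more than 10 % of instrument items. Item-level gaps
    in non-excluded records are mean-imputed within instrument and
    counted in ``n_imputed``.
    """
    item_cols = codebook.item_columns
    missing = [c for c in item_cols if c not in raw.columns]
    if missing:
        raise ScoringError(f"input table lacks item columns: {missing[:5]} ...")

    items = raw[item_cols].apply(pd.to_numeric, errors="coerce")
    missing_fraction = items.isna().mean(axis=1)
    excluded = missing_fraction > MISSING_EXCLUSION_FRACTION

    blocks = {
        "ghq": codebook.ghq12,
        "hadsa": codebook.hads_anxiety,
        "hadsd": codebook.hads_depression,
        "sle": [c for d in SLE_DOMAINS for c in codebook.sle[d]],
        "eri": list(codebook.eri_effort) + list(codebook.eri_reward),
        "ipaq": codebook.ipaq,
    }
    imputed = {}
    n_imputed = pd.Series(0, index=raw.index)
    for name, cols in blocks.items():
        filled, _ = _impute_instrument(items[cols])
        n_imputed += items[cols].isna().sum(axis=1)
        imputed[name] = filled

    rows = []
    for i in raw.index:
        rec: dict = {}
        if codebook.id_column in raw.columns:
            rec["participant_id"] = raw.loc[i, codebook.id_column]
        if excluded[i]:
            rec.update(
                missing_fraction=float(missing_fraction[i]),
                excluded=True,
                n_imputed=int(n_imputed[i]),
            )
            rows.append(rec)
            continue
        ghq = imputed["ghq"].loc[i].to_numpy()
        rec["ghq12_distress"] = score_ghq12(
            np.clip(np.round(ghq), 0, 3).astype(int), codebook.ghq12_method
        )
        for key, block in (("hads_anxiety", "hadsa"), ("hads_depression", "hadsd")):
            vals = np.clip(np.round(imputed[block].loc[i].to_numpy()), 0, 3).astype(int)
            score, flag = score_hads(vals)
            rec[key] = score
            rec[f"{key}_disorder"] = flag
        sle_vals = np.clip(np.round(imputed["sle"].loc[i].to_numpy()), 0, 5).astype(int)
        rec.update(score_sle_domains(sle_vals, aggregate=codebook.sle_aggregate))
        eri_block = imputed["eri"].loc[i]
        rec["eri_ratio"] = score_eri(
            eri_block[list(codebook.eri_effort)].to_numpy(),
            eri_block[list(codebook.eri_reward)].to_numpy(),
            codebook.eri_correction,
        )
        rec["ipaq_met"] = score_ipaq(*imputed["ipaq"].loc[i].to_numpy())
        for cov in codebook.covariates:
            rec[cov] = raw.loc[i, cov]
        rec["missing_fraction"] = float(missing_fraction[i])
        rec["excluded"] = False
        rec["n_imputed"] = int(n_imputed[i])
        rows.append(rec)
    return pd.DataFrame(rows, index=raw.index)
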