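"""Phenotype preparation: QC exclusions, scale scoring, rank-INT, sex-stratified z.

The cohort-level filters mirror standard perinatal practice: offspring
flagged for congenital anomalies or multiple birth are removed first, then
preterm births (gestation < 37 completed weeks), then implausible birth
weights (<= 2.5 kg or >= 5 kg).  Questionnaire scales are scored as item
sums with person-level mean imputation allowed when at least half the
items are observed.  Outcomes are mapped to normal quantiles by a
rank-inverse-normal transform and birth weight is z-standardised within
sex strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GESTATION_MIN_WEEKS = 37.0
BW_LOW_KG = 2.5   # excluded when <= this
BW_HIGH_KG = 5.0  # excluded when >= this

QC_REQUIRED = ["gestational_age_weeks", "birth_weight_kg",
               "congenital_anomaly", "multiple_birth"]


@dataclass
class QcReport:
    """Exclusion counts with fixed precedence: flags -> gestation -> birth weight."""
    n_input: int
    n_excluded_other: int
    n_excluded_gestation: int
    n_excluded_birthweight: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (self.n_retained + self.n_excluded_other
                 + self.n_excluded_gestation + self.n_excluded_birthweight)
        if total != self.n_input:
            raise ValueError("QC counts do not partition the input")

    def to_text(self) -> str:
        return "".join(f"{k}: {v}\n" for k, v in vars(self).items())


def qc_filter(phenotypes: pd.DataFrame) -> tuple[pd.DataFrame, QcReport]:
    """Apply the cohort exclusion rules; returns retained rows and a QcReport.

    Retains records with no anomaly/multiple-birth flag, gestation >= 37
    weeks, and 2.5 kg < birth weight < 5 kg (both boundaries excluded).
    Exclusion reasons are assigned with precedence flags -> gestation ->
    birth weight, so the counts partition the input.
    """
    missing = [c for c in QC_REQUIRED if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"phenotype table lacks required QC columns: {missing}")
    flagged = (phenotypes["congenital_anomaly"].astype(bool)
               | phenotypes["multiple_birth"].astype(bool)).to_numpy()
    ga_ok = (phenotypes["gestational_age_weeks"] >= GESTATION_MIN_WEEKS).to_numpy()
    bw = phenotypes["birth_weight_kg"].to_numpy()
    bw_ok = (bw > BW_LOW_KG) & (bw < BW_HIGH_KG)

    excl_other = flagged
    excl_gest = ~flagged & ~ga_ok
    excl_bw = ~flagged & ga_ok & ~bw_ok
    keep = ~flagged & ga_ok & bw_ok
    report = QcReport(
        n_input=len(phenotypes),
        n_excluded_other=int(excl_other.sum()),
        n_excluded_gestation=int(excl_gest.sum()),
        n_excluded_birthweight=int(excl_bw.sum()),
        n_retained=int(keep.sum()),
    )
    return phenotypes.loc[keep].copy(), report


def score_scale(items: np.ndarray) -> np.ndarray:
    """Score a questionnaire scale as an item sum with the 50% rule.

    ``items`` is persons x items with NaN for missing responses.  Persons
    with at least 50% nonmissing items receive (mean of observed items) x
    (number of items) — i.e. missing items imputed at the person's observed
    mean; persons below the threshold are scored missing.
    """
    items = np.asarray(items, float)
    if items.ndim != 2 or items.shape[1] == 0:
        raise ValueError("item matrix must be 2-D with at least one item")
    n_items = items.shape[1]
    n_obs = np.sum(~np.isnan(items), axis=1)
    mean_obs = np.nansum(items, axis=1) / np.maximum(n_obs, 1)
    scores = mean_obs * n_items
    scores[n_obs * 2 < n_items] = np.nan
    return scores


def rank_inverse_normal(values: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-inverse-normal transform with a configurable rank offset.

    Nonmissing values are replaced by Phi^-1((rank - c) / (n - 2c + 1));
    the default offset c = 3/8 is the Blom variant.  Ties share the average
    rank and missing entries stay missing.
    """
    values = np.asarray(values, float)
    obs = ~np.isnan(values)
    n = int(obs.sum())
    if n < 2:
        raise ValueError("rank-inverse-normal transform needs >= 2 nonmissing values")
    ranks = stats.rankdata(values[obs], method="average")
    out = np.full(values.shape, np.nan)
    out[obs] = stats.norm.ppf((ranks - c) / (n - 2 * c + 1))
    return out


def sex_stratified_z(birth_weight: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """z-standardise birth weight separately within each sex stratum.

    Uses the n-1 denominator; every stratum must have >= 2 members.
    Missing birth weights stay missing and do not enter stratum moments.
    """
    bw = np.asarray(birth_weight, float)
    sex = np.asarray(sex)
    if bw.shape != sex.shape:
        raise ValueError("birth_weight and sex must be aligned")
    out = np.full(bw.shape, np.nan)
    for stratum in pd.unique(sex):
        mask = (sex == stratum) & ~np.isnan(bw)
        if mask.sum() < 2:
            raise ValueError(f"sex stratum {stratum!r} has fewer than 2 members")
        vals = bw[mask]
        out[mask] = (vals - vals.mean()) / vals.std(ddof=1)
    return out
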