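"""Orchestration of the within-family Mendelian randomization analyses.

The causal question: is the observational association between lower birth
weight and childhood neurodevelopmental difficulties (NDDs) driven by the
intrauterine environment?  Because per-allele effects on the latent
intrauterine exposure are unavailable, no causal effect is *estimated*;
instead the pipeline tests the causal null — whether the maternal
birth-weight allele score associates with offspring NDDs conditional on
the offspring (and paternal) scores at the same loci.  Paternal scores
cannot act through the womb and serve as a negative control: a maternal
association with a null paternal one indicates an intrauterine effect,
similar maternal and paternal associations indicate postnatal/shared
mechanisms, and an offspring-only association indicates pleiotropy
through the offspring genome.

Stages: an observational LMM of NDD on birth weight; allele-score
benchmarking against birth weight; conditional score models in trio,
mother-offspring and father-offspring designs (with a GRM random effect);
weighted-score sensitivity runs with per-locus dosage adjustment; sex
stratification; and a rule-based interpretation of the resulting pattern
of associations against the multiplicity-corrected threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import transforms
from .grm import Grm
from .lmm import fit_lmm_reml
from .scores import compute_score, impute_missing_dosage
from .simulate import TrioCohort, DESIGNS

log = logging.getLogger(__name__)

MIN_COMPLETE_CASES = 50

DESIGN_ROLES = {
    "trio": ("maternal", "offspring", "paternal"),
    "maternal_dyad": ("maternal", "offspring"),
    "paternal_dyad": ("paternal", "offspring"),
}
ROLE_TO_MEMBER = {"maternal": "mother", "offspring": "offspring", "paternal": "father"}

RESULT_COLUMNS = ["outcome", "design", "set_id", "focal_role", "weighting",
                  "sex_stratum", "n", "beta", "se", "p"]

PATTERNS = ("intrauterine_effect", "postnatal_shared", "fetal_pleiotropy",
            "null", "inconclusive")


@dataclass
class CausalVerdict:
    """Rule-based reading of one outcome's conditional-association pattern."""
    pattern: str
    evidence: dict[str, bool]
    reason: str = ""

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "null" and any(self.evidence.values()):
            raise ValueError("null verdict requires no role to pass the threshold")


def subset_cohort(cohort: TrioCohort, mask: np.ndarray) -> TrioCohort:
    """Row-subset every aligned component of a cohort."""
    mask = np.asarray(mask)
    if mask.dtype != bool:
        m = np.zeros(cohort.n_children, bool)
        m[mask] = True
        mask = m
    return replace(
        cohort,
        family_id=cohort.family_id[mask],
        child_id=cohort.child_id[mask],
        family_index=cohort.family_index[mask],
        G_m=cohort.G_m[mask],
        G_f=cohort.G_f[mask],
        G_o=cohort.G_o[mask],
        phenotypes=cohort.phenotypes.loc[mask].reset_index(drop=True),
        liabilities=cohort.liabilities.loc[mask].reset_index(drop=True),
        items={k: v[mask] for k, v in cohort.items.items()},
        design=np.asarray(cohort.design)[mask],
        latents=(cohort.latents.loc[mask].reset_index(drop=True)
                 if cohort.latents is not None else None),
    )


def prepare_cohort(cohort: TrioCohort) -> tuple[TrioCohort, transforms.QcReport]:
    """Apply the perinatal QC exclusions to a cohort (all members aligned)."""
    _, report = transforms.qc_filter(cohort.phenotypes)
    flagged = (cohort.phenotypes["congenital_anomaly"].astype(bool)
               | cohort.phenotypes["multiple_birth"].astype(bool)).to_numpy()
    ga_ok = (cohort.phenotypes["gestational_age_weeks"]
             >= transforms.GESTATION_MIN_WEEKS).to_numpy()
    bw = cohort.phenotypes["birth_weight_kg"].to_numpy()
    keep = ~flagged & ga_ok & (bw > transforms.BW_LOW_KG) & (bw < transforms.BW_HIGH_KG)
    return subset_cohort(cohort, keep), report


def outcome_scores(cohort: TrioCohort) -> pd.DataFrame:
    """Scale scores per outcome: 50%-rule item sums when items exist, else liabilities."""
    if cohort.items:
        return pd.DataFrame({name: transforms.score_scale(mat)
                             for name, mat in cohort.items.items()})
    return cohort.liabilities.copy()


def covariate_matrix(
    phenotypes: pd.DataFrame,
    include_sex: bool = True,
    include_maternal_age: bool = True,
    include_paternal_age: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect covariate block: intercept, linear ages/gestation, dummies.

    Gestational age and parental ages enter linearly (centred); birth year
    and genotyping batch enter as categorical dummies (first level
    reference).
    """
    n = len(phenotypes)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    if include_sex:
        cols.append((phenotypes["sex"] == "M").to_numpy(float))
        names.append("sex_M")
    cols.append(phenotypes["gestational_age_weeks"].to_numpy(float) - 39.5)
    names.append("gestational_age")
    if include_maternal_age:
        cols.append(phenotypes["maternal_age"].to_numpy(float) - 30.0)
        names.append("maternal_age")
    if include_paternal_age:
        cols.append(phenotypes["paternal_age"].to_numpy(float) - 32.0)
        names.append("paternal_age")
    for var in ("birth_year", "batch"):
        dummies = pd.get_dummies(phenotypes[var], prefix=var, drop_first=True)
        for c in dummies.columns:
            col = dummies[c].to_numpy(float)
            if col.std() > 0:
                cols.append(col)
                names.append(str(c))
    return np.column_stack(cols), names


def _subset_grm(grm: Grm | None, mask: np.ndarray) -> Grm | None:
    if grm is None:
        return None
    idx = np.flatnonzero(mask)
    return Grm(ids=grm.ids[idx], matrix=grm.matrix[np.ix_(idx, idx)],
               n_loci_used=grm.n_loci_used)


def _fit_rows(y, X, names, grm, base: dict, focal_terms: dict[str, str]) -> list[dict]:
    """Fit one LMM and emit a result row per focal term (skips tiny samples)."""
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    if ok.sum() < MIN_COMPLETE_CASES:
        log.info("skipping %s: only %d complete cases", base.get("outcome"), ok.sum())
        return []
    sub_grm = _subset_grm(grm, ok) if grm is not None else None
    fit = fit_lmm_reml(y[ok], X[ok], grm=sub_grm, term_names=names)
    rows = []
    for role, term in focal_terms.items():
        beta, se, p = fit.term(term)
        rows.append({**base, "focal_role": role, "n": fit.n,
                     "beta": beta, "se": se, "p": p})
    return rows


def run_observational(
    cohort: TrioCohort,
    grm: Grm | None = None,
    outcomes: list[str] | None = None,
    include_sex: bool = True,
    sex_stratum: str | None = None,
    rank_int: bool = True,
) -> pd.DataFrame:
    """Conventional epidemiological LMM of each NDD outcome on birth weight.

    The outcome is rank-inverse-normal transformed; birth weight is
    sex-stratified z; covariates are sex, birth year, gestational duration,
    genotyping batch and parental ages, with a GRM random effect when
    supplied.
    """
    ph = cohort.phenotypes
    bwz = transforms.sex_stratified_z(ph["birth_weight_kg"].to_numpy(),
                                      ph["sex"].to_numpy())
    cov, cov_names = covariate_matrix(ph, include_sex=include_sex)
    X = np.column_stack([bwz, cov])
    names = ["birth_weight_z"] + cov_names
    scores_df = outcome_scores(cohort)
    rows: list[dict] = []
    for outcome in outcomes or scores_df.columns:
        y = scores_df[outcome].to_numpy(float)
        if rank_int:
            y = transforms.rank_inverse_normal(y)
        base = {"outcome": outcome, "design": "observational", "set_id": "",
                "weighting": "", "sex_stratum": sex_stratum or ""}
        rows += _fit_rows(y, X, names, grm, base, {"birth_weight": "birth_weight_z"})
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def _role_scores(
    cohort: TrioCohort, roles: tuple[str, ...], set_id: str, weighting: str
) -> dict[str, pd.Series]:
    out = {}
    for role in roles:
        dos = impute_missing_dosage(cohort.dosages(ROLE_TO_MEMBER[role]), cohort.snps)
        out[role] = compute_score(dos, cohort.snps, set_id, weighting,
                                  person_role=ROLE_TO_MEMBER[role]).values
    return out


def run_benchmarking(
    cohort: TrioCohort,
    set_ids: tuple[str, ...] = ("M1", "M2", "M3", "F1", "F2", "F3"),
    weighting: str = "unweighted",
    grm: Grm | None = None,
    design: str = "trio",
) -> pd.DataFrame:
    """Allele-score validity check: conditional association of each score with birth weight.

    For each score set, birth-weight z is regressed jointly on the
    available family roles' scores plus covariates, so each coefficient is
    conditional on the other roles.  Positive conditional offspring and
    maternal associations validate the scores as instruments.
    """
    mask = cohort.design_mask(design)
    if not mask.any():
        raise ValueError(f"no families support the {design} design")
    sub = subset_cohort(cohort, mask)
    roles = DESIGN_ROLES[design]
    ph = sub.phenotypes
    bwz = transforms.sex_stratified_z(ph["birth_weight_kg"].to_numpy(),
                                      ph["sex"].to_numpy())
    cov, cov_names = covariate_matrix(
        ph, include_maternal_age="maternal" in roles,
        include_paternal_age="paternal" in roles)
    sub_grm = _subset_grm(grm, mask)
    rows: list[dict] = []
    for set_id in set_ids:
        rs = _role_scores(sub, roles, set_id, weighting)
        X = np.column_stack([*(rs[r].to_numpy() for r in roles), cov])
        names = [f"score_{r}" for r in roles] + cov_names
        base = {"outcome": "birth_weight_z", "design": design, "set_id": set_id,
                "weighting": weighting, "sex_stratum": ""}
        rows += _fit_rows(bwz, X, names, sub_grm, base,
                          {r: f"score_{r}" for r in roles})
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def run_mr(
    cohort: TrioCohort,
    design: str = "maternal_dyad",
    set_id: str = "M1",
    weighting: str = "unweighted",
    grm: Grm | None = None,
    outcomes: list[str] | None = None,
    include_sex: bool = True,
    sex_stratum: str | None = None,
    rank_int: bool = True,
) -> pd.DataFrame:
    """Conditional allele-score models for one design, score set and weighting.

    Each rank-INT NDD outcome is regressed jointly on all available role
    scores plus covariates (the covariates of an unobserved parent are
    dropped with that parent), so every score coefficient is conditional
    on the other family members' scores.  Weighted sensitivity runs fit
    one model per focal role, adjusting for the *other* roles' per-locus
    dosages rather than their scores.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    mask = cohort.design_mask(design)
    if not mask.any():
        raise ValueError(f"no families support the {design} design")
    sub = subset_cohort(cohort, mask)
    roles = DESIGN_ROLES[design]
    ph = sub.phenotypes
    cov, cov_names = covariate_matrix(
        ph, include_sex=include_sex,
        include_maternal_age="maternal" in roles,
        include_paternal_age="paternal" in roles)
    sub_grm = _subset_grm(grm, mask)
    scores_df = outcome_scores(sub)
    rs = _role_scores(sub, roles, set_id, weighting)

    rows: list[dict] = []
    for outcome in outcomes or scores_df.columns:
        y = scores_df[outcome].to_numpy(float)
        if rank_int:
            y = transforms.rank_inverse_normal(y)
        base = {"outcome": outcome, "design": design, "set_id": set_id,
                "weighting": weighting, "sex_stratum": sex_stratum or ""}
        if weighting == "unweighted":
            X = np.column_stack([*(rs[r].to_numpy() for r in roles), cov])
            names = [f"score_{r}" for r in roles] + cov_names
            rows += _fit_rows(y, X, names, sub_grm, base,
                              {r: f"score_{r}" for r in roles})
        else:
            # weighted sensitivity: focal score + other roles' per-locus dosages
            from .snps import members
            set_cols = [s.snp_id for s in members(sub.snps, set_id)]
            for focal in roles:
                blocks = [rs[focal].to_numpy().reshape(-1, 1)]
                names = [f"score_{focal}"]
                for other in roles:
                    if other == focal:
                        continue
                    dos = impute_missing_dosage(
                        sub.dosages(ROLE_TO_MEMBER[other]), sub.snps)[set_cols]
                    blocks.append(dos.to_numpy())
                    names += [f"dos_{other}_{c}" for c in set_cols]
                X = np.column_stack(blocks + [cov])
                names += cov_names
                rows += _fit_rows(y, X, names, sub_grm, base,
                                  {focal: f"score_{focal}"})
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def sex_stratified(cohort: TrioCohort, runner=run_mr, **run_kwargs) -> pd.DataFrame:
    """Repeat an analysis within each sex stratum, dropping the sex covariate."""
    frames = []
    for stratum in ("M", "F"):
        mask = (cohort.phenotypes["sex"] == stratum).to_numpy()
        if not mask.any():
            log.info("sex stratum %s empty; skipped", stratum)
            continue
        sub = subset_cohort(cohort, mask)
        frames.append(runner(sub, include_sex=False, sex_stratum=stratum,
                             **run_kwargs))
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def interpret(results: pd.DataFrame, threshold: float) -> dict[str, CausalVerdict]:
    """Causal-pattern verdict per outcome from the conditional-role p-values.

    Requires maternal and paternal focal roles (trio design, or pooled
    maternal- and paternal-dyad rows).  Decision rules at the corrected
    threshold: maternal association with a paternal null indicates an
    intrauterine effect; maternal and paternal associations of similar
    strength indicate postnatal/shared mechanisms; an offspring-only
    association indicates fetal pleiotropy; nothing significant is the
    null pattern; anything else is inconclusive.
    """
    verdicts: dict[str, CausalVerdict] = {}
    for outcome, grp in results.groupby("outcome", sort=False):
        sig = {role: bool((g["p"] < threshold).any())
               for role, g in grp.groupby("focal_role")}
        have = set(sig)
        if not {"maternal", "paternal"} <= have:
            verdicts[outcome] = CausalVerdict(
                "inconclusive", sig,
                reason=f"missing roles: {sorted({'maternal', 'paternal'} - have)}")
            continue
        m, p = sig["maternal"], sig["paternal"]
        o = sig.get("offspring", False)
        if not any(sig.values()):
            verdicts[outcome] = CausalVerdict("null", sig)
        elif m and not p:
            verdicts[outcome] = CausalVerdict("intrauterine_effect", sig)
        elif m and p:
            verdicts[outcome] = CausalVerdict("postnatal_shared", sig)
        elif o and not m and not p:
            verdicts[outcome] = CausalVerdict("fetal_pleiotropy", sig)
        else:
            verdicts[outcome] = CausalVerdict(
                "inconclusive", sig, reason="paternal-only association")
    return verdicts
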