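"""Allele score construction for any family role and score set.

An unweighted score is the plain count of effect alleles across a score
set; weighted scores multiply each dosage by the variant's maternal
(M sets) or fetal (F sets) per-allele effect on the birth-weight z score.
Missing dosages can be imputed at the expected dosage 2*eaf before
scoring, or scores can be rescaled to the full set size from the SNPs a
person actually has.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .snps import SnpDefinition, members, MATERNAL_SETS

log = logging.getLogger(__name__)

WEIGHTINGS = ("unweighted", "maternal_weighted", "fetal_weighted")


@dataclass
class AlleleScore:
    """Per-person score values for one (role, set, weighting) combination."""
    person_role: str
    set_id: str
    weighting: str
    values: pd.Series
    n_snps_used: int


def _set_dosages(
    dosages: pd.DataFrame, snps: list[SnpDefinition], set_id: str
) -> tuple[pd.DataFrame, list[SnpDefinition]]:
    mem = members(snps, set_id)
    present = [s for s in mem if s.snp_id in dosages.columns]
    if not present:
        raise ValueError(f"no members of set {set_id} present in the dosage matrix")
    if len(present) < len(mem):
        log.info("set %s: %d of %d member SNPs present in dosages",
                 set_id, len(present), len(mem))
    return dosages[[s.snp_id for s in present]], present


def unweighted_score(
    dosages: pd.DataFrame,
    snps: list[SnpDefinition],
    set_id: str,
    person_role: str = "offspring",
) -> AlleleScore:
    """Sum of effect-allele dosages over the named score set.

    ``dosages`` is persons x SNPs with snp_id column labels; columns not in
    the set are ignored and set members absent from the matrix are dropped
    (an error if none remain).
    """
    sub, present = _set_dosages(dosages, snps, set_id)
    return AlleleScore(person_role, set_id, "unweighted",
                       sub.sum(axis=1), len(present))


def weighted_score(
    dosages: pd.DataFrame,
    snps: list[SnpDefinition],
    set_id: str,
    weighting: str | None = None,
    person_role: str = "offspring",
) -> AlleleScore:
    """Effect-size-weighted score: sum of weight_i * dosage_i over the set.

    The weight defaults to the maternal effect for M sets and the fetal
    effect for F sets; pass ``weighting`` explicitly to override.  A zero
    weight vector yields a degenerate score and emits a warning.
    """
    if weighting is None:
        weighting = "maternal_weighted" if set_id in MATERNAL_SETS else "fetal_weighted"
    if weighting not in ("maternal_weighted", "fetal_weighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    attr = "beta_maternal" if weighting == "maternal_weighted" else "beta_fetal"
    sub, present = _set_dosages(dosages, snps, set_id)
    w = np.array([getattr(s, attr) for s in present])
    if np.all(w == 0):
        warnings.warn(f"all {attr} weights are zero for set {set_id}: degenerate score",
                      stacklevel=2)
    return AlleleScore(person_role, set_id, weighting,
                       pd.Series(sub.to_numpy() @ w, index=sub.index), len(present))


def compute_score(
    dosages: pd.DataFrame,
    snps: list[SnpDefinition],
    set_id: str,
    weighting: str = "unweighted",
    person_role: str = "offspring",
) -> AlleleScore:
    """Dispatch to the unweighted or weighted score constructor."""
    if weighting == "unweighted":
        return unweighted_score(dosages, snps, set_id, person_role)
    return weighted_score(dosages, snps, set_id, weighting, person_role)


def impute_missing_dosage(
    dosages: pd.DataFrame, snps: list[SnpDefinition]
) -> pd.DataFrame:
    """Replace missing dosage entries with the expected dosage 2*eaf.

    Expectation-preserving: a score computed after imputation has the same
    population mean as the complete-data score.  SNPs with more than 50%
    missingness are imputed anyway but logged.
    """
    eaf = {s.snp_id: s.eaf for s in snps}
    out = dosages.copy()
    for col in out.columns:
        if col not in eaf:
            continue
        frac = out[col].isna().mean()
        if frac > 0.5:
            log.warning("SNP %s has %.0f%% missing dosages", col, 100 * frac)
        if frac > 0:
            out[col] = out[col].fillna(2.0 * eaf[col])
    return out


def rescale_to_set_size(score: AlleleScore, dosages: pd.DataFrame) -> AlleleScore:
    """Alternative missingness handling: rescale per person by available SNP count.

    Multiplies each person's score by (set size) / (nonmissing member SNPs
    for that person); an all-missing person stays missing.
    """
    cols = [c for c in dosages.columns]
    n_avail = dosages[cols].notna().sum(axis=1)
    factor = score.n_snps_used / n_avail.replace(0, np.nan)
    return AlleleScore(score.person_role, score.set_id, score.weighting,
                       score.values * factor, score.n_snps_used)


def scores_table(scores: list[AlleleScore], family_id: np.ndarray) -> pd.DataFrame:
    """Long-format score table: family_id, role, set, weighting, value."""
    frames = []
    for s in scores:
        frames.append(pd.DataFrame({
            "family_id": np.asarray(family_id),
            "role": s.person_role,
            "set": s.set_id,
            "weighting": s.weighting,
            "value": s.values.to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)
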