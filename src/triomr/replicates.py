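"""Monte-Carlo replicate studies over synthetic cohorts.

These helpers repeatedly draw cohorts from a scenario, push each through
the scoring + conditional-model pipeline (identity-GRM fast path, since
replicate cohorts contain no relatedness), and collect per-replicate
estimates.  They back the package's calibration, parameter-recovery,
mechanism-discrimination and negative-control checks.

Replicate cohorts are generated lean — a single NDD outcome, no
item-level matrices — because the properties under study concern the
conditional estimators, not the questionnaire plumbing.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import pipeline, transforms
from .lmm import conditional_f
from .scores import compute_score
from .simulate import ScenarioConfig, TrioCohort, simulate_cohort
from .snps import SnpDefinition


def lean(config: ScenarioConfig, **overrides) -> ScenarioConfig:
    """Strip a scenario to one outcome without item-level data."""
    return replace(config, n_outcomes=1, item_level=False, **overrides)


def _rep_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def conditional_replicates(
    panel: list[SnpDefinition],
    config: ScenarioConfig,
    n_replicates: int,
    base_seed: int,
    design: str = "maternal_dyad",
    set_id: str = "M1",
    weighting: str = "maternal_weighted",
    rank_int: bool = True,
) -> pd.DataFrame:
    """Per-replicate conditional score estimates for every role in a design.

    Returns one row per (replicate, focal role) with beta, se, p.  With
    ``rank_int=False`` the single outcome liability is analysed on its raw
    scale, where the generative conditional maternal coefficient is exactly
    gamma_mU * delta_U_ndd for the maternal-weighted score.
    """
    frames = []
    for rep, seed in enumerate(_rep_seeds(base_seed, n_replicates)):
        cohort = simulate_cohort(panel, replace(lean(config), seed=seed))
        res = pipeline.run_mr(cohort, design=design, set_id=set_id,
                              weighting=weighting, grm=None, rank_int=rank_int)
        res.insert(0, "rep", rep)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def rejection_rate(results: pd.DataFrame, role: str, alpha: float = 0.05) -> float:
    """Fraction of replicates whose focal-role p-value falls below alpha."""
    sub = results[results["focal_role"] == role]
    return float((sub["p"] < alpha).mean())


def mechanism_verdicts(
    panel: list[SnpDefinition],
    config: ScenarioConfig,
    n_replicates: int,
    base_seed: int,
    threshold: float = 0.005,
    weighting: str = "unweighted",
) -> list[str]:
    """Causal-pattern verdict per replicate from trio-design conditional models."""
    patterns = []
    for seed in _rep_seeds(base_seed, n_replicates):
        cohort = simulate_cohort(panel, replace(lean(config), seed=seed))
        res = pipeline.run_mr(cohort, design="trio", set_id="M1",
                              weighting=weighting, grm=None)
        verdict = pipeline.interpret(res, threshold)
        patterns.append(next(iter(verdict.values())).pattern)
    return patterns


def paternal_selection_study(
    panel: list[SnpDefinition],
    config: ScenarioConfig,
    n_replicates: int,
    base_seed: int,
    missing_father_fraction: float = 0.4,
    selection_strength: float = 1.0,
    weighting: str = "fetal_weighted",
) -> pd.DataFrame:
    """Paternal-dyad paternal coefficient under random vs selective father dropout.

    Each replicate cohort is thinned twice from the same full-trio draw:
    once with fathers missing at random and once with missingness tracking
    the paternal liability (the collider mechanism).  Returns rows
    (rep, mode, beta, se, p) for the paternal conditional coefficient.
    """
    from .simulate import apply_design

    rows = []
    for rep, seed in enumerate(_rep_seeds(base_seed, n_replicates)):
        cfg = replace(lean(config), seed=seed,
                      missing_father_fraction=0.0, missing_mother_fraction=0.0)
        cohort = simulate_cohort(panel, cfg)
        for mode, select in (("random", False), ("selective", True)):
            # keep families whose father is retained: invert the dropout flag
            thinned = apply_design(
                cohort, missing_father_fraction, 0.0, seed + 1,
                select_on_father=select, selection_strength=selection_strength)
            res = pipeline.run_mr(thinned, design="paternal_dyad", set_id="F1",
                                  weighting=weighting, grm=None)
            sub = res[res["focal_role"] == "paternal"].iloc[0]
            rows.append({"rep": rep, "mode": mode, "beta": sub["beta"],
                         "se": sub["se"], "p": sub["p"]})
    return pd.DataFrame(rows)


def fetal_score_variance(panel: list[SnpDefinition]) -> float:
    """Population variance of the fetal-weighted score under HWE."""
    return float(sum(s.beta_fetal ** 2 * 2 * s.eaf * (1 - s.eaf) for s in panel))


def strong_instrument_config(
    panel: list[SnpDefinition], r2: float = 0.02, n_families: int = 10_000
) -> ScenarioConfig:
    """Scenario in which the offspring fetal score explains ``r2`` of birth weight.

    Only the direct fetal path is active; the residual SD is solved from
    the panel's score variance so the score's population R^2 on the
    birth-weight z scale equals the requested value (gestational-age
    variance contribution included).
    """
    v = fetal_score_variance(panel)
    ga_var = (0.1 ** 2) * (1.5 ** 2)  # covariate contribution to bw z
    sigma2 = v * (1.0 - r2) / r2 - ga_var
    if sigma2 <= 0:
        raise ValueError("requested R^2 too large for this panel")
    return ScenarioConfig(n_families=n_families, beta_fetal_scale=1.0,
                          sigma_bw=float(np.sqrt(sigma2)),
                          n_outcomes=1, item_level=False)


def instrument_strength_replicates(
    panel: list[SnpDefinition],
    config: ScenarioConfig,
    n_replicates: int,
    base_seed: int,
) -> np.ndarray:
    """Conditional F of the offspring fetal score for birth weight, per replicate.

    The exposure is sex-stratified birth-weight z; the instrument is the
    offspring fetal-weighted score conditioned on the maternal and paternal
    scores plus the standard covariates.
    """
    fs = []
    for seed in _rep_seeds(base_seed, n_replicates):
        cohort = simulate_cohort(panel, replace(lean(config), seed=seed))
        ph = cohort.phenotypes
        bwz = transforms.sex_stratified_z(ph["birth_weight_kg"].to_numpy(),
                                          ph["sex"].to_numpy())
        s_o = compute_score(cohort.dosages("offspring"), panel, "F1",
                            "fetal_weighted").values.to_numpy()
        s_m = compute_score(cohort.dosages("mother"), panel, "F1",
                            "fetal_weighted").values.to_numpy()
        s_f = compute_score(cohort.dosages("father"), panel, "F1",
                            "fetal_weighted").values.to_numpy()
        cov, _ = pipeline.covariate_matrix(ph)
        fs.append(conditional_f(bwz, s_o, [s_m, s_f], cov[:, 1:]))
    return np.array(fs)
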