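"""Synthetic parent-offspring trio cohorts under configurable causal scenarios.

The generator emulates the statistical structure the within-family
Mendelian randomization design assumes: parents drawn in Hardy-Weinberg
equilibrium at independent loci, offspring genotypes produced by Mendelian
transmission, birth weight driven by both maternal-acting (via a latent
intrauterine factor U) and fetal-acting variant effects, and
neurodevelopmental (NDD) outcomes generated under one of five causal
scenarios:

* ``null`` — no genetic or confounding path touches the outcomes;
* ``intrauterine_causal`` — U causally raises NDD liability (the
  developmental-origins path: maternal score -> U -> NDD);
* ``fetal_pleiotropic`` — the offspring's own fetal-effect score acts on
  NDD liability directly (pleiotropy through the offspring genome);
* ``postnatal_paternal`` — the paternal score acts on NDD via the
  postnatal environment;
* ``confounding`` — a shared family confounder loads on both birth
  weight and NDD with no causal path between them.

Latent model per child (z denotes the birth-weight z scale)::

    U   = gamma_mU * sum_i beta_maternal_i * G_m,i + N(0, 1)
    bwz = delta_U_bw * U + beta_fetal_scale * sum_i beta_fetal_i * G_o,i
          + rho_confound * C + 0.1 * (gestational_age - 39.5) + N(0, sigma_bw)
    L_k = delta_U_ndd * U + theta_pleio * sum_i beta_fetal_i * G_o,i
          + theta_pat * sum_i beta_fetal_i * G_f,i + rho_confound * C
          + covariate terms + e_k

with C a per-family standard-normal confounder shared by siblings and
e_k equicorrelated noise across the outcomes (default correlation 0.4).
Birth weight in kg is mapped from bwz with sex-specific means (3.6 kg
male / 3.5 kg female) and SD 0.45 kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .snps import SnpDefinition

ROLES = ("mother", "father", "offspring")
DESIGNS = ("trio", "maternal_dyad", "paternal_dyad")

#: the 20 questionnaire outcomes (instrument_age), as analysed in childhood cohorts
OUTCOME_NAMES = [
    "SCQ-full_3y", "SCQ-full_8y", "SCQ-RRB_3y", "SCQ-RRB_8y",
    "SCQ-SCI_3y", "SCQ-SCI_8y",
    "CBCL-ADHD_18m", "CBCL-ADHD_3y", "CBCL-ADHD_5y",
    "RS-DBD-ADHD_8y", "RS-DBD-INA_8y", "RS-DBD-HYP_8y", "CPRS_5y",
    "ASQ-LANG_18m", "ASQ-LANG_3y", "ASQ-LANG_5y", "CCC-S_8y",
    "ASQ-MOTOR_18m", "ASQ-MOTOR_3y", "CDI-MOTOR_5y",
]

# fixed, small covariate effects (they exist to exercise adjustment code)
GA_EFFECT_BW = 0.1          # birth-weight z per gestational week beyond 39.5
SEX_EFFECT_NDD = 0.15       # male offset on NDD liability
YEAR_EFFECT_NDD = 0.01      # per birth year beyond 2004
MATAGE_EFFECT_NDD = 0.005   # per maternal year beyond 30.1
BATCH_EFFECT_NDD = {"b1": 0.0, "b2": 0.05, "b3": -0.05}
BW_MEAN_KG = {"M": 3.6, "F": 3.5}
BW_SD_KG = 0.45


@dataclass
class ScenarioConfig:
    """Parameters of the generative model; defaults are the null scenario."""

    n_families: int = 1000
    seed: int = 0
    gamma_mU: float = 0.0          # maternal true score -> latent intrauterine factor U
    delta_U_bw: float = 0.0        # U -> birth-weight z
    delta_U_ndd: float = 0.0       # U -> NDD liability (developmental-origins path)
    beta_fetal_scale: float = 0.0  # multiplier on fetal effects for birth weight
    theta_pleio: float = 0.0       # offspring fetal score -> NDD (pleiotropy)
    theta_pat: float = 0.0         # paternal fetal score -> NDD (postnatal path)
    rho_confound: float = 0.0      # family confounder loading on bwz and NDD
    sigma_bw: float = 0.8
    sigma_ndd: float = 1.0
    sib_fraction: float = 0.0
    missing_father_fraction: float = 0.0
    missing_mother_fraction: float = 0.0
    item_missing_rate: float = 0.0
    n_outcomes: int = 20
    outcome_corr: float = 0.4
    item_level: bool = True
    n_items: int = 10
    sigma_item: float = 1.5
    select_on_father: bool = False   # paternal missingness tracks paternal liability
    selection_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        for name in ("sib_fraction", "missing_father_fraction",
                     "missing_mother_fraction", "item_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.missing_father_fraction + self.missing_mother_fraction > 1.0:
            raise ValueError("missingness fractions sum to more than 1")
        if self.sigma_bw <= 0 or self.sigma_ndd <= 0 or self.sigma_item <= 0:
            raise ValueError("standard deviations must be positive")
        if not 1 <= self.n_outcomes <= len(OUTCOME_NAMES):
            raise ValueError(f"n_outcomes must lie in [1, {len(OUTCOME_NAMES)}]")
        if not 0.0 <= self.outcome_corr < 1.0:
            raise ValueError("outcome_corr must lie in [0, 1)")

    # -- scenario presets (effect sizes documented in docs/methods.md) ----
    @classmethod
    def null(cls, **kw) -> "ScenarioConfig":
        return cls(**kw)

    @classmethod
    def intrauterine_causal(cls, **kw) -> "ScenarioConfig":
        return cls(gamma_mU=3.0, delta_U_bw=0.5, delta_U_ndd=0.5,
                   beta_fetal_scale=1.0, **kw)

    @classmethod
    def fetal_pleiotropic(cls, **kw) -> "ScenarioConfig":
        return cls(gamma_mU=3.0, delta_U_bw=0.5, beta_fetal_scale=1.0,
                   theta_pleio=-1.0, **kw)

    @classmethod
    def postnatal_paternal(cls, **kw) -> "ScenarioConfig":
        return cls(gamma_mU=3.0, delta_U_bw=0.5, beta_fetal_scale=1.0,
                   theta_pat=1.0, **kw)

    @classmethod
    def confounding(cls, **kw) -> "ScenarioConfig":
        return cls(gamma_mU=3.0, delta_U_bw=0.5, beta_fetal_scale=1.0,
                   rho_confound=0.5, **kw)

    def outcome_names(self) -> list[str]:
        return OUTCOME_NAMES[: self.n_outcomes]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrioCohort:
    """Aligned genotype matrices and phenotypes, one row per child.

    Sibling rows repeat their parents' genotype rows; ``family_index``
    maps each child row to its family ordinal (0..n_families-1) and
    ``design`` records which members are observed for that family.
    """

    snps: list[SnpDefinition]
    family_id: np.ndarray
    child_id: np.ndarray
    family_index: np.ndarray
    G_m: np.ndarray
    G_f: np.ndarray
    G_o: np.ndarray
    phenotypes: pd.DataFrame
    liabilities: pd.DataFrame
    items: dict[str, np.ndarray] = field(default_factory=dict)
    design: np.ndarray | None = None
    config: ScenarioConfig | None = None
    latents: pd.DataFrame | None = None  # generator-internal truths (U, C, true scores)

    def __post_init__(self) -> None:
        n = len(self.family_id)
        for mat in (self.G_m, self.G_f, self.G_o):
            if mat.shape != (n, len(self.snps)):
                raise ValueError("genotype matrices must be children x SNPs, aligned")
        if len(self.phenotypes) != n:
            raise ValueError("phenotype table misaligned with genotype rows")
        if self.design is None:
            self.design = np.full(n, "trio", dtype=object)

    @property
    def n_children(self) -> int:
        return len(self.family_id)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def dosages(self, role: str) -> pd.DataFrame:
        """Dosage matrix for one family role as a snp_id-labelled DataFrame."""
        mat = {"mother": self.G_m, "father": self.G_f, "offspring": self.G_o}[role]
        return pd.DataFrame(mat, columns=self.snp_ids, index=self.phenotypes.index)

    def design_mask(self, design: str) -> np.ndarray:
        """Child rows usable under a given analysis design.

        Dyad analyses include full trios (the relevant parent is observed);
        the trio analysis requires both parents.
        """
        if design not in DESIGNS:
            raise ValueError(f"unknown design {design!r}")
        d = np.asarray(self.design)
        if design == "trio":
            return d == "trio"
        if design == "maternal_dyad":
            return (d == "trio") | (d == "maternal_dyad")
        return (d == "trio") | (d == "paternal_dyad")


def simulate_parents(
    n_families: int, snps: list[SnpDefinition], seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw maternal and paternal genotypes in HWE at each variant's eaf.

    Loci are independent (the score panel is assumed LD-pruned), so each
    column is Binomial(2, eaf) per parent.
    """
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(seed)
    eaf = np.array([s.eaf for s in snps])
    G_m = rng.binomial(2, eaf, size=(n_families, len(snps))).astype(float)
    G_f = rng.binomial(2, eaf, size=(n_families, len(snps))).astype(float)
    return G_m, G_f


def transmit(G_m: np.ndarray, G_f: np.ndarray, seed: int) -> np.ndarray:
    """Mendelian transmission: one allele from each parent, independently per SNP.

    The allele transmitted by a parent with genotype g in {0, 1, 2} is
    Bernoulli(g / 2).  Fractional parental genotypes are rejected —
    transmission is undefined for imputed dosages.
    """
    G_m = np.asarray(G_m, float)
    G_f = np.asarray(G_f, float)
    if G_m.shape != G_f.shape:
        raise ValueError("parental matrices must be aligned")
    for name, G in (("maternal", G_m), ("paternal", G_f)):
        if not np.all(np.mod(G, 1) == 0):
            raise ValueError(f"{name} genotypes are fractional; transmission undefined")
    rng = np.random.default_rng(seed)
    a_m = rng.random(G_m.shape) < G_m / 2.0
    a_f = rng.random(G_f.shape) < G_f / 2.0
    return (a_m.astype(float) + a_f.astype(float))


def true_scores(
    G: np.ndarray, snps: list[SnpDefinition], which: str
) -> np.ndarray:
    """Generative weighted score: sum of beta_maternal or beta_fetal times dosage."""
    betas = np.array([getattr(s, f"beta_{which}") for s in snps])
    return np.asarray(G, float) @ betas


def simulate_phenotypes(
    G_m: np.ndarray,
    G_f: np.ndarray,
    G_o: np.ndarray,
    family_index: np.ndarray,
    snps: list[SnpDefinition],
    config: ScenarioConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, np.ndarray], pd.DataFrame]:
    """Generate covariates, birth weight and NDD outcomes from the latent model.

    Returns the phenotype/covariate table, the outcome liability table,
    (when ``config.item_level``) per-outcome item response matrices, and a
    table of generator-internal latent truths (U, the family confounder C,
    the birth-weight z and the three true weighted scores).
    """
    rng = np.random.default_rng(seed)
    n = G_o.shape[0]
    n_fam = int(np.max(family_index)) + 1

    sex = np.where(rng.random(n) < 0.5, "M", "F")
    ga = np.clip(rng.normal(39.5, 1.5, n), 30.0, 43.0)
    birth_year = rng.integers(1999, 2010, n)
    maternal_age = np.clip(rng.normal(30.1, 4.5, n_fam), 18, 45)[family_index]
    paternal_age = np.clip(rng.normal(32.5, 5.1, n_fam), 18, 60)[family_index]
    batch = rng.choice(["b1", "b2", "b3"], n)
    anomaly = rng.random(n) < 0.02
    multiple = rng.random(n) < 0.015

    # true weighted scores, centred at their HWE population expectation so the
    # latent factors (and hence the kg scale) are mean-centred; slopes unchanged
    mu_m = sum(s.beta_maternal * 2 * s.eaf for s in snps)
    mu_f = sum(s.beta_fetal * 2 * s.eaf for s in snps)
    S_m_true = true_scores(G_m, snps, "maternal") - mu_m
    S_o_fet = true_scores(G_o, snps, "fetal") - mu_f
    S_f_fet = true_scores(G_f, snps, "fetal") - mu_f

    U = config.gamma_mU * S_m_true + rng.standard_normal(n)
    C = rng.standard_normal(n_fam)[family_index]  # shared family confounder

    bwz = (config.delta_U_bw * U
           + config.beta_fetal_scale * S_o_fet
           + config.rho_confound * C
           + GA_EFFECT_BW * (ga - 39.5)
           + rng.normal(0.0, config.sigma_bw, n))
    bw_kg = np.where(sex == "M", BW_MEAN_KG["M"], BW_MEAN_KG["F"]) + BW_SD_KG * bwz

    base = (config.delta_U_ndd * U
            + config.theta_pleio * S_o_fet
            + config.theta_pat * S_f_fet
            + config.rho_confound * C
            + SEX_EFFECT_NDD * (sex == "M")
            + YEAR_EFFECT_NDD * (birth_year - 2004)
            + MATAGE_EFFECT_NDD * (maternal_age - 30.1)
            + np.vectorize(BATCH_EFFECT_NDD.get)(batch))

    names = config.outcome_names()
    r = config.outcome_corr
    shared = rng.standard_normal(n)
    noise = (np.sqrt(r) * shared[:, None]
             + np.sqrt(1.0 - r) * rng.standard_normal((n, len(names))))
    liab = base[:, None] + config.sigma_ndd * noise
    liabilities = pd.DataFrame(liab, columns=names)

    items: dict[str, np.ndarray] = {}
    if config.item_level:
        for j, name in enumerate(names):
            resp = liab[:, [j]] + rng.normal(0.0, config.sigma_item,
                                             (n, config.n_items))
            if config.item_missing_rate > 0:
                mask = rng.random(resp.shape) < config.item_missing_rate
                resp = np.where(mask, np.nan, resp)
            items[name] = resp

    phenotypes = pd.DataFrame({
        "sex": sex,
        "birth_year": birth_year,
        "gestational_age_weeks": ga,
        "maternal_age": maternal_age,
        "paternal_age": paternal_age,
        "batch": batch,
        "congenital_anomaly": anomaly,
        "multiple_birth": multiple,
        "birth_weight_kg": bw_kg,
    })
    latents = pd.DataFrame({
        "U": U, "C": C, "bwz": bwz,
        "S_m_true": S_m_true, "S_o_fetal": S_o_fet, "S_f_fetal": S_f_fet,
    })
    return phenotypes, liabilities, items, latents


def apply_design(
    cohort: TrioCohort,
    missing_father_fraction: float,
    missing_mother_fraction: float,
    seed: int,
    select_on_father: bool = False,
    selection_strength: float = 0.0,
) -> TrioCohort:
    """Mark families as trios or dyads; optionally with selective paternal dropout.

    In random mode each family is independently assigned
    maternal_dyad / paternal_dyad / trio with the given probabilities.  In
    selection mode paternal presence depends on a paternal liability

        L_f = selection_strength * (z(paternal fetal score) + C*) + N(0, 1)

    where C* is a standard-normal proxy correlated with the family
    confounder entering the outcomes; fathers in the top
    ``missing_father_fraction`` quantile of L_f drop out.  Conditioning the
    retained sample on this common effect of paternal score and confounder
    is the collider mechanism hypothesised to bias paternal-dyad
    negative-control estimates.
    """
    if missing_father_fraction + missing_mother_fraction > 1.0:
        raise ValueError("missingness fractions sum to more than 1")
    rng = np.random.default_rng(seed)
    n_fam = int(np.max(cohort.family_index)) + 1
    design_fam = np.full(n_fam, "trio", dtype=object)

    if select_on_father and missing_father_fraction > 0:
        # paternal fetal score per family (first-born row of each family)
        first = np.zeros(n_fam, dtype=int)
        first[cohort.family_index[::-1]] = np.arange(cohort.n_children)[::-1]
        S_f = true_scores(cohort.G_f[first], cohort.snps, "fetal")
        z = (S_f - S_f.mean()) / (S_f.std() if S_f.std() > 0 else 1.0)
        if cohort.latents is not None:
            conf = cohort.latents["C"].to_numpy()[first]
        else:
            conf = rng.standard_normal(n_fam)
        L_f = selection_strength * (z + conf) + rng.standard_normal(n_fam)
        cut = np.quantile(L_f, 1.0 - missing_father_fraction)
        father_missing = L_f > cut
        u = rng.random(n_fam)
        mother_missing = ~father_missing & (
            u < missing_mother_fraction / max(1.0 - missing_father_fraction, 1e-12))
    else:
        u = rng.random(n_fam)
        father_missing = u < missing_father_fraction
        mother_missing = (u >= missing_father_fraction) & (
            u < missing_father_fraction + missing_mother_fraction)

    design_fam[father_missing] = "maternal_dyad"
    design_fam[mother_missing] = "paternal_dyad"
    return replace(cohort, design=design_fam[cohort.family_index])


def simulate_cohort(snps: list[SnpDefinition], config: ScenarioConfig) -> TrioCohort:
    """End-to-end cohort generation under one scenario configuration.

    Sibling families (the first ``sib_fraction`` of families) contribute a
    second offspring by an independent Mendelian transmission from the same
    parents; child rows are ordered first-borns then second-borns.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    n_fam = config.n_families
    G_m_fam, G_f_fam = simulate_parents(n_fam, snps, seeds[0])
    n_sib = int(round(config.sib_fraction * n_fam))
    family_index = np.concatenate([np.arange(n_fam), np.arange(n_sib)]).astype(int)

    G_m = G_m_fam[family_index]
    G_f = G_f_fam[family_index]
    G_o = transmit(G_m, G_f, seeds[1])

    phenotypes, liabilities, items, latents = simulate_phenotypes(
        G_m, G_f, G_o, family_index, snps, config, seeds[2])

    fam_ids = np.array([f"fam{i:06d}" for i in range(n_fam)])
    birth_order = np.concatenate([np.ones(n_fam, int), np.full(n_sib, 2, int)])
    child_id = np.array([f"{fam_ids[f]}_c{b}" for f, b in zip(family_index, birth_order)])
    phenotypes.insert(0, "family_id", fam_ids[family_index])
    phenotypes.insert(1, "child_id", child_id)

    cohort = TrioCohort(
        snps=list(snps),
        family_id=fam_ids[family_index],
        child_id=child_id,
        family_index=family_index,
        G_m=G_m, G_f=G_f, G_o=G_o,
        phenotypes=phenotypes,
        liabilities=liabilities,
        items=items,
        config=config,
        latents=latents,
    )
    if config.missing_father_fraction or config.missing_mother_fraction:
        cohort = apply_design(
            cohort, config.missing_father_fraction, config.missing_mother_fraction,
            seeds[3], select_on_father=config.select_on_father,
            selection_strength=config.selection_strength)
    return cohort


@dataclass
class BackgroundLoci:
    """Genome-wide background genotypes for GRM construction (offspring rows)."""
    G_o: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray


def simulate_background(
    cohort: TrioCohort, n_loci: int = 5000, seed: int = 0
) -> BackgroundLoci:
    """Simulate independent background loci on a synthetic map and transmit them.

    Parental background genotypes are drawn in HWE per family and
    transmitted independently to each child, so sibling rows acquire the
    expected 0.5 genome-wide relatedness while all other pairs are
    unrelated.  Loci are independent of the score panel.
    """
    rng = np.random.default_rng(seed)
    n_fam = int(np.max(cohort.family_index)) + 1
    q = rng.uniform(0.05, 0.95, n_loci)
    chrom = rng.integers(1, 23, n_loci)
    pos = rng.integers(1, 250_000_000, n_loci)
    Gm = rng.binomial(2, q, size=(n_fam, n_loci)).astype(float)
    Gf = rng.binomial(2, q, size=(n_fam, n_loci)).astype(float)
    Go = transmit(Gm[cohort.family_index], Gf[cohort.family_index],
                  int(rng.integers(2**31)))
    return BackgroundLoci(G_o=Go, chrom=chrom, pos_bp=pos)
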