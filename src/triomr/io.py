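"""Plain-text persistence of cohorts, scores, results and reports.

Everything is tab-separated or key:value text so that same-seed runs are
byte-identical and files remain inspectable.  Item-level questionnaire
matrices are not persisted; the phenotype table carries the scored
scales, which is what downstream analysis consumes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pipeline
from .simulate import ScenarioConfig, TrioCohort
from .snps import load_snp_table, write_snp_table

FLOAT_FMT = "%.10g"


def write_cohort(cohort: TrioCohort, directory) -> None:
    """Write a cohort as snps.tsv, per-role dosage tables, phenotypes.tsv, config.yaml."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_snp_table(cohort.snps, d / "snps.tsv")
    for role in ("mother", "father", "offspring"):
        dos = cohort.dosages(role).copy()
        dos.insert(0, "child_id", cohort.child_id)
        dos.insert(0, "family_id", cohort.family_id)
        dos.to_csv(d / f"dosages_{role}.tsv", sep="\t", index=False,
                   float_format=FLOAT_FMT)
    ph = cohort.phenotypes.copy()
    ph["design"] = np.asarray(cohort.design)
    outcomes = pipeline.outcome_scores(cohort)
    for col in outcomes.columns:
        ph[f"outcome:{col}"] = outcomes[col].to_numpy()
    ph.to_csv(d / "phenotypes.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    if cohort.config is not None:
        with open(d / "config.yaml", "w") as fh:
            yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)


def read_cohort(directory) -> TrioCohort:
    """Re-read a cohort written by :func:`write_cohort`.

    Outcome columns come back as the liability table (scored scales);
    item matrices are not round-tripped.
    """
    d = Path(directory)
    snps = load_snp_table(d / "snps.tsv")
    snp_ids = [s.snp_id for s in snps]
    mats = {}
    meta = None
    for role in ("mother", "father", "offspring"):
        df = pd.read_csv(d / f"dosages_{role}.tsv", sep="\t")
        if meta is None:
            meta = df[["family_id", "child_id"]]
        mats[role] = df[snp_ids].to_numpy(float)
    ph = pd.read_csv(d / "phenotypes.tsv", sep="\t")
    design = ph.pop("design").to_numpy(dtype=object)
    out_cols = [c for c in ph.columns if c.startswith("outcome:")]
    liabilities = ph[out_cols].rename(columns=lambda c: c.split(":", 1)[1])
    ph = ph.drop(columns=out_cols)

    fam = meta["family_id"].to_numpy()
    _, family_index = np.unique(fam, return_inverse=True)
    config = None
    cfg_path = d / "config.yaml"
    if cfg_path.exists():
        with open(cfg_path) as fh:
            config = ScenarioConfig(**yaml.safe_load(fh))
    return TrioCohort(
        snps=snps,
        family_id=fam,
        child_id=meta["child_id"].to_numpy(),
        family_index=family_index,
        G_m=mats["mother"], G_f=mats["father"], G_o=mats["offspring"],
        phenotypes=ph,
        liabilities=liabilities,
        design=design,
        config=config,
    )


def write_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("set_id", "weighting", "sex_stratum"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def write_verdicts(verdicts: dict, path) -> None:
    rows = [{"outcome": k, "pattern": v.pattern, "reason": v.reason,
             **{f"sig_{r}": s for r, s in sorted(v.evidence.items())}}
            for k, v in verdicts.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def table1_layout(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot long results into the per-set wide layout of the headline table.

    Rows are (focal role, outcome); per score set the columns give n,
    beta, SE and p.
    """
    df = results.copy()
    wide = df.pivot_table(
        index=["focal_role", "outcome"], columns="set_id",
        values=["n", "beta", "se", "p"], aggfunc="first", sort=False)
    wide.columns = [f"{set_id}_{stat}" for stat, set_id in wide.columns]
    return wide.reset_index()
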