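"""Birth-weight variant panels with maternal/fetal effect partitioning.

A genome-wide association study of birth weight resolves, for each
associated SNP, how much of its association acts through the maternal
genome (the intrauterine environment) and how much through the fetal
genome (direct growth effects).  Six overlapping, nested score sets are
built from that partition:

* ``M1`` / ``F1`` — every birth-weight-associated SNP;
* ``M2`` / ``F2`` — SNPs with evidence of a maternal (resp. fetal)
  association with birth weight;
* ``M3`` / ``F3`` — SNPs with a maternal-only (resp. fetal-only)
  association.

Nesting holds by construction: M3 ⊆ M2 ⊆ M1 and F3 ⊆ F2 ⊆ F1, and the
"-only" sets M3 and F3 are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields

import numpy as np
import pandas as pd

VALID_BASES = frozenset("ACGT")
SCORE_SETS = ("M1", "M2", "M3", "F1", "F2", "F3")
MATERNAL_SETS = ("M1", "M2", "M3")
FETAL_SETS = ("F1", "F2", "F3")

#: columns of the on-disk SNP definition table (tab-separated, 1-based positions)
TABLE_COLUMNS = [
    "snp_id", "chrom", "pos_bp", "effect_allele", "other_allele",
    "eaf", "beta_maternal", "beta_fetal",
    "in_M2", "in_M3", "in_F2", "in_F3",
]


@dataclass(frozen=True)
class SnpDefinition:
    """One autosomal birth-weight variant with its partitioned effects.

    ``beta_maternal`` / ``beta_fetal`` are per-effect-allele effects on the
    birth-weight z score acting through the maternal and fetal genome
    respectively.  Set membership is stored explicitly for sets 2 and 3;
    every variant belongs to M1 and F1.
    """

    snp_id: str
    chrom: int
    pos_bp: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta_maternal: float
    beta_fetal: float
    in_M2: bool = False
    in_M3: bool = False
    in_F2: bool = False
    in_F3: bool = False

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES:
            raise ValueError(f"{self.snp_id}: malformed effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_BASES:
            raise ValueError(f"{self.snp_id}: malformed other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not 1 <= int(self.chrom) <= 22:
            raise ValueError(f"{self.snp_id}: non-autosomal chromosome {self.chrom}")
        if self.pos_bp < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1 (1-based)")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.snp_id}: eaf {self.eaf} outside (0, 1)")
        if self.in_M3 and not self.in_M2:
            raise ValueError(f"{self.snp_id}: M3 membership requires M2 (nested sets)")
        if self.in_F3 and not self.in_F2:
            raise ValueError(f"{self.snp_id}: F3 membership requires F2 (nested sets)")
        if self.in_M3 and self.in_F3:
            raise ValueError(f"{self.snp_id}: maternal-only and fetal-only are exclusive")

    @property
    def snp_class(self) -> str:
        """Effect classification: maternal_only / fetal_only / both / unclassified."""
        if self.in_M3:
            return "maternal_only"
        if self.in_F3:
            return "fetal_only"
        if self.in_M2 and self.in_F2:
            return "both"
        return "unclassified"

    def in_set(self, set_id: str) -> bool:
        if set_id in ("M1", "F1"):
            return True
        if set_id == "M2":
            return self.in_M2
        if set_id == "M3":
            return self.in_M3
        if set_id == "F2":
            return self.in_F2
        if set_id == "F3":
            return self.in_F3
        raise ValueError(f"unknown score set {set_id!r}; expected one of {SCORE_SETS}")


def members(snps: list[SnpDefinition], set_id: str) -> list[SnpDefinition]:
    """Subset of ``snps`` belonging to the named score set (M1..F3)."""
    if set_id not in SCORE_SETS:
        raise ValueError(f"unknown score set {set_id!r}; expected one of {SCORE_SETS}")
    return [s for s in snps if s.in_set(set_id)]


def load_snp_table(path) -> list[SnpDefinition]:
    """Read a tab-separated SNP definition table into validated definitions.

    Raises ``ValueError`` naming the offending row on any malformed entry
    and rejects duplicated ``snp_id``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str},
                     float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table {path} lacks required columns: {missing}")
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated snp_id in {path}: {sorted(set(dup))}")
    out: list[SnpDefinition] = []
    for idx, row in df.iterrows():
        try:
            out.append(SnpDefinition(
                snp_id=str(row["snp_id"]),
                chrom=int(row["chrom"]),
                pos_bp=int(row["pos_bp"]),
                effect_allele=str(row["effect_allele"]),
                other_allele=str(row["other_allele"]),
                eaf=float(row["eaf"]),
                beta_maternal=float(row["beta_maternal"]),
                beta_fetal=float(row["beta_fetal"]),
                in_M2=bool(row["in_M2"]),
                in_M3=bool(row["in_M3"]),
                in_F2=bool(row["in_F2"]),
                in_F3=bool(row["in_F3"]),
            ))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"invalid SNP table row {idx} ({row.get('snp_id')}): {exc}") from exc
    return out


def write_snp_table(snps: list[SnpDefinition], path) -> None:
    """Write definitions as the tab-separated table dialect read by load_snp_table."""
    rows = [{f.name: getattr(s, f.name) for f in fields(SnpDefinition)} for s in snps]
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def to_frame(snps: list[SnpDefinition]) -> pd.DataFrame:
    """Definitions as a DataFrame indexed by snp_id (columns as on disk)."""
    df = pd.DataFrame([asdict(s) for s in snps], columns=TABLE_COLUMNS)
    return df.set_index("snp_id", drop=False)


def synthetic_panel(
    seed: int = 0,
    n_total: int = 205,
    n_m2: int = 71,
    n_m3: int = 31,
    n_f2: int = 143,
    n_f3: int = 63,
    beta_scale: float = 0.02,
) -> list[SnpDefinition]:
    """Synthetic variant panel reproducing the nested set sizes of the study panel.

    The real panel (variant identities, positions, weights) is not public in
    a machine-readable form, so this generator emits a panel with the same
    membership structure — defaults give 205 variants total with 71 in M2,
    31 in M3, 143 in F2 and 63 in F3 — random allele frequencies, and
    half-normal per-allele effects oriented so that the effect allele is the
    birth-weight-increasing allele for its own set.

    Membership layout (indices): M3 occupies the first ``n_m3`` slots, the
    remaining M2 members follow, F3 follows those, and the extra F2 members
    overlap the M2-only block first (the "both" class) before using fresh
    slots.  Feasibility of the requested counts is validated.
    """
    if not (n_m3 <= n_m2 <= n_total and n_f3 <= n_f2 <= n_total):
        raise ValueError("set sizes must be nested: |set3| <= |set2| <= |set1|")
    if n_m3 + n_f3 > n_total:
        raise ValueError("M3 and F3 are disjoint; their sizes cannot exceed the total")
    rng = np.random.default_rng(seed)

    in_m2 = np.zeros(n_total, bool)
    in_m3 = np.zeros(n_total, bool)
    in_f2 = np.zeros(n_total, bool)
    in_f3 = np.zeros(n_total, bool)
    in_m3[:n_m3] = True
    in_m2[:n_m2] = True
    # F3 (fetal-only) is disjoint from M2 (any maternal association), so it
    # needs its own block after the M2 members
    f3_lo = n_m2
    if f3_lo + n_f3 > n_total:
        raise ValueError("requested sizes leave no room for an F3 block disjoint from M2")
    in_f3[f3_lo:f3_lo + n_f3] = True
    in_f2[f3_lo:f3_lo + n_f3] = True
    # remaining F2 members: overlap the M2-only block first ("both" class), then fresh slots
    need = n_f2 - n_f3
    both = min(need, n_m2 - n_m3)
    in_f2[n_m3:n_m3 + both] = True
    need -= both
    fresh_lo = f3_lo + n_f3
    if need > n_total - fresh_lo:
        raise ValueError("requested F2 size does not fit in the panel")
    in_f2[fresh_lo:fresh_lo + need] = True

    eaf = rng.uniform(0.05, 0.95, n_total)
    # oriented (positive) effects where a set-2 association exists; near-null noise otherwise
    beta_m = np.where(in_m2, np.abs(rng.normal(0.0, beta_scale, n_total)) + 0.005,
                      rng.normal(0.0, beta_scale / 5, n_total))
    beta_f = np.where(in_f2, np.abs(rng.normal(0.0, beta_scale, n_total)) + 0.005,
                      rng.normal(0.0, beta_scale / 5, n_total))
    beta_f[in_m3] = rng.normal(0.0, beta_scale / 10, int(in_m3.sum()))  # maternal-only
    beta_m[in_f3] = rng.normal(0.0, beta_scale / 10, int(in_f3.sum()))  # fetal-only

    alleles = np.array(list("ACGT"))
    snps = []
    for i in range(n_total):
        ea, oa = rng.choice(alleles, size=2, replace=False)
        snps.append(SnpDefinition(
            snp_id=f"rs{100000 + i}",
            chrom=1 + i % 22,
            pos_bp=5_000_000 + (i // 22) * 12_000_000,
            effect_allele=str(ea),
            other_allele=str(oa),
            eaf=float(eaf[i]),
            beta_maternal=float(beta_m[i]),
            beta_fetal=float(beta_f[i]),
            in_M2=bool(in_m2[i]),
            in_M3=bool(in_m3[i]),
            in_F2=bool(in_f2[i]),
            in_F3=bool(in_f3[i]),
        ))
    return snps


def replicate_panel(
    n_snps: int = 50,
    seed: int = 0,
    beta_maternal_sd: float = 0.03,
    beta_fetal_sd: float = 0.05,
) -> list[SnpDefinition]:
    """Compact panel for Monte-Carlo replicate studies.

    All variants sit in M1/F1 only, with positive half-normal per-allele
    effects (effect alleles oriented to increase birth weight) and
    intermediate allele frequencies.  Default effect scales put the
    maternal score at roughly 2% and the fetal score at roughly 5% of
    birth-weight variance for 50 SNPs, mirroring the weak-maternal /
    stronger-fetal instrument asymmetry seen in real data.
    """
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(0.2, 0.8, n_snps)
    beta_m = np.abs(rng.normal(0.0, beta_maternal_sd, n_snps))
    beta_f = np.abs(rng.normal(0.0, beta_fetal_sd, n_snps))
    alleles = np.array(list("ACGT"))
    out = []
    for i in range(n_snps):
        ea, oa = rng.choice(alleles, size=2, replace=False)
        out.append(SnpDefinition(
            snp_id=f"sim{i}",
            chrom=1 + i % 22,
            pos_bp=10_000_000 + (i // 22) * 25_000_000,
            effect_allele=str(ea),
            other_allele=str(oa),
            eaf=float(eaf[i]),
            beta_maternal=float(beta_m[i]),
            beta_fetal=float(beta_f[i]),
        ))
    return out
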