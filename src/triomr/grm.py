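"""Genetic relationship matrix from background loci, excluding score-SNP windows.

The GRM entry for individuals j and k is the average over loci of
centred, variance-scaled dosage products

    A_jk = (1/m) * sum_i (g_ij - 2 p_i)(g_ik - 2 p_i) / (2 p_i (1 - p_i))

with p_i the sample allele frequency.  Loci falling within +/- 1 Mb of
any score variant are excluded so the random effect does not absorb the
fixed-effect instruments, and monomorphic loci are dropped.  Expected
entries: ~1 on the diagonal for outbred individuals, 0.5 for full-sib
pairs, 0 for unrelated pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .snps import SnpDefinition

log = logging.getLogger(__name__)

DEFAULT_HALF_WIDTH_BP = 1_000_000


@dataclass
class Grm:
    """Symmetric relationship matrix with aligned person/family identifiers."""
    ids: np.ndarray
    matrix: np.ndarray
    n_loci_used: int

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square and aligned with ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("GRM must be symmetric")


def exclusion_windows(
    snps: list[SnpDefinition], half_width_bp: int = DEFAULT_HALF_WIDTH_BP
) -> list[tuple[int, int, int]]:
    """Half-open exclusion intervals [pos - w, pos + w) around each score SNP.

    Overlapping or touching windows on the same chromosome are merged.
    Positions are 1-based; window starts are floored at 1.
    """
    raw = sorted((s.chrom, max(1, s.pos_bp - half_width_bp), s.pos_bp + half_width_bp)
                 for s in snps)
    merged: list[tuple[int, int, int]] = []
    for chrom, lo, hi in raw:
        if merged and merged[-1][0] == chrom and lo <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(merged[-1][2], hi))
        else:
            merged.append((chrom, lo, hi))
    return merged


def in_windows(
    chrom: np.ndarray, pos_bp: np.ndarray, windows: list[tuple[int, int, int]]
) -> np.ndarray:
    """Boolean mask of loci falling inside any half-open exclusion window."""
    chrom = np.asarray(chrom)
    pos_bp = np.asarray(pos_bp)
    mask = np.zeros(chrom.shape, bool)
    for c, lo, hi in windows:
        mask |= (chrom == c) & (pos_bp >= lo) & (pos_bp < hi)
    return mask


def compute_grm(
    background_dosages: np.ndarray,
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    windows: list[tuple[int, int, int]] | None = None,
    ids: np.ndarray | None = None,
) -> Grm:
    """Centred-and-scaled GRM over the loci surviving window exclusion.

    Sample allele frequencies (not any external panel's) are used for
    centring and scaling.  Monomorphic loci are dropped with a log entry;
    if no polymorphic locus survives an error is raised.
    """
    G = np.asarray(background_dosages, float)
    n, m = G.shape
    keep = np.ones(m, bool)
    if windows:
        keep &= ~in_windows(chrom, pos_bp, windows)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 loci survive window exclusion")
    G = G[:, keep]

    p = G.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0) & (G.std(axis=0) > 0.0)
    n_mono = int((~poly).sum())
    if n_mono:
        log.info("dropping %d monomorphic loci from GRM", n_mono)
    if not poly.any():
        raise ValueError("all loci are monomorphic; GRM undefined")
    G = G[:, poly]
    p = p[poly]

    Z = (G - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    m_used = Z.shape[1]
    A = (Z @ Z.T) / m_used
    A = (A + A.T) / 2.0  # enforce exact symmetry
    if ids is None:
        ids = np.arange(n)
    return Grm(ids=np.asarray(ids), matrix=A, n_loci_used=m_used)


def save_grm(grm: Grm, prefix: str) -> None:
    """Persist as plain text: lower triangle (row col value) plus an id sidecar."""
    with open(f"{prefix}.grm.txt", "w") as fh:
        fh.write(f"# n_loci_used: {grm.n_loci_used}\n")
        n = len(grm.ids)
        for i in range(n):
            for j in range(i + 1):
                fh.write(f"{i}\t{j}\t{grm.matrix[i, j]:.10g}\n")
    with open(f"{prefix}.grm.ids", "w") as fh:
        for pid in grm.ids:
            fh.write(f"{pid}\n")


def load_grm(prefix: str) -> Grm:
    """Read a GRM persisted by :func:`save_grm`."""
    with open(f"{prefix}.grm.ids") as fh:
        ids = np.array([line.strip() for line in fh if line.strip()])
    n = len(ids)
    A = np.zeros((n, n))
    n_loci = 0
    with open(f"{prefix}.grm.txt") as fh:
        for line in fh:
            if line.startswith("#"):
                n_loci = int(line.split(":")[1])
                continue
            i_s, j_s, v_s = line.split("\t")
            i, j = int(i_s), int(j_s)
            A[i, j] = A[j, i] = float(v_s)
    return Grm(ids=ids, matrix=A, n_loci_used=n_loci)
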