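"""Multiple-testing correction from the correlation structure of the outcomes.

Questionnaire outcomes measured repeatedly across ages are strongly
correlated, so a Bonferroni correction over their raw count is too harsh.
The corrected threshold here divides 0.05 by an effective number of
independent tests derived from the eigenvalues of the outcome correlation
matrix.  Two rules are provided:

* ``lji`` (default): the eigenvalue-magnitude estimate
  Meff = sum_i [ I(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ];
* ``pc995``: the number of principal components needed to explain 99.5%
  of the variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

ALPHA = 0.05


@dataclass
class EffectiveTests:
    n_outcomes: int
    n_effective: float
    threshold: float

    def __post_init__(self) -> None:
        if not 1.0 <= self.n_effective <= self.n_outcomes + 1e-9:
            raise ValueError("n_effective must lie in [1, n_outcomes]")
        if not 0.0 < self.threshold <= ALPHA:
            raise ValueError("threshold must lie in (0, 0.05]")

    def to_text(self) -> str:
        return (f"n_outcomes: {self.n_outcomes}\n"
                f"n_effective: {self.n_effective:.6f}\n"
                f"threshold: {self.threshold:.6g}\n")


def effective_tests(outcomes: pd.DataFrame, rule: str = "lji") -> EffectiveTests:
    """Effective number of independent outcomes and the corrected threshold.

    ``outcomes`` is persons x outcomes; correlations are pairwise-complete.
    Constant columns are dropped with a warning.  Uncorrelated outcomes
    give Meff = n (threshold 0.05/n); perfectly correlated outcomes give
    Meff = 1 (threshold 0.05).
    """
    df = pd.DataFrame(outcomes)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 outcomes")
    const = [c for c in df.columns if df[c].nunique(dropna=True) <= 1]
    if const:
        warnings.warn(f"dropping constant outcome columns: {const}", stacklevel=2)
        df = df.drop(columns=const)
        if df.shape[1] < 2:
            raise ValueError("fewer than 2 non-constant outcomes remain")
    corr = df.corr(min_periods=2).to_numpy()
    if np.isnan(corr).any():
        raise ValueError("correlation matrix has missing entries")
    lam = np.linalg.eigvalsh(corr)[::-1]
    lam = np.clip(lam, 0.0, None)
    k = df.shape[1]
    if rule == "lji":
        meff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    elif rule == "pc995":
        frac = np.cumsum(lam) / lam.sum()
        meff = float(np.searchsorted(frac, 0.995) + 1)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    meff = float(min(max(meff, 1.0), k))
    return EffectiveTests(n_outcomes=k, n_effective=meff, threshold=ALPHA / meff)
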