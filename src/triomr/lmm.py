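"""Linear mixed model y = X b + g + e with one GRM-structured random effect.

The genetic random effect has covariance sigma2_g * A (A the GRM) and the
residual sigma2_e * I.  Because there is a single random effect, the GRM
is eigendecomposed once and the restricted likelihood is profiled over
the variance ratio lambda = sigma2_g / sigma2_e by 1-D bounded
optimisation in the rotated basis — an exact spectral formulation of
GREML rather than an iterative average-information scheme.  Fixed effects
and their standard errors come from GLS at the optimum; Wald tests use
the normal reference, matching common GREML software (a t reference can
be substituted via ``use_t``).

With the identity GRM (or ``grm=None``) the model degenerates: only
sigma2_g + sigma2_e is identified and the fit reduces exactly to OLS,
which is used as a fast path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .grm import Grm

log = logging.getLogger(__name__)

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


@dataclass
class MixedModelFit:
    """REML variance components, GLS fixed effects and Wald tests."""
    beta: np.ndarray
    se: np.ndarray
    sigma2_g: float
    sigma2_e: float
    reml_loglik: float
    n: int
    term_names: list[str]
    wald_p: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.beta)
        if not (len(self.se) == len(self.term_names) == len(self.wald_p) == k):
            raise ValueError("fixed-effect vectors misaligned")
        if self.sigma2_g < 0 or self.sigma2_e <= 0:
            raise ValueError("variance components out of range")

    def term(self, name: str) -> tuple[float, float, float]:
        """(beta, se, p) for one named fixed-effect term."""
        i = self.term_names.index(name)
        return float(self.beta[i]), float(self.se[i]), float(self.wald_p[i])

    def summary_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "term": self.term_names, "beta": self.beta, "se": self.se,
            "p": self.wald_p, "n": self.n,
            "sigma2_g": self.sigma2_g, "sigma2_e": self.sigma2_e,
        })


def _check_rank(X: np.ndarray, term_names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify offending columns via QR pivoting on the correlation structure
        _, R = np.linalg.qr(X)
        bad = [term_names[j] for j in range(X.shape[1])
               if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"design matrix is rank deficient; collinear terms: {bad or 'unknown'}")


def _profile_negloglik(log_lam: float, d: np.ndarray, yt: np.ndarray,
                       Xt: np.ndarray) -> float:
    return -_profile_loglik(np.exp(log_lam), d, yt, Xt)[0]


def _profile_loglik(lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Profiled REML log-likelihood at variance ratio lam (sigma2_e profiled out)."""
    n, p = Xt.shape
    w = lam * d + 1.0
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    beta = np.linalg.solve(XtWX, XtWy)
    r = yt - Xt @ beta
    rss_w = float(r @ (r / w))
    sigma2_e = rss_w / (n - p)
    sign, logdet = np.linalg.slogdet(XtWX)
    ll = -0.5 * ((n - p) * np.log(sigma2_e) + np.sum(np.log(w)) + logdet + (n - p))
    return ll, beta, sigma2_e, XtWX


def reml_loglik(sigma2_g: float, sigma2_e: float, d: np.ndarray,
                yt: np.ndarray, Xt: np.ndarray) -> float:
    """REML log-likelihood at explicit variance components (rotated basis).

    Shares its parameterisation with the profiled fitter; exposed so
    independent grid searches can probe the same surface.
    """
    n, p = Xt.shape
    v = sigma2_g * d + sigma2_e
    if np.any(v <= 0):
        return -np.inf
    Xv = Xt / v[:, None]
    XtVX = Xt.T @ Xv
    beta = np.linalg.solve(XtVX, Xv.T @ yt)
    r = yt - Xt @ beta
    sign, logdet = np.linalg.slogdet(XtVX)
    return -0.5 * (np.sum(np.log(v)) + logdet + float(r @ (r / v)))


def fit_lmm_reml(
    y: np.ndarray,
    X: np.ndarray,
    grm: Grm | None = None,
    term_names: list[str] | None = None,
    use_t: bool = False,
) -> MixedModelFit:
    """Fit the single-random-effect LMM by spectral REML.

    Rows with any missing value in y or X are dropped first (complete-case,
    with the count logged); X must then be full column rank.  ``grm=None``
    or an identity GRM takes the OLS fast path with sigma2_g = 0.
    Negative GRM eigenvalues (non-PSD input) are clipped at zero with a
    warning.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if term_names is None:
        term_names = [f"x{j}" for j in range(X.shape[1])]
    ok = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("dropping %d incomplete cases before REML fit", n_drop)
    y = y[ok]
    X = X[ok]
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough complete cases for the design")
    _check_rank(X, term_names)

    if grm is None:
        identity_grm = True
    else:
        A = grm.matrix
        if A.shape[0] == len(ok) and n_drop:
            A = A[np.ix_(ok, ok)]
        if A.shape != (n, n):
            raise ValueError("GRM dimension does not match the analysis sample")
        identity_grm = np.array_equal(A, np.eye(n))

    if identity_grm:
        # A = I: only sigma2_g + sigma2_e identified; fit reduces to OLS
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sigma2_e = float(r @ r) / (n - p)
        cov = sigma2_e * np.linalg.inv(X.T @ X)
        ll = -0.5 * ((n - p) * np.log(sigma2_e)
                     + np.linalg.slogdet(X.T @ X)[1] + (n - p))
        sigma2_g = 0.0
    else:
        d, U = np.linalg.eigh(A)
        if d[0] < -1e-8:
            warnings.warn("GRM is not positive semidefinite; clipping negative "
                          "eigenvalues at 0", stacklevel=2)
        d = np.clip(d, 0.0, None)
        yt = U.T @ y
        Xt = U.T @ X

        res = optimize.minimize_scalar(
            _profile_negloglik, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
            args=(d, yt, Xt), options={"xatol": 1e-10})
        ll_opt, *_ = _profile_loglik(np.exp(res.x), d, yt, Xt)
        ll_zero, *_ = _profile_loglik(0.0, d, yt, Xt)
        lam = 0.0 if ll_zero >= ll_opt else float(np.exp(res.x))

        ll, beta, sigma2_e, XtWX = _profile_loglik(lam, d, yt, Xt)
        sigma2_g = lam * sigma2_e
        cov = sigma2_e * np.linalg.inv(XtWX)

    se = np.sqrt(np.diag(cov))
    z = beta / se
    if use_t:
        wald_p = 2.0 * stats.t.sf(np.abs(z), df=n - p)
    else:
        wald_p = 2.0 * stats.norm.sf(np.abs(z))
    return MixedModelFit(beta=beta, se=se, sigma2_g=float(sigma2_g),
                         sigma2_e=float(sigma2_e), reml_loglik=float(ll),
                         n=n, term_names=list(term_names), wald_p=wald_p)


def conditional_f(
    exposure: np.ndarray,
    instrument: np.ndarray,
    conditioning: list[np.ndarray] | None = None,
    covariates: np.ndarray | None = None,
) -> float:
    """Partial F for the instrument in a regression of the exposure.

    Regresses the exposure (birth-weight z) on the instrument score plus
    any conditioning scores and covariates; for a single score term the
    partial F equals the squared t statistic.  An instrument collinear
    with the conditioning set raises an error.
    """
    import statsmodels.api as sm

    exposure = np.asarray(exposure, float)
    cols = [np.asarray(instrument, float).reshape(-1, 1)]
    if conditioning:
        cols += [np.asarray(c, float).reshape(-1, 1) for c in conditioning]
    if covariates is not None:
        cov = np.asarray(covariates, float)
        if cov.ndim == 1:
            cov = cov.reshape(-1, 1)
        cols.append(cov)
    X = np.hstack(cols)
    X = sm.add_constant(X, has_constant="add")
    ok = ~np.isnan(exposure) & ~np.isnan(X).any(axis=1)
    X, yv = X[ok], exposure[ok]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("instrument is collinear with the conditioning terms")
    fit = sm.OLS(yv, X).fit()
    t_instr = fit.tvalues[1]  # column 0 is the constant
    return float(t_instr ** 2)
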