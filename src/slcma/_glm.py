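"""Shared numerics: weighted logistic IRLS, soft-thresholding, rounding.

The IRLS fitter here is the workhorse for hot loops (bootstrap replicates,
elbow refits, MICE sweeps). User-facing refits go through statsmodels; a unit
test pins this fitter against statsmodels GLM so both routes agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["LogisticFit", "fit_weighted_logistic", "soft_threshold", "round_half_up"]

# coefficients beyond this magnitude (on a standardized scale) are treated as
# evidence of separation / monotone likelihood
SEPARATION_BOUND = 25.0


@dataclass
class LogisticFit:
    """Result of a weighted logistic maximum-likelihood fit."""

    params: np.ndarray
    cov: np.ndarray
    deviance: float
    null_deviance: float
    converged: bool
    n_iter: int
    separated: bool
    eta: np.ndarray = field(repr=False, default=None)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def fittedvalues(self) -> np.ndarray:
        return expit(self.eta)


def _binomial_deviance(y: np.ndarray, eta: np.ndarray, w: np.ndarray) -> float:
    # -2 * sum w_i [y_i eta_i - log(1 + exp(eta_i))], stable via logaddexp
    return float(-2.0 * np.sum(w * (y * eta - np.logaddexp(0.0, eta))))


def fit_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    start: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    ridge: float = 0.0,
) -> LogisticFit:
    """Fit a logistic regression by Newton–Raphson (IRLS) with step halving.

    Parameters
    ----------
    X : (n, p) design matrix (caller supplies the intercept column).
    y : (n,) binary response in {0, 1}.
    sample_weight : optional non-negative case weights (frequency-style).
    offset : optional fixed linear-predictor offset.
    ridge : small L2 stabilizer added to the Hessian (0 = plain ML).

    Notes
    -----
    Rank-deficient designs are handled through ``lstsq`` steps and a
    pseudo-inverse covariance, so exactly collinear candidate sets (the
    accumulation score is the sum of the three period indicators) do not
    abort downstream refits.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    eta = X @ beta + off
    dev = _binomial_deviance(y, eta, w)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        wt = w * mu * (1.0 - mu)
        grad = X.T @ (w * (y - mu)) - ridge * beta
        H = (X * wt[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # step halving on the deviance
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            eta_c = X @ cand + off
            dev_c = _binomial_deviance(y, eta_c, w)
            if dev_c <= dev + 1e-12:
                break
            scale *= 0.5
        beta, eta = cand, eta_c
        if abs(dev - dev_c) < tol * (abs(dev) + 0.1):
            dev = dev_c
            converged = True
            break
        dev = dev_c

    mu = expit(eta)
    wt = w * mu * (1.0 - mu)
    H = (X * wt[:, None]).T @ X + ridge * np.eye(p)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)

    # null model: intercept-only (with offset), for deviance-explained bookkeeping
    wbar = w.sum()
    ybar = float(np.clip((w * y).sum() / wbar, 1e-12, 1 - 1e-12))
    eta0 = np.full(n, np.log(ybar / (1 - ybar)))
    null_dev = _binomial_deviance(y, eta0, w)

    separated = bool(np.abs(beta).max(initial=0.0) > SEPARATION_BOUND) and not converged

    return LogisticFit(
        params=beta,
        cov=cov,
        deviance=dev,
        null_deviance=null_dev,
        converged=converged,
        n_iter=it,
        separated=separated,
        eta=eta,
    )


def soft_threshold(x: float | np.ndarray, t: float):
    """Soft-thresholding operator S(x, t) = sign(x) max(|x| - t, 0)."""
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def round_half_up(x, decimals: int = 1):
    """Round half away from zero (display convention for printed tables).

    numpy rounds half to even; printed epidemiological tables round 0.25 -> 0.3.
    """
    f = 10.0 ** decimals
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.floor(np.abs(x) * f + 0.5) / f
    return float(out) if out.ndim == 0 else out
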