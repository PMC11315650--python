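"""L1-regularized logistic selection path with forced (unpenalized) covariates.

The selection stage of the structured life-course modelling approach: the
candidate life-course variables are standardized to unit variance and
penalized; the intercept and any adjustment covariates are never penalized.
The path is computed by IRLS + coordinate descent on a logarithmic penalty
grid dense enough to resolve entry order, from the smallest penalty at which
no candidate is active down to (numerically) the unpenalized fit.

A LARS-on-linear-probability route (via scikit-learn's ``lars_path`` on the
covariate-residualized problem) is provided as a cross-check, since the
method's selection machinery is classically least-angle regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._glm import SEPARATION_BOUND, fit_weighted_logistic, soft_threshold

__all__ = ["SelectionPath", "lasso_path_logistic", "lars_entry_order"]


@dataclass
class SelectionPath:
    """The ordered entry of candidate variables along the L1 path.

    Coefficients are stored both on the standardized (penalized) scale and
    mapped back to the original per-unit scale. ``deviance_explained`` is the
    fraction of the covariates-only (step 0) deviance explained at each grid
    point. Private arrays (design, response, weights) are retained so that
    elbow refits and selective inference can be reconstructed from the path
    alone.
    """

    candidate_names: list
    covariate_names: list
    penalties: np.ndarray
    coef_candidates: np.ndarray       # (G, p) original scale
    coef_candidates_std: np.ndarray   # (G, p) standardized scale
    coef_unpenalized: np.ndarray      # (G, 1 + q) intercept + covariates, original scale
    coef_unpenalized_std: np.ndarray  # same, intercept on the centered-candidate scale
    deviance: np.ndarray
    deviance_explained: np.ndarray
    null_deviance: float              # covariates-only deviance (step 0)
    entry_order: list
    entry_grid_index: dict
    centers: np.ndarray
    scales: np.ndarray
    separation: bool = False
    dropped: list = field(default_factory=list)
    has_unpenalized_endpoint: bool = False
    # retained data (not serialized)
    X_std: np.ndarray = field(repr=False, default=None)
    Z: np.ndarray = field(repr=False, default=None)
    y: np.ndarray = field(repr=False, default=None)
    sample_weight: np.ndarray = field(repr=False, default=None)

    def active_set(self, g: int, tol: float = 1e-9) -> list:
        c = self.coef_candidates_std[g]
        return [n for n, v in zip(self.candidate_names, c) if abs(v) > tol]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.coef_candidates, columns=self.candidate_names)
        df.insert(0, "penalty", self.penalties)
        df["deviance"] = self.deviance
        df["deviance_explained"] = self.deviance_explained
        df["n_active"] = [(np.abs(r) > 1e-9).sum() for r in self.coef_candidates_std]
        return df


def _coordinate_descent(
    Xfull: np.ndarray,
    z: np.ndarray,
    w: np.ndarray,
    beta: np.ndarray,
    penalized: np.ndarray,
    lam: float,
    N: float,
    tol: float = 1e-9,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """Penalized weighted least squares by cyclic coordinate descent.

    Minimizes (1/2N) sum w_i (z_i - x_i'beta)^2 + lam * sum_{j in penalized} |beta_j|.
    """
    r = z - Xfull @ beta
    denom = (w[:, None] * Xfull**2).sum(axis=0) / N
    cols = range(Xfull.shape[1])
    for _ in range(max_sweeps):
        max_delta = 0.0
        for j in cols:
            if denom[j] <= 0:
                continue
            xj = Xfull[:, j]
            rho = (w * xj * r).sum() / N + denom[j] * beta[j]
            new = soft_threshold(rho, lam) / denom[j] if penalized[j] else rho / denom[j]
            d = new - beta[j]
            if d != 0.0:
                r -= xj * d
                beta[j] = new
                max_delta = max(max_delta, abs(d) * np.sqrt(denom[j]))
        if max_delta < tol:
            break
    return beta


def lasso_path_logistic(
    candidates,
    y,
    covariates=None,
    sample_weight=None,
    n_penalties: int = 100,
    penalty_min_ratio: float = 1e-3,
    candidate_names=None,
    covariate_names=None,
    append_unpenalized: bool = True,
) -> SelectionPath:
    """Fit the penalized logistic path over the candidate variables.

    Parameters
    ----------
    candidates : (n, p) array or DataFrame of candidate life-course variables
        (standardized internally to unit variance).
    y : (n,) binary outcome.
    covariates : optional (n, q) forced adjustment variables, never penalized.
    sample_weight : optional case weights (e.g. 1/m over stacked imputations).
    n_penalties : size of the logarithmic penalty grid.
    penalty_min_ratio : smallest penalty as a fraction of the entry penalty.
    append_unpenalized : additionally compute the unpenalized (maximum
        likelihood) endpoint when the full design has full column rank.

    Returns
    -------
    SelectionPath
    """
    import pandas as pd

    if isinstance(candidates, pd.DataFrame):
        candidate_names = list(candidates.columns)
        Xc = candidates.to_numpy(float)
    else:
        Xc = np.asarray(candidates, dtype=float)
        if Xc.ndim == 1:
            Xc = Xc[:, None]
        if candidate_names is None:
            candidate_names = [f"x{j}" for j in range(Xc.shape[1])]
    candidate_names = list(candidate_names)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if y.sum() < 1 or y.sum() > n - 1:
        raise ValueError("outcome must contain at least one event and one non-event")
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    N = w.sum()

    if covariates is None:
        Zc = np.empty((n, 0))
        covariate_names = []
    elif isinstance(covariates, pd.DataFrame):
        covariate_names = list(covariates.columns)
        Zc = covariates.to_numpy(float)
    else:
        Zc = np.asarray(covariates, dtype=float)
        if Zc.ndim == 1:
            Zc = Zc[:, None]
        if covariate_names is None:
            covariate_names = [f"z{j}" for j in range(Zc.shape[1])]
    covariate_names = ["const"] + list(covariate_names)
    Z = np.column_stack([np.ones(n), Zc])

    # standardize candidates (weighted moments); drop zero-variance columns
    centers = (w @ Xc) / N
    scales = np.sqrt((w @ (Xc - centers) ** 2) / N)
    keep = scales > 1e-12
    dropped = [nme for nme, k in zip(candidate_names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance candidates: {dropped}")
        Xc, centers, scales = Xc[:, keep], centers[keep], scales[keep]
        candidate_names = [nme for nme, k in zip(candidate_names, keep) if k]
    Xs = (Xc - centers) / scales
    p = Xs.shape[1]

    # step 0: covariates-only fit
    base = fit_weighted_logistic(Z, y, sample_weight=w)
    dev0 = base.deviance
    p0 = expit(base.eta)

    lam_max = np.abs(Xs.T @ (w * (y - p0))).max() / N
    lam_max = max(lam_max, 1e-12)
    grid = np.geomspace(lam_max, lam_max * penalty_min_ratio, n_penalties)

    q1 = Z.shape[1]
    Xfull = np.column_stack([Z, Xs])
    penalized = np.r_[np.zeros(q1, bool), np.ones(p, bool)]
    beta = np.r_[base.params, np.zeros(p)]

    coef_std = np.zeros((n_penalties, p))
    coef_unpen = np.zeros((n_penalties, q1))
    dev = np.zeros(n_penalties)
    separation = False
    last = n_penalties

    for g, lam in enumerate(grid):
        # outer IRLS loop around penalized weighted least squares
        for _ in range(50):
            eta = Xfull @ beta
            mu = expit(eta)
            wirls = np.clip(mu * (1 - mu), 1e-5, None) * w
            z = eta + (y - mu) / np.clip(mu * (1 - mu), 1e-5, None)
            old = beta.copy()
            beta = _coordinate_descent(Xfull, z, wirls, beta, penalized, lam, N)
            if np.abs(beta - old).max() < 1e-9:
                break
        coef_unpen[g] = beta[:q1]
        coef_std[g] = beta[q1:]
        eta = Xfull @ beta
        dev[g] = float(-2.0 * np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
        if np.abs(beta).max() > SEPARATION_BOUND:
            warnings.warn("separation detected along the path; truncating at last stable penalty")
            separation = True
            last = g + 1
            break

    grid, coef_std, coef_unpen, dev = grid[:last], coef_std[:last], coef_unpen[:last], dev[:last]

    # optional unpenalized endpoint (only well-defined on full-rank designs)
    has_endpoint = False
    if append_unpenalized and not separation:
        if np.linalg.matrix_rank(Xfull) == Xfull.shape[1]:
            end = fit_weighted_logistic(Xfull, y, sample_weight=w, start=beta)
            if not end.separated:
                grid = np.r_[grid, 0.0]
                coef_unpen = np.vstack([coef_unpen, end.params[:q1]])
                coef_std = np.vstack([coef_std, end.params[q1:]])
                dev = np.r_[dev, end.deviance]
                has_endpoint = True

    dev_expl = (dev0 - dev) / dev0 if dev0 > 0 else np.zeros_like(dev)

    # entry order with score-based tie-breaking within a grid point
    entry_order: list = []
    entry_idx: dict = {}
    prev_eta = base.eta
    for g in range(len(grid)):
        active = np.abs(coef_std[g]) > 1e-9
        new = [j for j in range(p) if active[j] and candidate_names[j] not in entry_idx]
        if new:
            score = np.abs(Xs.T @ (w * (y - expit(prev_eta)))) / N
            new.sort(key=lambda j: (-score[j], candidate_names[j]))
            for j in new:
                entry_order.append(candidate_names[j])
                entry_idx[candidate_names[j]] = g
        prev_eta = Z @ coef_unpen[g] + Xs @ coef_std[g]

    # intercept back on the original candidate scale (candidates were centered)
    coef_orig = coef_std / scales
    coef_unpen_orig = coef_unpen.copy()
    coef_unpen_orig[:, 0] -= coef_orig @ centers

    return SelectionPath(
        candidate_names=candidate_names,
        covariate_names=covariate_names,
        penalties=grid,
        coef_candidates=coef_orig,
        coef_candidates_std=coef_std,
        coef_unpenalized=coef_unpen_orig,
        coef_unpenalized_std=coef_unpen,
        deviance=dev,
        deviance_explained=dev_expl,
        null_deviance=dev0,
        entry_order=entry_order,
        entry_grid_index=entry_idx,
        centers=centers,
        scales=scales,
        separation=separation,
        dropped=dropped,
        has_unpenalized_endpoint=has_endpoint,
        X_std=Xs,
        Z=Z,
        y=y,
        sample_weight=w,
    )


def lars_entry_order(candidates, y, covariates=None, candidate_names=None) -> list:
    """Candidate entry order from LARS on the linear-probability problem.

    Residualizes the outcome and the standardized candidates on the forced
    covariates (plus intercept), then runs least-angle regression. Used as an
    independent cross-check of the logistic path's entry order.
    """
    from sklearn.linear_model import lars_path

    import pandas as pd

    if isinstance(candidates, pd.DataFrame):
        candidate_names = list(candidates.columns)
        Xc = candidates.to_numpy(float)
    else:
        Xc = np.asarray(candidates, dtype=float)
        if candidate_names is None:
            candidate_names = [f"x{j}" for j in range(Xc.shape[1])]
    y = np.asarray(y, dtype=float)
    n = len(y)
    Z = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), np.asarray(covariates, float)])
    Xs = (Xc - Xc.mean(0)) / Xc.std(0)
    # project out the forced covariates
    Q, _ = np.linalg.qr(Z)
    Xr = Xs - Q @ (Q.T @ Xs)
    yr = y - Q @ (Q.T @ y)
    _, _, coefs = lars_path(Xr, yr, method="lasso")
    order = []
    for col in range(coefs.shape[1]):
        for j in np.flatnonzero(np.abs(coefs[:, col]) > 1e-12):
            name = candidate_names[j]
            if name not in order:
                order.append(name)
    return order
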