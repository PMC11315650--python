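"""Post-selection inference for the selected life-course model.

Three routes to honest uncertainty after L1 selection:

* **selective (polyhedral) intervals** — condition on the active-set-and-signs
  selection event at the chosen penalty, applied to the one-step Gaussian
  (weighted-least-squares working) approximation of the logistic fit, and
  invert truncated-normal pivots;
* **Bonferroni-corrected refits** — naive Wald refits widened for the number
  of candidates screened;
* **stacked bootstrap** — participants resampled with replacement, each
  carrying all m multiply-imputed rows at weight 1/m into a weighted logistic
  refit; percentile intervals at 95% and 99% with significance stars.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from ._glm import fit_weighted_logistic
from .path import SelectionPath

__all__ = [
    "EffectEstimate",
    "estimates_to_frame",
    "selective_inference",
    "bonferroni_refit",
    "stacked_bootstrap",
    "percentile_interval",
]


@dataclass
class EffectEstimate:
    """One variable's odds ratio with an uncertainty statement.

    ``method`` identifies the inference route: naive_wald, selective,
    bonferroni, stacked_bootstrap (or woolf for 2x2 tables).
    """

    variable: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float | None
    method: str
    log_or: float = None
    se: float | None = None
    stars: str = ""
    flags: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.log_or is None and self.odds_ratio is not None and self.odds_ratio > 0:
            self.log_or = math.log(self.odds_ratio)


def estimates_to_frame(estimates) -> pd.DataFrame:
    rows = [
        {
            "variable": e.variable,
            "odds_ratio": e.odds_ratio,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "p_value": e.p_value,
            "log_or": e.log_or,
            "se": e.se,
            "method": e.method,
            "stars": e.stars,
            "flags": ";".join(e.flags),
        }
        for e in estimates
    ]
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# selective (polyhedral / truncated-Gaussian) inference


def _norm_interval_prob(lo: np.ndarray | float, hi: np.ndarray | float) -> float:
    """P(lo < N(0,1) < hi), computed in the numerically favourable tail."""
    if hi <= lo:
        return 0.0
    if lo > 0:
        return stats.norm.sf(lo) - stats.norm.sf(hi)
    return stats.norm.cdf(hi) - stats.norm.cdf(lo)


def _truncated_normal_pivot(t: float, mu: float, sigma: float, a: float, b: float) -> float:
    """CDF at ``t`` of N(mu, sigma^2) truncated to [a, b]."""
    za, zb, zt = (a - mu) / sigma, (b - mu) / sigma, (t - mu) / sigma
    den = _norm_interval_prob(za, zb)
    if den <= 0.0:
        return float(zt > 0.5 * (za + zb))  # degenerate: point mass side
    return float(np.clip(_norm_interval_prob(za, zt) / den, 0.0, 1.0))


def _invert_pivot(t: float, sigma: float, a: float, b: float, target: float) -> float:
    """Solve mu such that the truncated-normal pivot at t equals ``target``.

    The pivot is monotone decreasing in mu; bisection with an adaptively
    expanded bracket. Returns +/- inf when the bracket cannot be closed
    (unbounded truncation region on that side).
    """
    f = lambda mu: _truncated_normal_pivot(t, mu, sigma, a, b) - target
    lo, hi = t - 10 * sigma, t + 10 * sigma
    for _ in range(40):
        if f(lo) > 0:
            break
        lo -= 10 * sigma
    else:
        return -np.inf
    for _ in range(40):
        if f(hi) < 0:
            break
        hi += 10 * sigma
    else:
        return np.inf
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-10 * sigma:
            break
    return 0.5 * (lo + hi)


class SelectionEventError(RuntimeError):
    """The polyhedral selection event is numerically empty/infeasible."""


def selective_inference(
    path: SelectionPath,
    k: int | None = None,
    level: float = 0.95,
    condition: bool = True,
) -> list[EffectEstimate]:
    """Selective confidence intervals for the first ``k`` selected variables.

    Conditions on the fixed-penalty selection event (active set and signs at
    the grid point where the k-th variable entered) applied to the
    weighted-least-squares working model of the logistic fit at that penalty
    (one-step Gaussian approximation). With ``condition=False`` (or an empty
    selection event) the intervals reduce to naive Wald intervals on the same
    working model.

    Odds ratios are reported per unit of the original candidate scale.
    """
    if k is None:
        k = len(path.entry_order)
    if k < 1:
        return []
    selected = path.entry_order[:k]
    g = path.entry_grid_index[selected[-1]]

    Xs, Z, y, w = path.X_std, path.Z, path.y, path.sample_weight
    n = len(y)
    N = w.sum()
    lam = path.penalties[g]
    beta_std = path.coef_candidates_std[g]
    eta = Z @ path.coef_unpenalized_std[g] + Xs @ beta_std
    mu = expit(eta)
    wvar = np.clip(mu * (1 - mu), 1e-5, None)
    W = w * wvar
    z = eta + (y - mu) / wvar  # working response; z ~ N(theta, diag(1/W)) approx

    active = np.flatnonzero(np.abs(beta_std) > 1e-9)
    # the conditioning event uses the actual active set at g (generically the
    # first k entries); targets are the requested selected variables
    q1 = Z.shape[1]
    XM = np.column_stack([Z, Xs[:, active]])
    signs = np.sign(beta_std[active])
    stilde = np.r_[np.zeros(q1), signs]

    XtW = XM.T * W
    K = np.linalg.inv(XtW @ XM)
    KXtW = K @ XtW          # maps z -> relaxed refit coefficients
    offset = K @ (N * lam * stilde)

    A_rows, b_rows = [], []
    if condition:
        # sign constraints on active penalized coefficients
        for i, s in enumerate(signs):
            j = q1 + i
            A_rows.append(-s * KXtW[j])
            b_rows.append(-s * offset[j])
        # inactive-candidate KKT constraints
        inact = [j for j in range(Xs.shape[1]) if j not in active]
        for j in inact:
            v = Xs[:, j] * W
            row = v - (v @ XM) @ KXtW
            const = v @ (XM @ offset)
            A_rows.append(row / (N * lam))
            b_rows.append(1.0 + const / (N * lam))
            A_rows.append(-row / (N * lam))
            b_rows.append(1.0 - const / (N * lam))
    A = np.array(A_rows) if A_rows else np.empty((0, n))
    b = np.array(b_rows) if b_rows else np.empty(0)

    alpha = 1.0 - level
    out = []
    Az = A @ z if len(A) else np.empty(0)
    for name in selected:
        jx = path.candidate_names.index(name)
        hit = np.flatnonzero(active == jx)
        if hit.size == 0:
            # can only happen after simultaneous-entry ties; report a naive
            # working-model interval from a refit that includes the variable
            warnings.warn(f"{name} not active at the conditioning penalty; naive interval")
            XMj = np.column_stack([XM, Xs[:, jx]])
            Kj = np.linalg.inv((XMj.T * W) @ XMj)
            tj = float((Kj @ (XMj.T * W) @ z)[-1])
            sj = math.sqrt(Kj[-1, -1])
            zc = stats.norm.ppf(1 - alpha / 2)
            scale = path.scales[jx]
            out.append(
                EffectEstimate(
                    variable=name,
                    odds_ratio=math.exp(tj / scale),
                    ci_low=math.exp((tj - zc * sj) / scale),
                    ci_high=math.exp((tj + zc * sj) / scale),
                    p_value=float(2 * stats.norm.sf(abs(tj) / sj)),
                    method="naive_wald",
                    log_or=tj / scale,
                    se=sj / scale,
                    flags=("tie_fallback",),
                )
            )
            continue
        pos_in_active = int(hit[0])
        j = q1 + pos_in_active
        eta_dir = KXtW[j]            # eta'z = relaxed coefficient
        t = float(eta_dir @ z)
        sigma2 = float(K[j, j])      # eta' Sigma eta with Sigma = diag(1/W)
        sigma = math.sqrt(max(sigma2, 1e-300))

        if len(A) and condition:
            d = A @ (XM @ K[:, j]) / sigma2  # A c, with c = Sigma eta / sigma^2 = XM K e_j / sigma^2
            resid = np.maximum(b - Az, 0.0)
            vlo, vhi = -np.inf, np.inf
            for di, ri in zip(d, resid):
                if di > 1e-12:
                    vhi = min(vhi, t + ri / di)
                elif di < -1e-12:
                    vlo = max(vlo, t + ri / di)
            if vlo >= vhi:
                raise SelectionEventError(
                    f"empty truncation interval for {name}: [{vlo:.4g}, {vhi:.4g}]"
                )
        else:
            vlo, vhi = -np.inf, np.inf

        flags = []
        if np.isinf(vlo) and np.isinf(vhi):
            lo_c, hi_c = t - stats.norm.ppf(1 - alpha / 2) * sigma, t + stats.norm.ppf(1 - alpha / 2) * sigma
            pval = 2 * stats.norm.sf(abs(t) / sigma)
            method = "selective" if condition else "naive_wald"
        else:
            lo_c = _invert_pivot(t, sigma, vlo, vhi, 1 - alpha / 2)
            hi_c = _invert_pivot(t, sigma, vlo, vhi, alpha / 2)
            if np.isinf(lo_c) or np.isinf(hi_c):
                flags.append("one_sided")
            F0 = _truncated_normal_pivot(t, 0.0, sigma, vlo, vhi)
            pval = 2 * min(F0, 1 - F0)
            method = "selective"

        scale = path.scales[jx]
        out.append(
            EffectEstimate(
                variable=name,
                odds_ratio=math.exp(t / scale),
                ci_low=math.exp(lo_c / scale) if np.isfinite(lo_c) else 0.0,
                ci_high=math.exp(hi_c / scale) if np.isfinite(hi_c) else np.inf,
                p_value=float(pval),
                method=method,
                log_or=t / scale,
                se=sigma / scale,
                flags=tuple(flags),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Bonferroni


def bonferroni_refit(estimates, n_candidates: int, level: float = 0.95) -> list[EffectEstimate]:
    """Bonferroni correction of naive refit estimates for selection over
    ``n_candidates`` screened variables: p-values multiplied (capped at 1),
    intervals widened to level 1 - alpha/n_candidates."""
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    alpha = 1.0 - level
    zc = stats.norm.ppf(1 - alpha / (2 * n_candidates))
    out = []
    for e in estimates:
        if e.se is None:
            raise ValueError("Bonferroni correction needs a log-scale standard error")
        out.append(
            EffectEstimate(
                variable=e.variable,
                odds_ratio=e.odds_ratio,
                ci_low=math.exp(e.log_or - zc * e.se),
                ci_high=math.exp(e.log_or + zc * e.se),
                p_value=min(1.0, e.p_value * n_candidates) if e.p_value is not None else None,
                method="bonferroni",
                log_or=e.log_or,
                se=e.se,
                flags=e.flags,
            )
        )
    return out


# ---------------------------------------------------------------------------
# stacked bootstrap over multiply-imputed datasets


def percentile_interval(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Percentile interval whose endpoints are order statistics of ``samples``.

    Uses the inverse empirical CDF: Q(q) is the ceil(q*B)-th order statistic.
    """
    s = np.sort(np.asarray(samples, dtype=float))
    B = len(s)

    def q(p: float) -> float:
        k = max(int(math.ceil(p * B - 1e-12)), 1)
        return float(s[k - 1])

    a = (1.0 - level) / 2.0
    return q(a), q(1.0 - a)


def stacked_bootstrap(
    imputed,
    outcome: str,
    variables,
    covariates=None,
    B: int = 1000,
    seed: int | None = None,
    id_col: str = "participant_id",
) -> list[EffectEstimate]:
    """Bootstrap the selected logistic model over stacked imputed datasets.

    Participants (not rows) are resampled with replacement; each sampled
    participant contributes all m imputed rows at weight 1/m (multiplied by
    its resampling multiplicity) to a weighted logistic refit. Percentile
    intervals are formed at 95% and 99%; stars are "*" when the 95% interval
    excludes 1 and "**" when the 99% interval excludes 1. The reported
    interval is the 95% one.

    Replicates whose refit fails to converge are dropped and counted; more
    than 5% dropped raises.
    """
    imputed = list(imputed)
    m = len(imputed)
    if m < 1:
        raise ValueError("need at least one imputed dataset")
    if B < 200:
        warnings.warn("B < 200 bootstrap replicates gives unstable percentile intervals")
    variables = list(variables)
    covariates = list(covariates) if covariates is not None else []
    cols = variables + covariates

    ids0 = imputed[0][id_col].to_numpy()
    for t in imputed[1:]:
        if not np.array_equal(t[id_col].to_numpy(), ids0):
            raise ValueError("imputed datasets must share identical participant ids and order")
    n = len(ids0)

    # participant-major stacking: rows [i*m, (i+1)*m) belong to participant i
    Xs, ys = [], []
    for t in imputed:
        Xs.append(np.column_stack([np.ones(n), t[cols].to_numpy(float)]))
        ys.append(t[outcome].to_numpy(float))
    X = np.stack(Xs, axis=1).reshape(n * m, -1)
    y = np.stack(ys, axis=1).reshape(n * m)

    base_w = np.full(n * m, 1.0 / m)
    full = fit_weighted_logistic(X, y, sample_weight=base_w)
    point = full.params

    rng = np.random.default_rng(seed)
    draws = np.empty((B, X.shape[1]))
    dropped = 0
    kept = 0
    for b in range(B):
        counts = np.bincount(rng.integers(0, n, size=n), minlength=n)
        wrep = np.repeat(counts, m) / m
        fit = fit_weighted_logistic(X, y, sample_weight=wrep, start=point, max_iter=50)
        if not fit.converged or not np.isfinite(fit.params).all():
            dropped += 1
            continue
        draws[kept] = fit.params
        kept += 1
    if dropped > 0.05 * B:
        raise RuntimeError(f"{dropped}/{B} bootstrap replicates failed to converge")
    draws = draws[:kept]

    names = ["const"] + cols
    out = []
    for j, name in enumerate(names):
        if name == "const":
            continue
        ors = np.exp(draws[:, j])
        lo95, hi95 = percentile_interval(ors, 0.95)
        lo99, hi99 = percentile_interval(ors, 0.99)
        stars = "**" if (lo99 > 1.0 or hi99 < 1.0) else ("*" if (lo95 > 1.0 or hi95 < 1.0) else "")
        out.append(
            EffectEstimate(
                variable=name,
                odds_ratio=float(np.exp(point[j])),
                ci_low=lo95,
                ci_high=hi95,
                p_value=None,
                method="stacked_bootstrap",
                log_or=float(point[j]),
                se=float(np.log(ors).std(ddof=1)),
                stars=stars,
                flags=(f"dropped={dropped}",) if dropped else (),
            )
        )
    return out
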