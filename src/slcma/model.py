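"""Structured life-course model: selection, elbow choice, refits, summary.

`SLCMA` is the user-facing model object, built from a binary outcome, a
candidate matrix of life-course variables, and forced adjustment covariates
(statsmodels style). ``fit()`` runs the penalized selection path, picks the
model size by the elbow rule, refits the selected variables unpenalized, and
returns an `SLCMAResults` carrying estimates, the hypothesis adjudication,
and post-selection inference hooks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import fit_weighted_logistic
from .encoding import CANDIDATE_NAMES, COVARIATE_NAMES, PovertyDefinition, build_design, interpret_selection
from .inference import (
    EffectEstimate,
    bonferroni_refit,
    estimates_to_frame,
    selective_inference,
)
from .path import SelectionPath, lars_entry_order, lasso_path_logistic

__all__ = ["SLCMA", "SLCMAResults", "ElbowChoice", "elbow_select", "refit_selected", "k_from_increments"]


@dataclass
class ElbowChoice:
    """Elbow-rule model-size choice.

    ``increments`` are per-step gains in deviance explained from nested
    unpenalized refits following the path's entry order; they sum to the
    total deviance explained by all entered variables. ``k_selected`` is the
    largest k whose steps 1..k each contribute at least ``tau`` of the total.
    """

    k_selected: int
    increments: np.ndarray
    cumulative: np.ndarray
    total: float
    tau: float
    entry_order: list
    selected: list = field(init=False)

    def __post_init__(self) -> None:
        self.selected = list(self.entry_order[: self.k_selected])

    def plot_data(self) -> pd.DataFrame:
        """Step vs cumulative deviance explained (for the elbow plot)."""
        return pd.DataFrame(
            {
                "step": np.arange(len(self.cumulative) + 1),
                "cumulative_deviance_explained": np.r_[0.0, self.cumulative],
                "variable": ["(covariates only)"] + list(self.entry_order),
            }
        )


def k_from_increments(increments, total: float, tau: float, tol: float = 1e-8) -> int:
    """Largest k such that every increment 1..k is >= tau * total."""
    if total <= tol:
        return 0
    k = 0
    for inc in increments:
        if inc >= tau * total:
            k += 1
        else:
            break
    return k


def elbow_select(path: SelectionPath, tau: float = 0.05, gate_alpha: float = 0.05) -> ElbowChoice:
    """Choose the number of selected variables from the path by the elbow rule.

    Deviance explained is measured by nested unpenalized refits (covariates
    plus the first k entered candidates, k = 0..K); the per-step increments
    approximate the jumps in the elbow plot. A flat elbow plot means nothing
    is selected: the rule first requires the entered candidates to jointly
    improve on the covariates-only fit by a likelihood-ratio test at
    ``gate_alpha`` (the "total deviance explained ~ 0" degenerate case);
    past that gate, ``k_selected`` is the largest k whose steps 1..k each
    contribute at least ``tau`` of the total. Rank-deficient refits (the
    accumulation score is collinear with the three period indicators) fall
    back to least-squares Newton steps and can contribute ~0 increments,
    which the rule treats as beyond the elbow.
    """
    order = path.entry_order
    y, Z, w = path.y, path.Z, path.sample_weight
    dev0 = path.null_deviance
    de = [0.0]
    for k in range(1, len(order) + 1):
        cols = [path.candidate_names.index(nm) for nm in order[:k]]
        X = np.column_stack([Z, path.X_std[:, cols]])
        fit = fit_weighted_logistic(X, y, sample_weight=w, ridge=1e-8)
        de.append((dev0 - fit.deviance) / dev0 if dev0 > 0 else 0.0)
    cumulative = np.asarray(de[1:])
    increments = np.diff(np.r_[0.0, cumulative])
    increments = np.maximum(increments, 0.0)
    total = float(cumulative[-1]) if len(cumulative) else 0.0
    # global gate: deviance reduction of the full entered set vs chi-square
    k_entered = len(order)
    if k_entered and total * dev0 <= stats.chi2.ppf(1 - gate_alpha, df=k_entered):
        k = 0
    else:
        k = k_from_increments(increments, total, tau)
    return ElbowChoice(
        k_selected=k,
        increments=increments,
        cumulative=cumulative,
        total=total,
        tau=tau,
        entry_order=list(order),
    )


def _profile_likelihood_ci(endog, exog, j: int, level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood CI for coefficient ``j`` of a logistic fit (used as
    a fallback when Wald intervals break down under near-separation)."""
    import statsmodels.api as sm

    full = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    dev_min = full.deviance
    bhat = full.params[j]
    crit = stats.chi2.ppf(level, 1)

    others = [c for c in range(exog.shape[1]) if c != j]

    def profile_dev(bj: float) -> float:
        off = exog[:, j] * bj
        f = sm.GLM(endog, exog[:, others], family=sm.families.Binomial(), offset=off).fit()
        return f.deviance - dev_min - crit

    def solve(direction: int) -> float:
        step = max(abs(bhat), 0.5)
        lo, hi = bhat, bhat + direction * step
        for _ in range(60):
            if profile_dev(hi) > 0:
                break
            hi += direction * step
        else:
            return direction * np.inf
        from scipy.optimize import brentq

        a, b = sorted((lo, hi))
        return float(brentq(profile_dev, a, b, xtol=1e-6))

    return solve(-1), solve(+1)


def refit_selected(
    path: SelectionPath,
    selected=None,
    level: float = 0.95,
) -> list[EffectEstimate]:
    """Unpenalized logistic refit of the selected candidates plus covariates.

    Reports odds ratios per unit of the original candidate scale with naive
    Wald intervals (post-selection corrections come from
    :func:`slcma.inference.selective_inference`, :func:`bonferroni_refit`
    or the stacked bootstrap). Near-separation triggers a profile-likelihood
    fallback for the affected interval and is flagged.
    """
    import statsmodels.api as sm

    if selected is None:
        selected = list(path.entry_order)
    selected = list(selected)
    y, Z, w = path.y, path.Z, path.sample_weight
    cols = [path.candidate_names.index(nm) for nm in selected]
    # original-scale candidates reconstructed from the standardized copy
    Xorig = path.X_std[:, cols] * path.scales[cols] + path.centers[cols]
    X = np.column_stack([Z, Xorig])
    names = list(path.covariate_names) + selected

    kwargs = {} if w is None else {"freq_weights": w}
    model = sm.GLM(y, X, family=sm.families.Binomial(), **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
    zc = stats.norm.ppf(1 - (1 - level) / 2)

    out = []
    for nm in selected:
        j = names.index(nm)
        b, se = float(res.params[j]), float(res.bse[j])
        flags: list[str] = []
        lo, hi = b - zc * se, b + zc * se
        if se > 50 or abs(b) > 25 or not np.isfinite(se):
            flags.append("separation")
            try:
                lo, hi = _profile_likelihood_ci(y, X, j, level)
                flags.append("profile_ci")
            except Exception:
                pass
        out.append(
            EffectEstimate(
                variable=nm,
                odds_ratio=float(np.exp(b)),
                ci_low=float(np.exp(lo)),
                ci_high=float(np.exp(hi)) if np.isfinite(hi) else np.inf,
                p_value=float(res.pvalues[j]),
                method="naive_wald",
                log_or=b,
                se=se,
                flags=tuple(flags),
            )
        )
    return out


class SLCMA:
    """Structured life-course modelling approach for a binary outcome.

    Parameters
    ----------
    endog : (n,) binary outcome.
    candidates : DataFrame of candidate life-course variables (penalized,
        standardized internally).
    covariates : optional DataFrame of forced adjustment variables.
    weights : optional case weights (e.g. 1/m across stacked imputations).

    Examples
    --------
    >>> model = SLCMA.from_cohort(table, outcome="violent_any", adjusted=True)
    >>> res = model.fit(tau=0.05)
    >>> res.selected_, res.hypothesis_
    """

    def __init__(self, endog, candidates: pd.DataFrame, covariates: pd.DataFrame | None = None, weights=None):
        self.endog = np.asarray(endog, dtype=float)
        self.candidates = candidates if isinstance(candidates, pd.DataFrame) else pd.DataFrame(candidates)
        self.covariates = covariates
        self.weights = None if weights is None else np.asarray(weights, dtype=float)
        n = len(self.endog)
        if len(self.candidates) != n or (covariates is not None and len(covariates) != n):
            raise ValueError("endog, candidates and covariates must have equal length")

    @classmethod
    def from_cohort(
        cls,
        table: pd.DataFrame,
        poverty: PovertyDefinition = PovertyDefinition(),
        outcome: str = "violent_any",
        adjusted: bool = True,
        include_mobility: bool = True,
        drop_incomplete: bool = True,
    ) -> "SLCMA":
        """Build the model from a cohort table (incomes + covariates + outcomes)."""
        design = build_design(table, poverty, include_mobility=include_mobility)
        if drop_incomplete:
            design = design[design["complete"] & design[outcome].notna()]
        cand_cols = [c for c in CANDIDATE_NAMES if c in design.columns]
        cov = design[list(COVARIATE_NAMES)] if adjusted else None
        return cls(design[outcome], design[cand_cols], cov)

    def fit(
        self,
        tau: float = 0.05,
        n_penalties: int = 100,
        penalty_min_ratio: float = 1e-3,
        method: str = "logistic",
        level: float = 0.95,
    ) -> "SLCMAResults":
        """Run path, elbow choice and unpenalized refit of the selection."""
        if method not in ("logistic", "lars"):
            raise ValueError("method must be 'logistic' or 'lars'")
        path = lasso_path_logistic(
            self.candidates,
            self.endog,
            covariates=self.covariates,
            sample_weight=self.weights,
            n_penalties=n_penalties,
            penalty_min_ratio=penalty_min_ratio,
        )
        if method == "lars":
            order = lars_entry_order(
                self.candidates,
                self.endog,
                covariates=None if self.covariates is None else np.asarray(self.covariates, float),
            )
            path.entry_order = order
            path.entry_grid_index = {
                nm: path.entry_grid_index.get(nm, len(path.penalties) - 1) for nm in order
            }
        elbow = elbow_select(path, tau=tau)
        selected = elbow.selected
        estimates = refit_selected(path, selected, level=level) if selected else []
        est_frame = estimates_to_frame(estimates) if estimates else None
        hypothesis = interpret_selection(selected, est_frame)
        return SLCMAResults(self, path, elbow, estimates, hypothesis, level)


class SLCMAResults:
    """Fit results: selection path, elbow choice, selected-model estimates."""

    def __init__(self, model: SLCMA, path: SelectionPath, elbow: ElbowChoice, estimates, hypothesis: str, level: float):
        self.model = model
        self.path = path
        self.elbow = elbow
        self.estimates = estimates
        self.hypothesis_ = hypothesis
        self.level = level

    @property
    def selected_(self) -> list:
        return list(self.elbow.selected)

    @property
    def k_selected_(self) -> int:
        return self.elbow.k_selected

    @property
    def estimates_(self) -> pd.DataFrame:
        if not self.estimates:
            return pd.DataFrame(
                columns=["odds_ratio", "ci_low", "ci_high", "p_value", "log_or", "se", "method", "stars", "flags"]
            )
        return estimates_to_frame(self.estimates)

    def selective_inference(self, level: float | None = None, condition: bool = True):
        """Polyhedral selective intervals for the selected variables."""
        return selective_inference(
            self.path, k=self.k_selected_, level=level or self.level, condition=condition
        )

    def bonferroni(self, level: float | None = None):
        """Bonferroni-corrected refit intervals over the screened candidates."""
        return bonferroni_refit(
            self.estimates, n_candidates=len(self.path.candidate_names), level=level or self.level
        )

    def plot_elbow(self, ax=None):
        """Elbow plot: cumulative deviance explained by path step."""
        import matplotlib

        if ax is None:
            matplotlib.use("Agg", force=False)
            import matplotlib.pyplot as plt

            _, ax = plt.subplots(figsize=(5, 3.5))
        d = self.elbow.plot_data()
        ax.plot(d["step"], d["cumulative_deviance_explained"], marker="o")
        for _, r in d.iterrows():
            ax.annotate(
                str(r["variable"]),
                (r["step"], r["cumulative_deviance_explained"]),
                fontsize=7,
                rotation=30,
                xytext=(2, 4),
                textcoords="offset points",
            )
        ax.axvline(self.k_selected_, ls="--", color="grey", lw=0.8)
        ax.set_xlabel("path step (variables entered)")
        ax.set_ylabel("deviance explained")
        ax.set_title(f"elbow choice: k = {self.k_selected_}")
        return ax

    def summary(self) -> str:
        lines = [
            "Structured Life Course Modelling Approach",
            "=" * 57,
            f"n obs:              {len(self.model.endog)}",
            f"events:             {int(self.model.endog.sum())}",
            f"candidates:         {', '.join(self.path.candidate_names)}",
            f"covariates forced:  {', '.join(self.path.covariate_names[1:]) or '(none)'}",
            f"entry order:        {', '.join(self.path.entry_order) or '(none)'}",
            f"elbow rule:         tau = {self.elbow.tau}, k selected = {self.k_selected_}",
            f"hypothesis:         {self.hypothesis_}",
            "-" * 57,
        ]
        if self.estimates:
            lines.append(f"{'variable':<22}{'OR':>7}{'95% CI':>18}{'p':>9}")
            for e in self.estimates:
                ci = f"({e.ci_low:.2f}, {e.ci_high:.2f})"
                lines.append(f"{e.variable:<22}{e.odds_ratio:>7.2f}{ci:>18}{e.p_value:>9.3g}")
        else:
            lines.append("no candidate selected: no association")
        lines.append("=" * 57)
        lines.append("naive Wald intervals; see selective_inference(), bonferroni(),")
        lines.append("or the stacked bootstrap for selection-aware uncertainty.")
        return "\n".join(lines)
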