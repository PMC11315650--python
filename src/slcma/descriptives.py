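"""Descriptive surfaces: cross-tabulations, 2x2 odds ratios, poverty
continuity, offence characterizations and the age-crime curve.

Percentages are rounded half-up to one decimal and computed on cases with
valid data, matching the display conventions of published cohort tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import round_half_up
from .encoding import PovertyDefinition, threshold_poverty
from .inference import EffectEstimate

__all__ = [
    "CrossTab",
    "AgeCrimeCurve",
    "crosstab",
    "odds_ratio_2x2",
    "poverty_continuity",
    "offence_summary",
    "age_crime_curve",
    "derive_outcomes",
]


@dataclass
class CrossTab:
    row_var: str
    col_var: str
    counts: pd.DataFrame
    percentages: pd.DataFrame  # rounded half-up, 1 decimal
    percent: str               # "row" or "column"
    n_valid: int
    n_missing: int

    def to_markdown(self) -> str:
        cells = self.counts.astype(str) + " (" + self.percentages.map(lambda v: f"{v:.1f}") + "%)"
        return cells.to_markdown()


def crosstab(table: pd.DataFrame, row_var: str, col_var: str, percent: str = "row") -> CrossTab:
    """Cross-tabulate two categorical variables with row/column percentages.

    Rows with a missing value in either variable are excluded from the
    denominators. Empty strata yield a zero row whose percentages are NaN
    (flagged with a warning).
    """
    if percent not in ("row", "column"):
        raise ValueError("percent must be 'row' or 'column'")
    valid = table[[row_var, col_var]].dropna()
    counts = pd.crosstab(valid[row_var], valid[col_var], dropna=False)
    axis = 1 if percent == "row" else 0
    denom = counts.sum(axis=axis)
    if (denom == 0).any():
        warnings.warn("empty stratum: percentages undefined for some rows/columns")
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = counts.div(denom.replace(0, np.nan), axis=1 - axis) * 100.0
    pct = pct.map(lambda v: round_half_up(v, 1) if np.isfinite(v) else np.nan)
    return CrossTab(
        row_var=row_var,
        col_var=col_var,
        counts=counts,
        percentages=pct,
        percent=percent,
        n_valid=len(valid),
        n_missing=len(table) - len(valid),
    )


def odds_ratio_2x2(a: float, b: float, c: float, d: float, level: float = 0.95) -> EffectEstimate:
    """Odds ratio (a*d)/(b*c) with a Woolf (log-normal) confidence interval.

    Cell layout: a = exposed cases, b = exposed non-cases, c = unexposed
    cases, d = unexposed non-cases. Any zero cell triggers the
    Haldane–Anscombe 0.5 correction (flagged). Identical to the exponentiated
    slope of a saturated logistic regression on the same table.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("cell counts must be non-negative")
    flags = []
    if (cells == 0).any():
        warnings.warn("zero cell in 2x2 table; applying Haldane-Anscombe correction")
        cells = cells + 0.5
        flags.append("haldane_anscombe")
    a_, b_, c_, d_ = cells
    log_or = math.log(a_ * d_) - math.log(b_ * c_)
    se = math.sqrt(1 / a_ + 1 / b_ + 1 / c_ + 1 / d_)
    zc = stats.norm.ppf(1 - (1 - level) / 2)
    zstat = log_or / se
    return EffectEstimate(
        variable="exposure",
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - zc * se),
        ci_high=math.exp(log_or + zc * se),
        p_value=2 * stats.norm.sf(abs(zstat)),
        method="woolf",
        log_or=log_or,
        se=se,
        flags=tuple(flags),
    )


def poverty_continuity(
    table: pd.DataFrame, definition: PovertyDefinition = PovertyDefinition()
) -> pd.DataFrame:
    """Transition summary across age pairs on complete exposure rows.

    For each ordered age pair: P(poor later | poor earlier), P(poor later |
    not poor earlier), and the 2x2 odds ratio with its Woolf interval.
    """
    cols = {"birth": "income_birth", "child": "income_child", "adult": "income_adult"}
    pov = {
        age: threshold_poverty(table[c].to_numpy(float), definition, table[c].to_numpy(float))
        for age, c in cols.items()
    }
    rows = []
    for early, late in (("birth", "child"), ("birth", "adult"), ("child", "adult")):
        pe, pl = pov[early], pov[late]
        ok = ~(np.isnan(pe) | np.isnan(pl))
        pe, pl = pe[ok], pl[ok]
        a = int(((pe == 1) & (pl == 1)).sum())
        b = int(((pe == 1) & (pl == 0)).sum())
        c = int(((pe == 0) & (pl == 1)).sum())
        d = int(((pe == 0) & (pl == 0)).sum())
        est = odds_ratio_2x2(a, b, c, d)
        rows.append(
            {
                "earlier": early,
                "later": late,
                "n": a + b + c + d,
                "p_later_given_earlier_poor": a / (a + b) if a + b else np.nan,
                "p_later_given_earlier_not_poor": c / (c + d) if c + d else np.nan,
                "odds_ratio": est.odds_ratio,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "flags": ";".join(est.flags),
            }
        )
    return pd.DataFrame(rows)


#: attributes whose unknown codes are excluded from the denominator (the
#: published convention) versus reported as a category of their own
_EXCLUDE_UNKNOWN = ("completed", "weapon", "context")
_REPORT_UNKNOWN = ("relationship", "disposition")


def offence_summary(records: pd.DataFrame, offence_type: str = "homicide") -> pd.DataFrame:
    """Characterize offences of one type, attribute by attribute.

    For completed/attempted status, weapon and context, records coded
    'unknown' are excluded from that attribute's denominator; for
    relationship and disposition the unknown-type codes are reported
    categories. Percentages are rounded half-up to one decimal.
    """
    if records.empty:
        return pd.DataFrame(columns=["attribute", "category", "count", "denominator", "percent"])
    sub = records[records["offence_type"] == offence_type] if "offence_type" in records else records
    rows = []
    for attr in (*_EXCLUDE_UNKNOWN, *_REPORT_UNKNOWN):
        if attr not in sub.columns:
            continue
        vals = sub[attr].dropna()
        if attr in _EXCLUDE_UNKNOWN:
            vals = vals[vals != "unknown"]
        denom = len(vals)
        for cat, cnt in vals.value_counts().items():
            rows.append(
                {
                    "attribute": attr,
                    "category": cat,
                    "count": int(cnt),
                    "denominator": denom,
                    "percent": round_half_up(100.0 * cnt / denom, 1) if denom else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AgeCrimeCurve:
    """Offence counts by single year of age, homicide vs non-lethal.

    Ages above ``age_max`` (the last year with complete 12-month records)
    are excluded from the curve and counted in ``overflow``.
    """

    data: pd.DataFrame          # index: age; columns: homicide, non_lethal
    age_min: int
    age_max: int
    overflow: dict = field(default_factory=dict)

    @property
    def totals(self) -> dict:
        return {c: int(self.data[c].sum()) for c in self.data.columns}


def age_crime_curve(records: pd.DataFrame, age_min: int = 10, age_max: int = 30) -> AgeCrimeCurve:
    """Aggregate offence records into an age-crime curve on [age_min, age_max]."""
    ages = records["age_at_offence"].to_numpy() if len(records) else np.array([], dtype=int)
    if len(ages) and (np.min(ages) < 0 or np.max(ages) > 120):
        raise ValueError("age_at_offence contains negative or absurd values")
    idx = pd.RangeIndex(age_min, age_max + 1, name="age")
    data = pd.DataFrame(0, index=idx, columns=["homicide", "non_lethal"])
    overflow: dict = {"homicide": 0, "non_lethal": 0}
    for otype in ("homicide", "non_lethal"):
        sub = records[records["offence_type"] == otype] if len(records) else records
        if len(sub) == 0:
            continue
        a = sub["age_at_offence"].astype(int)
        in_window = (a >= age_min) & (a <= age_max)
        vc = a[in_window].value_counts()
        data.loc[vc.index, otype] = vc.to_numpy()
        overflow[otype] = int((~in_window).sum())
    return AgeCrimeCurve(data=data, age_min=age_min, age_max=age_max, overflow=overflow)


def derive_outcomes(
    records: pd.DataFrame,
    table: pd.DataFrame,
    fight_cols: tuple = ("fight_22", "fight_30"),
) -> pd.DataFrame:
    """Set the outcome flags on the cohort table from offence records.

    violent_any: any offence record; homicide_any: any homicide record (so
    homicide implies violence by construction); violent_after22: any offence
    at age > 22. fight_any is set from self-report columns when present
    (fight at either wave vs none at both); otherwise left untouched.
    Offence records whose id is absent from the table are reported.
    """
    out = table.copy()
    ids = set(out["participant_id"])
    orphans = sorted(set(records["participant_id"]) - ids) if len(records) else []
    if orphans:
        warnings.warn(f"{len(orphans)} offence records reference unknown participants: {orphans[:5]}...")

    by_id = records[records["participant_id"].isin(ids)] if len(records) else records
    violent_ids = set(by_id["participant_id"]) if len(by_id) else set()
    hom_ids = (
        set(by_id.loc[by_id["offence_type"] == "homicide", "participant_id"]) if len(by_id) else set()
    )
    after22_ids = (
        set(by_id.loc[by_id["age_at_offence"] > 22, "participant_id"]) if len(by_id) else set()
    )
    out["violent_any"] = out["participant_id"].isin(violent_ids).astype(int)
    out["homicide_any"] = out["participant_id"].isin(hom_ids).astype(int)
    out["violent_after22"] = out["participant_id"].isin(after22_ids).astype(int)
    if all(c in out.columns for c in fight_cols):
        f = out[list(fight_cols)]
        any_fight = (f == 1).any(axis=1)
        all_valid_or_any = any_fight | f.notna().all(axis=1)
        out["fight_any"] = np.where(all_valid_or_any, any_fight.astype(float), np.nan)
    return out
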