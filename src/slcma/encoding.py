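"""Poverty definitions and life-course hypothesis encoding.

Incomes become binary poverty exposures under one of three definitions
(absolute <3 minimum wages, absolute <1, or lowest income tertile), and the
three exposures become the six candidate variables that encode the competing
life-course hypotheses:

=====================  ====================================================
candidate              hypothesis encoded
=====================  ====================================================
accumulation           count of ages exposed (0-3)
poverty_birth          exposure at birth (critical/sensitive period)
poverty_child          exposure at age 4
poverty_adult          exposure at age 22
mobility_birth_adult   not poor at birth, poor at 22 (downward mobility)
mobility_child_adult   not poor at age 4, poor at 22
=====================  ====================================================

Critical and sensitive period share the period indicators; they are
distinguished after selection by :func:`interpret_selection`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PovertyDefinition",
    "CANDIDATE_NAMES",
    "COVARIATE_NAMES",
    "threshold_poverty",
    "encode_hypotheses",
    "build_design",
    "interpret_selection",
]

CANDIDATE_NAMES = (
    "accumulation",
    "poverty_birth",
    "poverty_child",
    "poverty_adult",
    "mobility_birth_adult",
    "mobility_child_adult",
)

COVARIATE_NAMES = ("sex", "maternal_educ_low", "maternal_age_young")

_PERIODS = {"poverty_birth": "birth", "poverty_child": "early childhood", "poverty_adult": "early adulthood"}
_MOBILITY = {"mobility_birth_adult": "birth to adulthood", "mobility_child_adult": "childhood to adulthood"}


@dataclass(frozen=True)
class PovertyDefinition:
    """How income is dichotomized into poverty exposure.

    kind='absolute_threshold' flags income strictly below ``threshold``
    minimum wages (the boundary itself is not poor). kind='tertile' flags the
    lowest income tertile at each age; ties at the cut go to the poor group,
    so the poor group is the smallest set containing at least a third of the
    valid incomes.
    """

    kind: str = "absolute_threshold"
    threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.kind not in ("absolute_threshold", "tertile"):
            raise ValueError("kind must be 'absolute_threshold' or 'tertile'")
        if self.kind == "absolute_threshold" and not self.threshold > 0:
            raise ValueError("threshold must be positive")


def threshold_poverty(
    income, definition: PovertyDefinition = PovertyDefinition(), cohort_incomes=None
):
    """Binary poverty indicator (float with NaN for missing income).

    For the tertile definition the full per-age income vector must be
    supplied via ``cohort_incomes``; the cut is the smallest observed income
    ``c`` such that at least a third of valid incomes are <= c.
    """
    x = np.asarray(income, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if definition.kind == "absolute_threshold":
        out = np.where(np.isnan(x), np.nan, (x < definition.threshold).astype(float))
    else:
        if cohort_incomes is None:
            raise ValueError("tertile definition requires the cohort income vector")
        ref = np.asarray(cohort_incomes, dtype=float)
        ref = np.sort(ref[~np.isnan(ref)])
        if ref.size == 0:
            raise ValueError("no valid cohort incomes to compute the tertile cut")
        k = math.ceil(ref.size / 3)
        cut = ref[k - 1]
        out = np.where(np.isnan(x), np.nan, (x <= cut).astype(float))
    return float(out[0]) if scalar else out


def encode_hypotheses(p_birth, p_child, p_adult) -> pd.DataFrame:
    """Build the six candidate variables from the three period indicators.

    Accepts scalars or aligned arrays; missing indicators (NaN) propagate and
    flag the row incomplete. The accumulation identity
    ``accumulation = poverty_birth + poverty_child + poverty_adult`` holds on
    every complete row by construction.
    """
    pb = np.atleast_1d(np.asarray(p_birth, dtype=float))
    pc = np.atleast_1d(np.asarray(p_child, dtype=float))
    pa = np.atleast_1d(np.asarray(p_adult, dtype=float))
    for name, v in (("p_birth", pb), ("p_child", pc), ("p_adult", pa)):
        valid = v[~np.isnan(v)]
        if not np.isin(valid, (0.0, 1.0)).all():
            raise ValueError(f"{name} must be binary (0/1) or missing")
    design = pd.DataFrame(
        {
            "accumulation": pb + pc + pa,
            "poverty_birth": pb,
            "poverty_child": pc,
            "poverty_adult": pa,
            "mobility_birth_adult": (1 - pb) * pa,
            "mobility_child_adult": (1 - pc) * pa,
        }
    )
    design["complete"] = ~design[list(CANDIDATE_NAMES)].isna().any(axis=1)
    return design


def build_design(
    table: pd.DataFrame,
    definition: PovertyDefinition = PovertyDefinition(),
    include_mobility: bool = True,
) -> pd.DataFrame:
    """Candidate design matrix for a cohort table (plus covariates).

    Returns one row per participant with the candidate columns, the forced
    covariates, outcomes, and a ``complete`` flag (False where any exposure
    is missing; such rows are excluded from complete-case fits but retained
    for the imputation path).
    """
    indicators = {}
    for age, col in zip(("birth", "child", "adult"), ("income_birth", "income_child", "income_adult")):
        indicators[age] = threshold_poverty(
            table[col].to_numpy(float), definition, cohort_incomes=table[col].to_numpy(float)
        )
    design = encode_hypotheses(indicators["birth"], indicators["child"], indicators["adult"])
    design.index = table.index
    if not include_mobility:
        design = design.drop(columns=list(_MOBILITY))
    keep = [c for c in table.columns if c not in design.columns]
    return pd.concat([table[keep], design], axis=1)


def interpret_selection(selected, estimates: pd.DataFrame | None = None) -> str:
    """Adjudicate the life-course hypothesis label from a selected set.

    Rules: a single period indicator alone is a critical period; a period
    indicator alongside accumulation (or alongside weaker other-period
    indicators) is a sensitive period at that age; accumulation alone is
    accumulation; mobility variables contribute a mobility component; several
    components are reported jointly. ``estimates`` (indexed by variable, with
    a ``log_or`` or ``odds_ratio`` column) resolves which of several selected
    periods is strongest; without it, selection order decides.
    """
    selected = list(selected)
    unknown = [s for s in selected if s not in CANDIDATE_NAMES]
    if unknown:
        raise ValueError(f"unknown candidate variables: {unknown}")
    if not selected:
        return "no association"

    has_acc = "accumulation" in selected
    periods = [s for s in selected if s in _PERIODS]
    mobility = [s for s in selected if s in _MOBILITY]

    components: list[str] = []
    if periods:
        if len(periods) == 1 and not has_acc and not mobility:
            return f"critical period: {_PERIODS[periods[0]]}"
        strongest = periods[0]
        if len(periods) > 1 and estimates is not None:
            strength = {}
            for p in periods:
                row = estimates.loc[p]
                strength[p] = abs(row["log_or"]) if "log_or" in row else abs(np.log(row["odds_ratio"]))
            strongest = max(periods, key=strength.get)
        label = f"sensitive period: {_PERIODS[strongest]}"
        if has_acc:
            label += " (with accumulation)"
        components.append(label)
    elif has_acc:
        components.append("accumulation")
    for m in mobility:
        components.append(f"mobility: {_MOBILITY[m]}")
    return " + ".join(components)
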