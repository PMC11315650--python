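"""Synthetic birth-cohort generator.

Emulates the statistical structure of a 1982 Brazilian birth cohort followed
to age 30: household income (in monthly-minimum-wage units) measured at
birth, age 4 and age 22 and linked across ages by a Gaussian copula; binary
covariates (sex, low maternal education, young maternal age); rare binary
violence/homicide outcomes driven by a configurable life-course mechanism;
MAR attrition at the child and adult income waves; and per-offence records
feeding an age-crime curve.

Default parameters are calibrated so that, at the default <3 minimum-wage
poverty line, marginal poverty prevalences are 69.6/58.5/37.0% at the three
ages, poverty continuity odds ratios match the cohort's published pairwise
values, chronic (all-three-ages) poverty is 26.1%, and outcome prevalences
are 20.5% (any violence) and 0.9% (homicide) under the default
accumulation-plus-adult-period mechanism.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

__all__ = [
    "SimulationParams",
    "OffenceParams",
    "simulate_cohort",
    "apply_missingness",
    "simulate_offences",
    "latent_corr_for_or",
    "write_cohort",
    "read_cohort",
    "write_offences",
    "read_offences",
]

MECHANISMS = ("accumulation", "critical", "sensitive", "mobility", "null")

AGE_LABELS = ("birth", "child", "adult")

#: cohort-table column order (the documented CSV header)
COHORT_COLUMNS = [
    "participant_id",
    "income_birth",
    "income_child",
    "income_adult",
    "sex",
    "maternal_educ_low",
    "maternal_age_young",
    "alive_at_10",
    "violent_any",
    "homicide_any",
    "fight_any",
    "violent_after22",
]

OFFENCE_COLUMNS = [
    "participant_id",
    "age_at_offence",
    "offence_type",
    "completed",
    "weapon",
    "relationship",
    "context",
    "disposition",
]

# marginal poverty prevalences at <3 minimum wages, at birth / age 4 / age 22
_DEFAULT_PREVALENCES = (0.696, 0.585, 0.370)
_DEFAULT_LOG_SD = 0.9

# latent copula correlations: (birth,child) and (birth,adult) solved so the
# implied 2x2 poverty ORs are 13.15 and 3.99; (child,adult) solved so the
# copula-implied chronic-poverty probability is 26.1%
_DEFAULT_LATENT_CORR = (
    (1.0, 0.7613, 0.4621),
    (0.7613, 1.0, 0.3922),
    (0.4621, 0.3922, 1.0),
)


def _default_income_log_mean() -> tuple[float, float, float]:
    """Log-means s.t. P(income < 3) hits the default prevalences exactly."""
    return tuple(
        float(np.log(3.0) - _DEFAULT_LOG_SD * stats.norm.ppf(p))
        for p in _DEFAULT_PREVALENCES
    )


def latent_corr_for_or(p1: float, p2: float, target_or: float) -> float:
    """Solve the Gaussian-copula latent correlation giving a target 2x2 OR.

    For binary indicators with marginal prevalences ``p1``, ``p2`` obtained by
    thresholding a bivariate normal at latent correlation rho, returns the rho
    whose implied cross-tabulation has odds ratio ``target_or``.
    """

    q1, q2 = stats.norm.ppf(p1), stats.norm.ppf(p2)

    def implied_or(rho: float) -> float:
        p11 = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf(
            [q1, q2]
        )
        p10, p01 = p1 - p11, p2 - p11
        p00 = 1 - p1 - p2 + p11
        return (p11 * p00) / (p10 * p01)

    return float(optimize.brentq(lambda r: implied_or(r) - target_or, -0.95, 0.97, xtol=1e-6))


@dataclass
class OffenceParams:
    """Parameters of the offence-history generator.

    ``mean_offences`` is the mean number of recorded violent offences per
    offender (zero-truncated scale); the default is the cohort's printed
    2907 offences over 1151 offenders. Ages follow a discretized Beta shape
    on [age_min, age_max]; the default shape keeps offending frequent into
    the late twenties, mirroring the flat right tail of this cohort's
    age-crime curve. Categorical attribute probabilities default to the
    published homicide-offence characteristics (unknown codes included).
    """

    mean_offences: float = 2907.0 / 1151.0
    dispersion: float = 0.8  # negative-binomial shape k; smaller = more overdispersed
    age_min: int = 10
    age_max: int = 30
    age_shape_a: float = 1.8
    age_shape_b: float = 1.4
    mean_extra_homicides: float = 58.0 / 48.0 - 1.0
    homicide_attrs: dict = field(
        default_factory=lambda: {
            "completed": {"attempted": 39 / 58, "completed": 17 / 58, "unknown": 2 / 58},
            "weapon": {
                "firearm": 23 / 58,
                "sharp": 7 / 58,
                "none": 7 / 58,
                "unknown": 21 / 58,
            },
            "relationship": {
                "partner": 3 / 58,
                "known": 31 / 58,
                "unknown_to_offender": 4 / 58,
                "unidentified": 20 / 58,
            },
            "context": {
                "domestic": 9 / 58,
                "street": 20 / 58,
                "other": 7 / 58,
                "unknown": 22 / 58,
            },
            "disposition": {
                "no_court": 21 / 58,
                "convicted": 9 / 58,
                "archived": 12 / 58,
                "acquitted": 16 / 58,
            },
        }
    )
    nonlethal_attrs: dict = field(
        default_factory=lambda: {
            "completed": {"unknown": 1.0},
            "weapon": {"none": 0.50, "sharp": 0.15, "firearm": 0.10, "unknown": 0.25},
            "relationship": {
                "partner": 0.10,
                "known": 0.40,
                "unknown_to_offender": 0.20,
                "unidentified": 0.30,
            },
            "context": {"domestic": 0.25, "street": 0.50, "other": 0.15, "unknown": 0.10},
            "disposition": {
                "no_court": 0.40,
                "convicted": 0.20,
                "archived": 0.25,
                "acquitted": 0.15,
            },
        }
    )

    def __post_init__(self) -> None:
        if self.mean_offences <= 1.0:
            raise ValueError("mean_offences must exceed 1 (every offender has >= 1 record)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not (0 <= self.age_min < self.age_max):
            raise ValueError("need 0 <= age_min < age_max")
        for attrs in (self.homicide_attrs, self.nonlethal_attrs):
            for name, probs in attrs.items():
                total = sum(probs.values())
                if not np.isclose(total, 1.0, atol=1e-8):
                    raise ValueError(f"{name} category probabilities sum to {total}, not 1")


@dataclass
class SimulationParams:
    """Generative parameters for a synthetic life-course cohort.

    The outcome model is, per participant,

        logit P(outcome) = beta0 + beta_acc * accumulation
                           + sum_a beta_age[a] * poverty_a
                           + beta_mob * (mob_birth_adult + mob_child_adult)
                           + beta_sex * male + beta_mat_educ * low_educ
                           + beta_mat_age * young_mother

    with true poverty indicators derived from the complete (pre-attrition)
    incomes at ``poverty_threshold``. ``mechanism`` declares which exposure
    coefficients are allowed to be non-zero; the rest must be zero.
    """

    n_participants: int = 5660
    income_log_mean: tuple[float, float, float] = field(
        default_factory=_default_income_log_mean
    )
    income_log_sd: tuple[float, float, float] = (_DEFAULT_LOG_SD,) * 3
    latent_corr: tuple = _DEFAULT_LATENT_CORR
    prop_male: float = 0.514
    prop_mat_age_young: float = 0.154
    prop_mat_educ_low: float = 0.332
    # socio-economic gradients: log-odds of low maternal education / young
    # maternal age per 1 SD *lower* latent family income (marginal
    # proportions are preserved by intercept calibration)
    educ_income_loading: float = 1.0
    mat_age_income_loading: float = 0.5
    mechanism: str = "sensitive"
    poverty_threshold: float = 3.0
    beta0_violence: float = -2.7887
    beta0_homicide: float = -6.2432
    beta_acc: float = 0.285
    beta_age: tuple[float, float, float] = (0.0, 0.0, 0.30)
    beta_mob: float = 0.0
    beta_sex: float = 1.1
    beta_mat_educ: float = 0.3
    beta_mat_age: float = 0.2
    prob_alive_at_10: float = 1.0 - 254.0 / 5914.0
    fight_prob_violent: float = 0.55
    fight_prob_nonviolent: float = 0.10
    prob_after22_given_violent: float = 0.75
    missing_rate_child: float = 0.159
    missing_rate_adult: float = 0.211
    mar_coef: dict = field(default_factory=lambda: {"maternal_educ_low": 0.5})
    offence: OffenceParams = field(default_factory=OffenceParams)
    seed: int = 1982

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        C = np.asarray(self.latent_corr, dtype=float)
        if C.shape != (3, 3) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("latent_corr must be a symmetric 3x3 matrix with unit diagonal")
        if np.linalg.eigvalsh(C).min() <= 1e-10:
            raise ValueError("latent_corr must be positive-definite")
        for name in (
            "prop_male",
            "prop_mat_age_young",
            "prop_mat_educ_low",
            "prob_alive_at_10",
            "fight_prob_violent",
            "fight_prob_nonviolent",
            "prob_after22_given_violent",
            "missing_rate_child",
            "missing_rate_adult",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        self._check_mechanism()
        if any(sd <= 0 for sd in self.income_log_sd):
            raise ValueError("income_log_sd must be positive")
        if self.poverty_threshold <= 0:
            raise ValueError("poverty_threshold must be positive")

    def _check_mechanism(self) -> None:
        ages_active = np.count_nonzero(self.beta_age)
        errors = {
            "null": self.beta_acc != 0 or ages_active or self.beta_mob != 0,
            "accumulation": ages_active or self.beta_mob != 0,
            "critical": self.beta_acc != 0 or self.beta_mob != 0 or ages_active > 1,
            "sensitive": self.beta_mob != 0,
            "mobility": self.beta_acc != 0 or ages_active,
        }
        if errors[self.mechanism]:
            raise ValueError(
                f"mechanism '{self.mechanism}' requires its inactive exposure betas to be zero"
            )

    @classmethod
    def for_mechanism(cls, mechanism: str, **overrides) -> "SimulationParams":
        """Build params for a named mechanism with all exposure betas zeroed
        except those the mechanism allows (supply them in ``overrides``)."""
        base = dict(mechanism=mechanism, beta_acc=0.0, beta_age=(0.0, 0.0, 0.0), beta_mob=0.0)
        base.update(overrides)
        return cls(**base)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, OffenceParams):
                return dataclasses.asdict(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=default, indent=2, sort_keys=True)


def _covariate_matrix(table: pd.DataFrame) -> np.ndarray:
    return table[["sex", "maternal_educ_low", "maternal_age_young"]].to_numpy(float)


def simulate_cohort(params: SimulationParams) -> pd.DataFrame:
    """Draw a complete synthetic cohort table (no missingness).

    Incomes are generated by a Gaussian copula (latent MVN, lognormal
    marginals); outcomes are Bernoulli draws from the logistic structural
    model using the true poverty indicators. Identical params + seed give a
    bit-identical table.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_participants

    C = np.asarray(params.latent_corr, dtype=float)
    L = np.linalg.cholesky(C)
    Z = rng.standard_normal((n, 3)) @ L.T
    mu = np.asarray(params.income_log_mean)
    sd = np.asarray(params.income_log_sd)
    incomes = np.exp(mu + sd * Z)

    sex = (rng.random(n) < params.prop_male).astype(int)
    # maternal covariates ride the latent income factor (social gradient);
    # intercepts are solved so the marginal proportions hold exactly
    zbar = Z.mean(axis=1)
    zbar = (zbar - zbar.mean()) / zbar.std()
    lin_educ = params.educ_income_loading * (-zbar)
    lin_age = params.mat_age_income_loading * (-zbar)
    mat_educ = (
        rng.random(n) < expit(_calibrated_intercept(params.prop_mat_educ_low, lin_educ) + lin_educ)
    ).astype(int)
    mat_age = (
        rng.random(n) < expit(_calibrated_intercept(params.prop_mat_age_young, lin_age) + lin_age)
    ).astype(int)
    alive = (rng.random(n) < params.prob_alive_at_10).astype(int)

    poverty = (incomes < params.poverty_threshold).astype(float)
    acc = poverty.sum(axis=1)
    mob_ba = (1 - poverty[:, 0]) * poverty[:, 2]
    mob_ca = (1 - poverty[:, 1]) * poverty[:, 2]

    lp_core = (
        params.beta_acc * acc
        + poverty @ np.asarray(params.beta_age)
        + params.beta_mob * (mob_ba + mob_ca)
        + params.beta_sex * sex
        + params.beta_mat_educ * mat_educ
        + params.beta_mat_age * mat_age
    )
    violent = rng.random(n) < expit(params.beta0_violence + lp_core)
    homicide = rng.random(n) < expit(params.beta0_homicide + lp_core)
    violent_any = (violent | homicide).astype(int)
    homicide_any = homicide.astype(int)

    p_fight = np.where(violent_any == 1, params.fight_prob_violent, params.fight_prob_nonviolent)
    fight_any = (rng.random(n) < p_fight).astype(int)
    violent_after22 = (
        (violent_any == 1) & (rng.random(n) < params.prob_after22_given_violent)
    ).astype(int)

    return pd.DataFrame(
        {
            "participant_id": np.arange(n, dtype=int),
            "income_birth": incomes[:, 0],
            "income_child": incomes[:, 1],
            "income_adult": incomes[:, 2],
            "sex": sex,
            "maternal_educ_low": mat_educ,
            "maternal_age_young": mat_age,
            "alive_at_10": alive,
            "violent_any": violent_any,
            "homicide_any": homicide_any,
            "fight_any": fight_any,
            "violent_after22": violent_after22,
        },
        columns=COHORT_COLUMNS,
    )


def _calibrated_intercept(target_rate: float, lin: np.ndarray) -> float:
    """Intercept alpha with mean(expit(alpha + lin)) == target_rate."""
    if target_rate <= 0.0:
        return -np.inf
    if target_rate >= 1.0:
        return np.inf
    if np.allclose(lin, 0.0):
        return float(logit(target_rate))
    return float(
        optimize.brentq(lambda a: expit(a + lin).mean() - target_rate, -40.0, 40.0)
    )


def apply_missingness(table: pd.DataFrame, params: SimulationParams) -> pd.DataFrame:
    """Blank child/adult incomes by a MAR mechanism on observed covariates.

    The missingness propensity is logistic in the covariates listed in
    ``params.mar_coef``; the intercept is solved so the expected marginal
    missingness rate equals ``missing_rate_child`` / ``missing_rate_adult``
    exactly on the table at hand (so configured rates hold whatever the MAR
    coefficients). Income at birth is never blanked: enrolment was at birth.
    """
    for name, rate in (
        ("missing_rate_child", params.missing_rate_child),
        ("missing_rate_adult", params.missing_rate_adult),
    ):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")

    out = table.copy()
    rng = np.random.default_rng([int(params.seed), 1])
    lin = np.zeros(len(out))
    for cov, coef in params.mar_coef.items():
        lin = lin + coef * out[cov].to_numpy(float)

    for col, rate in (
        ("income_child", params.missing_rate_child),
        ("income_adult", params.missing_rate_adult),
    ):
        if rate == 0.0:
            continue
        alpha = _calibrated_intercept(rate, lin)
        p_miss = expit(alpha + lin)
        mask = rng.random(len(out)) < p_miss
        out.loc[mask, col] = np.nan
    return out


def _zt_negbin_counts(rng: np.random.Generator, n: int, params: OffenceParams) -> np.ndarray:
    """Zero-truncated negative-binomial counts with truncated mean
    ``params.mean_offences`` (untruncated mean solved numerically)."""
    k = params.dispersion
    target = params.mean_offences

    def trunc_mean(m0: float) -> float:
        p0 = (k / (k + m0)) ** k
        return m0 / (1.0 - p0)

    m0 = optimize.brentq(lambda m: trunc_mean(m) - target, 1e-9, 10.0 * target)
    p = k / (k + m0)
    counts = rng.negative_binomial(k, p, size=n)
    # rejection: redraw zeros until none remain
    zero = counts == 0
    while zero.any():
        counts[zero] = rng.negative_binomial(k, p, size=int(zero.sum()))
        zero = counts == 0
    return counts


def _draw_categories(rng: np.random.Generator, probs: dict, size: int) -> np.ndarray:
    cats = np.array(list(probs.keys()), dtype=object)
    p = np.array(list(probs.values()), dtype=float)
    p = p / p.sum()
    return rng.choice(cats, size=size, p=p)


def simulate_offences(table: pd.DataFrame, params: SimulationParams) -> pd.DataFrame:
    """Generate per-offence records for every participant with violent_any=1.

    Each offender receives a zero-truncated negative-binomial number of
    offences; homicide offenders receive 1 + Poisson homicide records (their
    total is raised to fit if needed). Ages are drawn from a discretized Beta
    distribution on [age_min, age_max]; categorical attributes from the
    configured per-type probabilities.
    """
    op = params.offence
    rng = np.random.default_rng([int(params.seed), 2])

    offenders = table.loc[table["violent_any"] == 1, ["participant_id", "homicide_any"]]
    if offenders.empty:
        return pd.DataFrame(columns=OFFENCE_COLUMNS)

    n_off = len(offenders)
    counts = _zt_negbin_counts(rng, n_off, op)
    n_hom = np.where(
        offenders["homicide_any"].to_numpy(int) == 1,
        1 + rng.poisson(op.mean_extra_homicides, size=n_off),
        0,
    )
    counts = np.maximum(counts, n_hom)

    ids = np.repeat(offenders["participant_id"].to_numpy(), counts)
    total = int(counts.sum())
    # within each offender block the first n_hom records are homicides
    pos_in_block = np.concatenate([np.arange(c) for c in counts]) if total else np.array([], int)
    hom_flag = pos_in_block < np.repeat(n_hom, counts)

    ages_grid = np.arange(op.age_min, op.age_max + 1)
    mids = (ages_grid - op.age_min + 0.5) / (op.age_max - op.age_min + 1)
    pmf = stats.beta.pdf(mids, op.age_shape_a, op.age_shape_b)
    pmf = pmf / pmf.sum()
    ages = rng.choice(ages_grid, size=total, p=pmf)

    records = pd.DataFrame(
        {
            "participant_id": ids,
            "age_at_offence": ages,
            "offence_type": np.where(hom_flag, "homicide", "non_lethal"),
        }
    )
    for attr in ("completed", "weapon", "relationship", "context", "disposition"):
        vals = np.empty(total, dtype=object)
        for flag, probs in ((True, op.homicide_attrs), (False, op.nonlethal_attrs)):
            m = hom_flag == flag
            if m.any():
                vals[m] = _draw_categories(rng, probs[attr], int(m.sum()))
        records[attr] = vals
    return records[OFFENCE_COLUMNS]


# ---------------------------------------------------------------------------
# CSV round trip with provenance sidecar


def write_cohort(table: pd.DataFrame, path: str | Path, params: SimulationParams | None = None) -> None:
    path = Path(path)
    table.to_csv(path, index=False)
    if params is not None:
        path.with_suffix(".params.json").write_text(params.to_json())


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_offences(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_offences(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
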