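"""Generator behaviour: calibration, copula structure, missingness, offences."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from slcma import (
    SimulationParams,
    apply_missingness,
    latent_corr_for_or,
    read_cohort,
    simulate_cohort,
    simulate_offences,
    write_cohort,
)


def test_seeded_runs_are_bit_reproducible(tmp_path, default_params):
    a = simulate_cohort(default_params)
    b = simulate_cohort(dataclasses.replace(default_params))
    pd.testing.assert_frame_equal(a, b)
    write_cohort(a, tmp_path / "a.csv")
    write_cohort(b, tmp_path / "b.csv")
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


def test_csv_round_trip_preserves_values(tmp_path, cohort_missing):
    write_cohort(cohort_missing, tmp_path / "c.csv")
    back = read_cohort(tmp_path / "c.csv")
    pd.testing.assert_frame_equal(back, cohort_missing.reset_index(drop=True))


def test_default_poverty_prevalences_match_calibration():
    """Marginal poverty prevalences hit 69.6/58.5/37.0% within 1.5 points."""
    t = simulate_cohort(SimulationParams(n_participants=10_000, seed=5))
    prev = (t[["income_birth", "income_child", "income_adult"]] < 3.0).mean()
    for got, want in zip(prev, (0.696, 0.585, 0.370)):
        assert abs(got - want) < 0.015


def test_null_mechanism_prevalence_matches_intercept():
    """With all exposure and covariate betas zero, outcome prevalence is
    logistic(beta0) within 3 Monte Carlo SEs."""
    p = SimulationParams.for_mechanism(
        "null", n_participants=50_000, seed=8,
        beta_sex=0.0, beta_mat_educ=0.0, beta_mat_age=0.0,
        beta0_violence=-1.5, beta0_homicide=-30.0,
    )
    t = simulate_cohort(p)
    want = expit(-1.5)
    se = np.sqrt(want * (1 - want) / len(t))
    assert abs(t["violent_any"].mean() - want) < 3 * se


def test_identity_copula_gives_independent_poverty_indicators():
    eye = tuple(tuple(float(i == j) for j in range(3)) for i in range(3))
    p = SimulationParams.for_mechanism("null", n_participants=50_000, seed=9, latent_corr=eye)
    t = simulate_cohort(p)
    pov = (t[["income_birth", "income_child", "income_adult"]] < 3.0).astype(float)
    corr = pov.corr().to_numpy()
    off_diag = corr[~np.eye(3, dtype=bool)]
    assert np.abs(off_diag).max() < 3.5 / np.sqrt(len(t))


def test_homicide_implies_violence(cohort):
    assert (cohort.loc[cohort["homicide_any"] == 1, "violent_any"] == 1).all()


def test_latent_corr_solver_round_trips():
    rho = latent_corr_for_or(0.696, 0.370, 3.99)
    assert rho == pytest.approx(0.4621, abs=2e-3)


def test_invalid_latent_corr_rejected():
    bad = ((1.0, 0.99, -0.99), (0.99, 1.0, 0.99), (-0.99, 0.99, 1.0))
    with pytest.raises(ValueError, match="positive-definite"):
        SimulationParams(latent_corr=bad)


def test_mechanism_constraints_enforced():
    with pytest.raises(ValueError, match="inactive"):
        SimulationParams(mechanism="null")  # default betas are non-zero
    with pytest.raises(ValueError, match="inactive"):
        SimulationParams.for_mechanism("accumulation", beta_age=(0.1, 0.0, 0.0))
    # a valid single-age critical spec passes
    SimulationParams.for_mechanism("critical", beta_age=(0.0, 0.0, 0.4))


class TestMissingness:
    def test_zero_rates_leave_table_unchanged(self, cohort, default_params):
        p = dataclasses.replace(default_params, missing_rate_child=0.0, missing_rate_adult=0.0)
        pd.testing.assert_frame_equal(apply_missingness(cohort, p), cohort)

    def test_complete_case_fraction_matches_product_of_retentions(self):
        """Covariate-independent rates (0.159, 0.211) give a complete-case
        fraction of 0.841 * 0.789 = 0.663 within Monte Carlo error."""
        p = SimulationParams(n_participants=40_000, seed=13, mar_coef={})
        t = apply_missingness(simulate_cohort(p), p)
        cc = t[["income_child", "income_adult"]].notna().all(axis=1).mean()
        want = (1 - 0.159) * (1 - 0.211)
        assert cc == pytest.approx(want, abs=3 * np.sqrt(want * (1 - want) / len(t)))

    def test_birth_income_never_missing(self, cohort_missing):
        assert cohort_missing["income_birth"].notna().all()

    def test_mar_on_maternal_education_biases_complete_cases(self):
        """With missingness loading on low maternal education, the
        complete-case poverty prevalence is biased downward (poorer families
        drop out more)."""
        p = SimulationParams(n_participants=30_000, seed=17, mar_coef={"maternal_educ_low": 1.5})
        t = apply_missingness(simulate_cohort(p), p)
        full = (t["income_birth"] < 3).mean()
        cc = t["income_adult"].notna()
        assert (t.loc[cc, "income_birth"] < 3).mean() < full

    def test_rates_validated(self, cohort, default_params):
        p = dataclasses.replace(default_params)
        object.__setattr__(p, "missing_rate_child", 1.4)
        with pytest.raises(ValueError):
            apply_missingness(cohort, p)


class TestOffences:
    def test_zero_offenders_gives_empty_list(self, default_params):
        t = simulate_cohort(default_params).head(50).copy()
        t["violent_any"] = 0
        t["homicide_any"] = 0
        assert simulate_offences(t, default_params).empty

    def test_every_offender_has_a_record_and_homicides_match(self, cohort, offences):
        got = set(offences["participant_id"])
        want = set(cohort.loc[cohort["violent_any"] == 1, "participant_id"])
        assert got == want
        hom_ids = set(offences.loc[offences["offence_type"] == "homicide", "participant_id"])
        assert hom_ids == set(cohort.loc[cohort["homicide_any"] == 1, "participant_id"])

    def test_mean_offences_per_offender_matches_configured_ratio(self):
        """Configured mean 2907/1151 recovered within Monte Carlo error."""
        p = SimulationParams(n_participants=40_000, seed=21)
        t = simulate_cohort(p)
        off = simulate_offences(t, p)
        n_off = int(t["violent_any"].sum())
        got = len(off) / n_off
        # homicide-count flooring nudges the mean up slightly; MC se ~ 0.05
        assert got == pytest.approx(2907 / 1151, abs=0.1)

    def test_weapon_split_matches_configured_probabilities(self):
        """Coded homicide weapon split approaches 62.2/18.9/18.9."""
        p = SimulationParams(n_participants=100_000, seed=22)
        t = simulate_cohort(p)
        off = simulate_offences(t, p)
        hom = off[off["offence_type"] == "homicide"]
        coded = hom[hom["weapon"] != "unknown"]["weapon"].value_counts(normalize=True)
        assert coded["firearm"] == pytest.approx(23 / 37, abs=0.04)
        assert coded["sharp"] == pytest.approx(7 / 37, abs=0.04)

    def test_ages_within_window(self, offences, default_params):
        assert offences["age_at_offence"].between(10, 30).all()
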