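"""Descriptive tables reproduce printed counts/percentages; OR oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from slcma import (
    PovertyDefinition,
    age_crime_curve,
    crosstab,
    derive_outcomes,
    odds_ratio_2x2,
    offence_summary,
    poverty_continuity,
)


def _expand_counts(rows):
    """Build a long DataFrame from (row_value, col_value, count) triples."""
    frames = []
    for r, c, n in rows:
        frames.append(pd.DataFrame({"row": [r] * n, "col": [c] * n}))
    return pd.concat(frames, ignore_index=True)


class TestCrossTab:
    def test_published_poverty_by_outcome_row_percentages(self):
        """Poverty-at-birth x outcome counts reproduce the printed row
        percentages 74.7 / 24.3 / 1.0 and 86.0 / 13.6 / 0.3."""
        t = _expand_counts(
            [
                ("poor", "none", 1997), ("poor", "non_lethal", 650), ("poor", "homicide", 26),
                ("not_poor", "none", 1004), ("not_poor", "non_lethal", 159), ("not_poor", "homicide", 4),
            ]
        )
        ct = crosstab(t, "row", "col", percent="row")
        assert ct.percentages.loc["poor", "non_lethal"] == 24.3
        assert ct.percentages.loc["poor", "none"] == 74.7
        assert ct.percentages.loc["poor", "homicide"] == 1.0
        assert ct.percentages.loc["not_poor", "none"] == 86.0
        assert ct.counts.loc["poor"].sum() == 2673

    def test_zero_ages_poor_row(self):
        t = _expand_counts(
            [("0", "none", 730), ("0", "non_lethal", 97), ("0", "homicide", 2)]
        )
        ct = crosstab(t, "row", "col", percent="row")
        assert ct.percentages.loc["0", "homicide"] == 0.2
        assert ct.percentages.loc["0", "non_lethal"] == 11.7

    def test_single_cell_is_100_percent(self):
        t = pd.DataFrame({"row": ["a"], "col": ["x"]})
        ct = crosstab(t, "row", "col")
        assert ct.percentages.loc["a", "x"] == 100.0

    def test_missing_excluded_from_denominators(self):
        t = pd.DataFrame({"row": ["a", "a", None, "b"], "col": ["x", "y", "x", None]})
        ct = crosstab(t, "row", "col")
        assert ct.n_valid == 2 and ct.n_missing == 2
        assert ct.counts.to_numpy().sum() == 2

    def test_column_percentages(self):
        t = _expand_counts([("f", "tot", 2876), ("m", "tot", 3037)])
        ct = crosstab(t, "row", "col", percent="column")
        assert ct.percentages.loc["f", "tot"] == 48.6
        assert ct.percentages.loc["m", "tot"] == 51.4


class TestOddsRatio2x2:
    def test_symmetric_table_is_one(self):
        assert odds_ratio_2x2(10, 10, 10, 10).odds_ratio == pytest.approx(1.0)

    def test_published_homicide_by_poverty_at_birth(self):
        """Printed counts a=26, b=2647, c=4, d=1163 give OR ~ 2.86."""
        est = odds_ratio_2x2(26, 2647, 4, 1163)
        assert est.odds_ratio == pytest.approx((26 * 1163) / (4 * 2647), abs=1e-12)
        assert round(est.odds_ratio, 2) == 2.86

    @pytest.mark.parametrize("cells", [(30, 70, 20, 80), (5, 12, 9, 3), (150, 40, 60, 90)])
    def test_matches_saturated_logistic_regression(self, cells):
        a, b, c, d = cells
        est = odds_ratio_2x2(a, b, c, d)
        x = np.r_[np.ones(a + b), np.zeros(c + d)]
        y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert est.odds_ratio == pytest.approx(np.exp(fit.params[1]), abs=1e-6)
        # Woolf CI equals the logistic Wald CI for a saturated 2x2
        lo, hi = np.exp(fit.conf_int()[1])
        assert est.ci_low == pytest.approx(lo, abs=1e-4)
        assert est.ci_high == pytest.approx(hi, abs=1e-4)

    def test_zero_cell_haldane_correction(self):
        with pytest.warns(UserWarning, match="Haldane"):
            est = odds_ratio_2x2(0, 10, 5, 5)
        assert "haldane_anscombe" in est.flags
        assert np.isfinite(est.odds_ratio)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_2x2(-1, 2, 3, 4)


class TestPovertyContinuity:
    def test_independent_exposures_or_near_one(self, rng):
        n = 40_000
        t = pd.DataFrame(
            {
                "income_birth": rng.lognormal(1.0, 0.8, n),
                "income_child": rng.lognormal(1.0, 0.8, n),
                "income_adult": rng.lognormal(1.0, 0.8, n),
            }
        )
        cont = poverty_continuity(t)
        assert np.allclose(cont["odds_ratio"], 1.0, atol=0.15)

    def test_calibrated_cohort_reproduces_continuity_ors(self, cohort):
        """Latent correlations were calibrated to pairwise ORs 13.15
        (birth->child) and 3.99 (birth->adult)."""
        cont = poverty_continuity(cohort).set_index(["earlier", "later"])
        bc = cont.loc[("birth", "child"), "odds_ratio"]
        ba = cont.loc[("birth", "adult"), "odds_ratio"]
        assert bc == pytest.approx(13.15, rel=0.25)
        assert ba == pytest.approx(3.99, rel=0.2)

    def test_perfect_persistence_flagged(self):
        t = pd.DataFrame(
            {
                "income_birth": [1.0] * 5 + [5.0] * 5,
                "income_child": [1.0] * 5 + [5.0] * 5,
                "income_adult": [1.0] * 5 + [5.0] * 5,
            }
        )
        with pytest.warns(UserWarning, match="Haldane"):
            cont = poverty_continuity(t)
        row = cont.set_index(["earlier", "later"]).loc[("birth", "child")]
        assert row["p_later_given_earlier_poor"] == 1.0
        assert "haldane_anscombe" in row["flags"]


def _published_homicide_records():
    rows = []

    def add(attr_values):
        rows.append(attr_values)

    base = dict(participant_id=0, age_at_offence=20, offence_type="homicide")
    recs = []
    specs = {
        "completed": [("attempted", 39), ("completed", 17), ("unknown", 2)],
        "weapon": [("firearm", 23), ("sharp", 7), ("none", 7), ("unknown", 21)],
        "relationship": [("partner", 3), ("known", 31), ("unknown_to_offender", 4), ("unidentified", 20)],
        "context": [("domestic", 9), ("street", 20), ("other", 7), ("unknown", 22)],
        "disposition": [("no_court", 21), ("convicted", 9), ("archived", 12), ("acquitted", 16)],
    }
    cols = {a: sum(([v] * n for v, n in vals), []) for a, vals in specs.items()}
    recs = pd.DataFrame({**{k: [base[k]] * 58 for k in base}, **cols})
    return recs


class TestOffenceSummary:
    def test_published_percentages_reproduced(self):
        """58 homicide records with published category counts reproduce the
        printed percentages: firearm 62.2, convicted 15.5, completed 30.4,
        street 55.6, unidentified 34.5."""
        summ = _published_homicide_records()
        out = offence_summary(summ).set_index(["attribute", "category"])["percent"]
        assert out[("weapon", "firearm")] == 62.2
        assert out[("disposition", "convicted")] == 15.5
        assert out[("completed", "completed")] == 30.4
        assert out[("context", "street")] == 55.6
        assert out[("relationship", "unidentified")] == 34.5

    def test_unknowns_excluded_only_for_coded_attributes(self):
        out = _published_homicide_records()
        summ = offence_summary(out)
        weapon_denoms = summ[summ["attribute"] == "weapon"]["denominator"].unique()
        rel_denoms = summ[summ["attribute"] == "relationship"]["denominator"].unique()
        assert weapon_denoms.tolist() == [37]   # 58 - 21 uncodable
        assert rel_denoms.tolist() == [58]      # unknowns are a reported category

    def test_empty_records_give_empty_summary(self):
        assert offence_summary(pd.DataFrame()).empty


class TestAgeCrimeCurve:
    def test_single_offence_single_spike(self):
        r = pd.DataFrame(
            {"participant_id": [1], "age_at_offence": [20], "offence_type": ["non_lethal"]}
        )
        curve = age_crime_curve(r)
        assert curve.data.loc[20, "non_lethal"] == 1
        assert curve.data.to_numpy().sum() == 1

    def test_totals_match_record_totals(self, offences):
        curve = age_crime_curve(offences)
        t = curve.totals
        assert t["homicide"] + curve.overflow["homicide"] == (offences["offence_type"] == "homicide").sum()
        assert t["non_lethal"] + curve.overflow["non_lethal"] == (offences["offence_type"] == "non_lethal").sum()

    def test_offence_after_cutoff_goes_to_overflow(self):
        r = pd.DataFrame(
            {"participant_id": [1, 2], "age_at_offence": [31, 25], "offence_type": ["non_lethal"] * 2}
        )
        curve = age_crime_curve(r)
        assert curve.overflow["non_lethal"] == 1
        assert curve.data["non_lethal"].sum() == 1

    def test_absurd_ages_rejected(self):
        r = pd.DataFrame(
            {"participant_id": [1], "age_at_offence": [-3], "offence_type": ["non_lethal"]}
        )
        with pytest.raises(ValueError, match="absurd"):
            age_crime_curve(r)


class TestDeriveOutcomes:
    def _table(self):
        return pd.DataFrame(
            {
                "participant_id": [1, 2, 3],
                "violent_any": [0, 0, 0],
                "homicide_any": [0, 0, 0],
                "violent_after22": [0, 0, 0],
            }
        )

    def test_homicide_only_offender_is_violent(self):
        r = pd.DataFrame(
            {"participant_id": [1], "age_at_offence": [24], "offence_type": ["homicide"]}
        )
        out = derive_outcomes(r, self._table())
        row = out.set_index("participant_id").loc[1]
        assert row["violent_any"] == 1 and row["homicide_any"] == 1 and row["violent_after22"] == 1

    def test_offences_at_or_before_22_not_after22(self):
        r = pd.DataFrame(
            {"participant_id": [2, 2], "age_at_offence": [18, 22], "offence_type": ["non_lethal"] * 2}
        )
        out = derive_outcomes(r, self._table()).set_index("participant_id")
        assert out.loc[2, "violent_any"] == 1
        assert out.loc[2, "violent_after22"] == 0

    def test_fight_at_either_wave_counts(self):
        t = self._table()
        t["fight_22"] = [1, 0, np.nan]
        t["fight_30"] = [0, 0, np.nan]
        out = derive_outcomes(pd.DataFrame(columns=["participant_id", "age_at_offence", "offence_type"]), t)
        assert out["fight_any"].tolist()[:2] == [1.0, 0.0]
        assert np.isnan(out["fight_any"].iloc[2])

    def test_orphan_ids_warn(self):
        r = pd.DataFrame(
            {"participant_id": [99], "age_at_offence": [20], "offence_type": ["non_lethal"]}
        )
        with pytest.warns(UserWarning, match="unknown participants"):
            derive_outcomes(r, self._table())
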