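"""ASCVD risk equation, eligibility rules, and outcome classification."""

import math
from datetime import date

import pandas as pd
import pytest

import cogload as cl
from cogload.cohort import load_pce_coefficients
from cogload.errors import DomainError, MissingDataError


def _record(**kw):
    base = dict(
        age=55.0,
        sex="male",
        race_ethnicity="White",
        systolic_bp=120.0,
        total_cholesterol=213.0,
        hdl=50.0,
        ldl=130.0,
        hba1c=5.5,
        smoking_flag=False,
    )
    base.update(kw)
    return cl.PatientRecord(**base)


def _oracle_risk(group, age, tc, hdl, sbp, treated, smoker, dm):
    """Independent hand computation of the pooled-cohort-equations formula."""
    g = load_pce_coefficients()["groups"][group]
    la, ltc, lh, ls = math.log(age), math.log(tc), math.log(hdl), math.log(sbp)
    terms = {
        "ln_age": la,
        "ln_age_sq": la**2,
        "ln_tc": ltc,
        "ln_age_ln_tc": la * ltc,
        "ln_hdl": lh,
        "ln_age_ln_hdl": la * lh,
        "ln_sbp_treated": ls if treated else 0.0,
        "ln_age_ln_sbp_treated": la * ls if treated else 0.0,
        "ln_sbp_untreated": 0.0 if treated else ls,
        "ln_age_ln_sbp_untreated": 0.0 if treated else la * ls,
        "smoker": float(smoker),
        "ln_age_smoker": la * float(smoker),
        "diabetes": float(dm),
    }
    lp = sum(c * terms[k] for k, c in g["coefficients"].items())
    return 1.0 - g["baseline_survival"] ** math.exp(lp - g["mean_lp"])


class TestAscvdRisk:
    # the guideline's printed reference profiles: 55-year-old, TC 213,
    # HDL 50, untreated SBP 120, nonsmoker, nondiabetic
    @pytest.mark.parametrize(
        "sex, race, printed",
        [
            ("female", "White", 0.021),
            ("female", "Black", 0.030),
            ("male", "White", 0.053),
            ("male", "Black", 0.061),
        ],
    )
    def test_reference_profiles(self, sex, race, printed):
        rec = _record(sex=sex, race_ethnicity=race)
        risk = cl.ascvd_risk_2013(rec)
        group = f"{'black' if race == 'Black' else 'white'}_{sex}"
        oracle = _oracle_risk(group, 55, 213, 50, 120, False, False, False)
        assert risk == pytest.approx(oracle, abs=1e-4)
        assert risk == pytest.approx(printed, abs=1e-3)

    @pytest.mark.parametrize("sex", ["male", "female"])
    @pytest.mark.parametrize("race", ["White", "Black", "Asian", "Other"])
    @pytest.mark.parametrize("age", [40.0, 60.0, 75.0])
    def test_risk_is_a_probability(self, sex, race, age):
        risk = cl.ascvd_risk_2013(_record(sex=sex, race_ethnicity=race, age=age))
        assert 0.0 <= risk <= 1.0

    def test_risk_monotone_in_untreated_sbp(self):
        low = cl.ascvd_risk_2013(_record(systolic_bp=110.0))
        high = cl.ascvd_risk_2013(_record(systolic_bp=160.0))
        assert high > low

    def test_missing_input_names_variable(self):
        with pytest.raises(MissingDataError, match="hdl"):
            cl.ascvd_risk_2013(_record(hdl=None))

    def test_out_of_range_age_rejected(self):
        with pytest.raises(DomainError):
            cl.ascvd_risk_2013(_record(age=85.0))

    def test_non_stratified_race_uses_non_black_coefficients(self):
        a = cl.ascvd_risk_2013(_record(race_ethnicity="Asian"))
        w = cl.ascvd_risk_2013(_record(race_ethnicity="White"))
        assert a == w


class TestEligibility:
    def test_high_risk_midlife_patient_is_eligible(self):
        res = cl.assess_eligibility(_record(age=50.0), risk_override=0.08)
        assert res.eligible and res.indication == "risk_ge_7.5"
        assert res.exclusion_reason is None

    def test_pregnancy_excludes_despite_qualification(self):
        res = cl.assess_eligibility(
            _record(age=50.0, sex="female", pregnancy_flag=True), risk_override=0.20
        )
        assert not res.eligible
        assert res.exclusion_reason == "pregnancy"

    def test_risk_rule_requires_age_40_to_75(self):
        res = cl.assess_eligibility(_record(age=35.0, ldl=150.0), risk_override=0.20)
        assert not res.eligible and res.indication == "none"

    def test_ldl190_requires_diabetes_as_printed(self):
        rec = _record(age=50.0, ldl=195.0)
        assert not cl.assess_eligibility(rec, risk_override=0.01).eligible
        dm = _record(age=50.0, ldl=195.0, hba1c=7.0)
        res = cl.assess_eligibility(dm, risk_override=0.01)
        assert res.eligible and res.indication == "ldl190_dm"
        # config switch restores the usual guideline reading
        alone = cl.assess_eligibility(
            rec, risk_override=0.01, ldl190_requires_diabetes=False
        )
        assert alone.eligible and alone.indication == "ldl190_dm"

    def test_diabetes_disjunction_at_hba1c_threshold(self):
        below = _record(age=45.0, prior_mi_or_stroke_flag=True, hba1c=6.4)
        above = _record(age=45.0, prior_mi_or_stroke_flag=True, hba1c=6.5)
        r_below = cl.assess_eligibility(below, risk_override=0.01)
        r_above = cl.assess_eligibility(above, risk_override=0.01)
        assert r_below.indication == "ascvd_history"
        assert r_above.indication == "dm_with_ascvd_history"

    @pytest.mark.parametrize(
        "flag, reason",
        [
            ("statin_allergy_or_contraindication_flag", "statin_allergy_or_contraindication"),
            ("hepatitis_flag", "hepatitis"),
            ("cirrhosis_flag", "cirrhosis"),
            ("esrd_flag", "esrd"),
            ("ckd_flag", "ckd"),
        ],
    )
    def test_exclusions_dominate_every_inclusion(self, flag, reason):
        rec = _record(age=50.0, prior_mi_or_stroke_flag=True, **{flag: True})
        res = cl.assess_eligibility(rec, risk_override=0.5)
        assert not res.eligible and res.exclusion_reason == reason

    def test_stale_measurements_mean_missing_risk_inputs(self):
        rec = _record(age=50.0)
        rec.encounter_date = date(2024, 6, 1)
        rec.measurement_dates = {"lipids": date(2020, 1, 1)}
        res = cl.assess_eligibility(rec)
        assert not res.eligible and res.exclusion_reason == "missing_risk_inputs"

    def test_eligibility_frame_runs_on_simulated_cohort(self):
        pats = cl.simulate_patients(cl.SimulationConfig(n_patients=60, seed=8))
        table = cl.eligibility_frame(pats)
        assert len(table) == 60
        assert table["eligible"].any()
        elig = table[table["eligible"]]
        assert (elig["exclusion_reason"].isna()).all()
        assert (elig["indication"] != "none").all()


class TestClassifyOutcome:
    WINDOW = (pd.Timestamp("2024-03-01 13:00"), pd.Timestamp("2024-03-01 14:30"))

    def _orders(self, rows):
        return pd.DataFrame(
            {
                "csn": [r[0] for r in rows],
                "medication": [r[1] for r in rows],
                "order_time": pd.to_datetime([r[2] for r in rows]),
            }
        )

    def test_single_statin_order_initiates(self):
        orders = self._orders([("c1", "atorvastatin", "2024-03-01 13:55")])
        out = cl.classify_outcome("c1", orders, self.WINDOW)
        assert out.initiated and out.order_timestamp == pd.Timestamp("2024-03-01 13:55")

    def test_no_orders_not_initiated(self):
        out = cl.classify_outcome("c1", self._orders([]), self.WINDOW)
        assert not out.initiated and out.order_timestamp is None

    def test_two_orders_take_the_earlier(self):
        rows = [
            ("c1", "rosuvastatin", "2024-03-01 14:10"),
            ("c1", "atorvastatin", "2024-03-01 13:20"),
        ]
        out = cl.classify_outcome("c1", self._orders(rows), self.WINDOW)
        # brute force: min over the statin order timestamps
        assert out.order_timestamp == min(pd.to_datetime([r[2] for r in rows]))

    def test_non_statin_orders_ignored(self):
        orders = self._orders([("c1", "lisinopril", "2024-03-01 13:30")])
        assert not cl.classify_outcome("c1", orders, self.WINDOW).initiated

    def test_order_outside_segments_warns_but_counts(self):
        orders = self._orders([("c1", "atorvastatin", "2024-03-01 13:30")])
        segments = [
            (pd.Timestamp("2024-03-01 13:00"), pd.Timestamp("2024-03-01 13:10")),
            (pd.Timestamp("2024-03-01 14:00"), pd.Timestamp("2024-03-01 14:30")),
        ]
        with pytest.warns(UserWarning, match="outside"):
            out = cl.classify_outcome("c1", orders, self.WINDOW, segments=segments)
        assert out.initiated
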