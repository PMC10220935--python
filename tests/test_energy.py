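"""BMR equation, AEE/TEE/PAL formulas and the PAL correction map."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actipal import (
    Anthropometry,
    CorrectionModel,
    EnergyParams,
    InputError,
    MeasuredEnergy,
    MEN_CORRECTION,
    WOMEN_CORRECTION,
    WearRules,
    corrected_tee,
    correct_pal,
    daily_aee,
    ganpule_bmr,
    participant_energy,
    tee_and_pal,
)

WOMEN_MEAN = Anthropometry("F", 74.0, 149.4, 52.5)
MEN_MEAN = Anthropometry("M", 75.0, 162.0, 62.7)


class TestGanpuleBMR:
    def test_women_cohort_mean_anthropometry(self):
        # tabulated cohort mean is 962 kcal/day (inputs are rounded means)
        assert ganpule_bmr(WOMEN_MEAN) == pytest.approx(962.0, abs=2.0)

    def test_men_cohort_mean_anthropometry(self):
        assert ganpule_bmr(MEN_MEAN) == pytest.approx(1279.0, abs=2.0)

    def test_weight_coefficient_by_finite_difference(self):
        heavier = Anthropometry("F", 74.0, 149.4, 53.5)
        diff = ganpule_bmr(heavier) - ganpule_bmr(WOMEN_MEAN)
        assert diff == pytest.approx(0.0481 * 1000 / 4.186, abs=1e-9)

    @pytest.mark.parametrize(
        "field,delta,coef",
        [("age_y", 1.0, -0.0138), ("stature_cm", 1.0, 0.0234), ("weight_kg", 1.0, 0.0481)],
    )
    def test_linearity_in_each_covariate(self, field, delta, coef):
        base = dict(sex="M", age_y=70.0, stature_cm=165.0, weight_kg=60.0)
        bumped = dict(base)
        bumped[field] += delta
        diff = ganpule_bmr(Anthropometry(**bumped)) - ganpule_bmr(Anthropometry(**base))
        assert diff == pytest.approx(coef * delta * 1000 / 4.186, abs=1e-9)

    def test_sex_term_doubles_for_women(self):
        m = ganpule_bmr(Anthropometry("M", 70.0, 160.0, 55.0))
        f = ganpule_bmr(Anthropometry("F", 70.0, 160.0, 55.0))
        assert m - f == pytest.approx(0.5473 * 1000 / 4.186, abs=1e-9)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sex="F", age_y=17.0, stature_cm=150.0, weight_kg=50.0),
            dict(sex="F", age_y=74.0, stature_cm=99.0, weight_kg=50.0),
            dict(sex="F", age_y=74.0, stature_cm=150.0, weight_kg=20.0),
            dict(sex="X", age_y=74.0, stature_cm=150.0, weight_kg=50.0),
        ],
    )
    def test_out_of_range_anthropometry_rejected(self, kwargs):
        with pytest.raises(InputError):
            Anthropometry(**kwargs)


class TestDailyAEE:
    def test_all_resting_day_has_zero_aee(self):
        assert daily_aee(np.ones(1440), 1000.0) == pytest.approx(0.0)

    def test_closed_form_at_two_mets(self):
        assert daily_aee(np.full(1440, 2.0), 1000.0) == pytest.approx(1100.0)

    def test_imputed_09_day_is_negative(self):
        assert daily_aee(np.full(1440, 0.9), 1000.0) == pytest.approx(-110.0)

    def test_wrong_minute_count_rejected(self):
        with pytest.raises(InputError):
            daily_aee(np.ones(1000), 1000.0)

    def test_sensitivity_variant_without_rest_subtraction(self):
        # literal reading: raw METs x RMR; kept for sensitivity analysis
        assert daily_aee(np.ones(1440), 1000.0, subtract_rest=False) == pytest.approx(1100.0)


class TestTeeAndPal:
    def test_pal_is_10_over_9_when_aee_zero(self):
        tee, pal = tee_and_pal(1000.0, 0.0)
        assert pal == pytest.approx(10.0 / 9.0)

    def test_direct_arithmetic(self):
        tee, pal = tee_and_pal(1000.0, 530.0)
        assert tee == pytest.approx(1700.0)
        assert pal == pytest.approx(1.7)

    @given(
        st.floats(min_value=500, max_value=3000),
        st.floats(min_value=-200, max_value=2000),
    )
    @settings(max_examples=100, deadline=None)
    def test_identities(self, bmr, aee):
        tee, pal = tee_and_pal(bmr, aee)
        assert pal * bmr == pytest.approx(tee, rel=1e-12)
        # DIT is exactly one tenth of TEE: TEE - (BMR + AEE) = TEE / 10
        assert tee - (bmr + aee) == pytest.approx(tee / 10.0, rel=1e-9)

    def test_nonpositive_bmr_rejected(self):
        with pytest.raises(InputError):
            tee_and_pal(0.0, 100.0)


class TestCorrection:
    def test_women_table_mean(self):
        assert correct_pal(1.71, WOMEN_CORRECTION) == pytest.approx(1.83, abs=0.005)

    def test_men_table_mean(self):
        assert correct_pal(1.61, MEN_CORRECTION) == pytest.approx(1.82, abs=0.005)

    def test_identity_model(self):
        ident = CorrectionModel("F", 1.0, 0.0)
        assert correct_pal(1.234, ident) == pytest.approx(1.234)

    def test_strictly_monotone(self):
        x = np.linspace(1.0, 2.5, 20)
        y = [correct_pal(v, WOMEN_CORRECTION) for v in x]
        assert (np.diff(y) > 0).all()

    def test_missing_model_rejected(self):
        with pytest.raises(InputError):
            correct_pal(1.7, None)

    def test_corrected_tee_products(self):
        assert corrected_tee(1.828, 962.5) == pytest.approx(1759.5, abs=0.5)
        assert corrected_tee(2.0, 1000.0) == pytest.approx(2000.0)
        assert corrected_tee(10.0 / 9.0, 900.0) == pytest.approx(1000.0)
        with pytest.raises(InputError):
            corrected_tee(1.8, 0.0)


class TestParticipantEnergy:
    def make_minutes(self, mets_by_day, wear_by_day):
        frames = []
        for d, (m, w) in enumerate(zip(mets_by_day, wear_by_day)):
            frames.append(
                pd.DataFrame(
                    {
                        "day": d,
                        "minute_of_day": np.arange(1440),
                        "mets": m,
                        "wear": w,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def test_noiseless_schedule_recovers_analytic_pal(self):
        # 840 wear minutes at exactly 2.0 METs, 600 non-wear at 0.9
        wear = np.arange(1440) < 840
        mets = np.where(wear, 2.0, 0.9)
        minutes = self.make_minutes([mets] * 3, [wear] * 3)
        anthro = Anthropometry("F", 74.0, 149.4, 52.5)
        bmr = ganpule_bmr(anthro)
        pred = participant_energy(minutes, anthro)
        mean_met = (840 * 2.0 + 600 * 0.9) / 1440
        pal_analytic = (10.0 / 9.0) * (1 + 1.1 * (mean_met - 1))
        assert pred.pal_pred == pytest.approx(pal_analytic, abs=1e-10)
        assert pred.tee_pred == pytest.approx(pal_analytic * bmr, rel=1e-12)

    def test_nagayoshi_applies_to_wear_minutes_only(self):
        wear = np.arange(1440) < 840
        mets = np.where(wear, 1.0, 0.9)
        minutes = self.make_minutes([mets] * 3, [wear] * 3)
        anthro = Anthropometry("F", 74.0, 149.4, 52.5)
        pred = participant_energy(minutes, anthro)
        # adjusted wear METs = 1.297, imputed minutes stay at 0.9
        mean_adj = (840 * 1.297 + 600 * 0.9) / 1440
        pal_expected = (10.0 / 9.0) * (1 + 1.1 * (mean_adj - 1))
        assert pred.pal_nagayoshi == pytest.approx(pal_expected, abs=1e-9)

    def test_invalid_days_are_excluded_from_averaging(self):
        wear_good = np.arange(1440) < 840
        wear_bad = np.arange(1440) < 100  # below the 600-minute rule
        mets_good = np.where(wear_good, 2.0, 0.9)
        mets_bad = np.where(wear_bad, 6.0, 0.9)
        minutes = self.make_minutes(
            [mets_good, mets_good, mets_good, mets_bad],
            [wear_good, wear_good, wear_good, wear_bad],
        )
        anthro = Anthropometry("F", 74.0, 149.4, 52.5)
        pred = participant_energy(minutes, anthro)
        only_good = participant_energy(
            self.make_minutes([mets_good] * 3, [wear_good] * 3), anthro
        )
        assert pred.pal_pred == pytest.approx(only_good.pal_pred, rel=1e-12)

    def test_correction_sex_mismatch_rejected(self):
        wear = np.arange(1440) < 840
        mets = np.where(wear, 2.0, 0.9)
        minutes = self.make_minutes([mets] * 3, [wear] * 3)
        anthro = Anthropometry("F", 74.0, 149.4, 52.5)
        with pytest.raises(InputError):
            participant_energy(minutes, anthro, correction=MEN_CORRECTION)


def test_measured_energy_pal_identity():
    m = MeasuredEnergy(bmr_kcal_d=1021.0, tee_kcal_d=1863.0)
    assert m.pal == pytest.approx(1863.0 / 1021.0)
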