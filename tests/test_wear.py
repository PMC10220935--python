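"""Minute aggregation, non-wear run detection, valid days and imputation."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actipal import (
    InputError,
    WearRules,
    day_summaries,
    detect_nonwear,
    impute_nonwear,
    minute_mets,
    select_valid,
)

RULES = WearRules()


def epochs_frame(mets, zero=None):
    """Epoch frame with ac values encoding the zero-count flag."""
    mets = np.asarray(mets, dtype=float)
    zero = np.zeros(mets.size, dtype=bool) if zero is None else np.asarray(zero)
    ac = np.where(zero, 0.0, 50.0)
    return pd.DataFrame(
        {
            "epoch_index": np.arange(mets.size),
            "ac_fil_mg": ac,
            "ac_unfil_mg": ac,
            "mets": mets,
        }
    )


def minutes_frame(zero_pattern, mets=1.2, day=0):
    """Minute records from a boolean zero pattern."""
    zero = np.asarray(zero_pattern, dtype=bool)
    return pd.DataFrame(
        {
            "day": day,
            "minute_of_day": np.arange(zero.size),
            "mets": np.where(zero, 0.9, mets),
            "zero_minute": zero,
        }
    )


class TestMinuteMets:
    def test_mean_of_six_constant_epochs(self):
        out = minute_mets(epochs_frame([1.0] * 6))
        assert len(out) == 1
        assert out.loc[0, "mets"] == pytest.approx(1.0)

    def test_arithmetic_mean(self):
        out = minute_mets(epochs_frame([1, 1, 1, 2, 2, 2]))
        assert out.loc[0, "mets"] == pytest.approx(1.5)

    def test_trailing_partial_minute_dropped(self):
        out = minute_mets(epochs_frame([1.0] * 7))
        assert len(out) == 1

    def test_zero_minute_requires_all_epochs_zero(self):
        zero = np.array([True] * 6 + [True] * 5 + [False])
        out = minute_mets(epochs_frame([1.0] * 12, zero))
        assert out["zero_minute"].tolist() == [True, False]

    def test_day_rollover(self):
        out = minute_mets(epochs_frame([1.0] * 12), start_day=0, start_minute=1439)
        assert out["day"].tolist() == [0, 1]
        assert out["minute_of_day"].tolist() == [1439, 0]


def brute_force_nonwear(zero, min_run):
    """Enumerate all runs directly."""
    nonwear = [False] * len(zero)
    i = 0
    while i < len(zero):
        if zero[i]:
            j = i
            while j < len(zero) and zero[j]:
                j += 1
            if j - i >= min_run:
                for k in range(i, j):
                    nonwear[k] = True
            i = j
        else:
            i += 1
    return [not x for x in nonwear]


class TestDetectNonwear:
    def test_59_consecutive_zero_minutes_remain_wear(self):
        m = minutes_frame([True] * 59 + [False] * 10)
        assert detect_nonwear(m, RULES).all()

    def test_60_consecutive_zero_minutes_are_nonwear(self):
        m = minutes_frame([True] * 60 + [False] * 10)
        wear = detect_nonwear(m, RULES)
        assert (~wear[:60]).all() and wear[60:].all()

    def test_two_runs_split_by_activity(self):
        pattern = [True] * 120 + [False] * 10 + [True] * 120
        wear = detect_nonwear(minutes_frame(pattern), RULES)
        assert wear.sum() == 10
        assert (~wear[:120]).all() and (~wear[130:]).all()

    def test_runs_do_not_span_midnight_by_default(self):
        # 40 zero minutes at end of day 0 + 40 at start of day 1: no run >= 60
        m0 = minutes_frame([False] * 1400 + [True] * 40, day=0)
        m1 = minutes_frame([True] * 40 + [False] * 1400, day=1)
        m = pd.concat([m0, m1], ignore_index=True)
        assert detect_nonwear(m, RULES).all()
        spanning = WearRules(span_midnight=True)
        wear = detect_nonwear(m, spanning)
        assert (~wear).sum() == 80

    def test_idempotent(self):
        m = minutes_frame([True] * 100 + [False] * 30 + [True] * 59)
        w1 = detect_nonwear(m, RULES)
        m2 = m.copy()
        w2 = detect_nonwear(m2, RULES)
        np.testing.assert_array_equal(w1, w2)

    @given(st.lists(st.booleans(), min_size=1, max_size=400))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_run_scan(self, pattern):
        rules = WearRules(nonwear_run_min=5)
        wear = detect_nonwear(minutes_frame(pattern), rules)
        assert wear.tolist() == brute_force_nonwear(pattern, 5)


class TestImputeNonwear:
    def test_fully_worn_day_unchanged(self):
        m = minutes_frame([False] * 1440)
        m["wear"] = True
        out = impute_nonwear(m, RULES)
        np.testing.assert_allclose(out["mets"], m["mets"])

    def test_nonwear_minutes_get_09(self):
        m = minutes_frame([False] * 1440, mets=2.0)
        m["wear"] = np.array([True] * 600 + [False] * 840)
        out = impute_nonwear(m, RULES)
        assert (out.loc[~out["wear"], "mets"] == 0.9).all()
        assert (out.loc[out["wear"], "mets"] == 2.0).all()

    def test_missing_minutes_become_nonwear(self):
        m = minutes_frame([False] * 100, mets=1.5)
        m["wear"] = True
        out = impute_nonwear(m, RULES)
        assert len(out) == 1440
        assert out["wear"].sum() == 100
        assert out.loc[~out["wear"], "mets"].eq(0.9).all()

    def test_all_nonwear_day_mean_is_09(self):
        m = minutes_frame([True] * 1440)
        m["wear"] = False
        out = impute_nonwear(m, RULES)
        assert out["mets"].mean() == pytest.approx(0.9)

    def test_wear_plus_nonwear_is_1440(self):
        m = minutes_frame([False] * 700, mets=1.3)
        m["wear"] = np.array([True] * 650 + [False] * 50)
        out = impute_nonwear(m, RULES)
        assert out["wear"].sum() + (~out["wear"]).sum() == 1440


class TestDaySummariesAndSelection:
    def make_days(self, wear_minutes_list):
        frames = []
        for d, w in enumerate(wear_minutes_list):
            m = minutes_frame([False] * 1440, mets=1.8, day=d)
            m["wear"] = np.arange(1440) < w
            frames.append(impute_nonwear(m, RULES))
        return day_summaries(pd.concat(frames, ignore_index=True), RULES)

    def test_valid_day_thresholds(self):
        days = self.make_days([599, 600, 601, 700])
        valid, retained = select_valid(days, RULES)
        assert len(valid) == 3
        assert retained

    def test_two_valid_days_excluded(self):
        days = self.make_days([650, 650])
        valid, retained = select_valid(days, RULES)
        assert len(valid) == 2
        assert not retained

    def test_intensity_minutes_tally_wear_only(self):
        days = self.make_days([600])
        row = days.iloc[0]
        # all wear minutes at 1.8 METs -> light; imputed minutes not tallied
        assert row["light_min"] == 600
        assert row["sedentary_min"] == 0
        assert row["sedentary_min"] + row["light_min"] + row["mvpa_min"] == row["wear_minutes"]

    def test_empty_days_rejected(self):
        with pytest.raises(InputError):
            select_valid(pd.DataFrame(columns=["wear_minutes"]), RULES)

    def test_partial_day_rejected_by_summary(self):
        m = minutes_frame([False] * 100)
        m["wear"] = True
        with pytest.raises(InputError):
            day_summaries(m, RULES)
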