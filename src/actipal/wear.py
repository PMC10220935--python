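"""Minute aggregation, non-wear detection, valid-day selection and imputation.

Epoch METs are averaged into minute-by-minute METs (six 10-s epochs per
minute). A maximal run of at least 60 consecutive zero-count minutes is a
non-wear period; days with at least 600 wear minutes are valid days; a
participant needs at least three valid days to be retained. Non-wear
minutes are imputed at 0.9 METs before energy computation.

"Zero counts" is interpreted at the epoch level: an epoch counts as zero
when both synthesized accelerations are zero at the device's 3 mG
resolution (below half a quantization step), and a minute is a zero
minute when all of its epochs are zero. By default zero runs are
evaluated within each calendar day, matching day-level wear accounting;
set ``WearRules.span_midnight`` to let runs cross midnight.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InputError
from .params import IntensityCutoffs, MetAlgorithmParams, WearRules
from .mets import intensity_category

__all__ = [
    "minute_mets",
    "detect_nonwear",
    "impute_nonwear",
    "day_summaries",
    "select_valid",
]

MINUTES_PER_DAY = 1440


def minute_mets(
    epochs: pd.DataFrame,
    params: MetAlgorithmParams | None = None,
    start_day: int = 0,
    start_minute: int = 0,
) -> pd.DataFrame:
    """Aggregate annotated epochs into minute records.

    Each complete minute's METs is the arithmetic mean of its epochs
    (six at the default 10-s epoch); a trailing partial minute is
    dropped. A minute is flagged ``zero_minute`` when every constituent
    epoch has both synthesized accelerations at zero within the device
    resolution. Minutes are assigned consecutive (day, minute_of_day)
    slots starting at ``start_day``/``start_minute``.

    Returns columns: day, minute_of_day, mets, zero_minute.
    """
    params = params or MetAlgorithmParams()
    if "mets" not in epochs.columns:
        raise InputError("epochs must carry a 'mets' column (run annotate_epochs first)")
    per_min = int(round(60.0 / params.epoch_s))
    n_min = len(epochs) // per_min
    if n_min == 0:
        return pd.DataFrame(
            columns=["day", "minute_of_day", "mets", "zero_minute"]
        ).astype({"day": int, "minute_of_day": int, "mets": float, "zero_minute": bool})
    m = epochs["mets"].to_numpy()[: n_min * per_min].reshape(n_min, per_min)
    fil = epochs["ac_fil_mg"].to_numpy()[: n_min * per_min].reshape(n_min, per_min)
    unfil = epochs["ac_unfil_mg"].to_numpy()[: n_min * per_min].reshape(n_min, per_min)
    tol = params.resolution_mg / 2.0
    zero = ((np.abs(fil) < tol) & (np.abs(unfil) < tol)).all(axis=1)
    slots = start_day * MINUTES_PER_DAY + start_minute + np.arange(n_min)
    return pd.DataFrame(
        {
            "day": slots // MINUTES_PER_DAY,
            "minute_of_day": slots % MINUTES_PER_DAY,
            "mets": m.mean(axis=1),
            "zero_minute": zero,
        }
    )


def _zero_runs(zero: np.ndarray, min_run: int) -> np.ndarray:
    """Boolean mask of positions inside a zero run of length >= min_run."""
    nonwear = np.zeros(zero.size, dtype=bool)
    if zero.size == 0:
        return nonwear
    padded = np.concatenate(([False], zero, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            nonwear[s:e] = True
    return nonwear


def detect_nonwear(minutes: pd.DataFrame, rules: WearRules | None = None) -> np.ndarray:
    """Wear mask over minute records (True = worn).

    Minutes must be contiguous within each day and sorted. Runs of
    ``zero_minute`` shorter than the non-wear threshold remain wear.
    """
    rules = rules or WearRules()
    if "zero_minute" not in minutes.columns:
        raise InputError("minute records must carry a 'zero_minute' column")
    zero = minutes["zero_minute"].to_numpy(dtype=bool)
    if rules.span_midnight:
        nonwear = _zero_runs(zero, rules.nonwear_run_min)
    else:
        nonwear = np.zeros(len(minutes), dtype=bool)
        for _, idx in minutes.groupby("day", sort=False).indices.items():
            nonwear[idx] = _zero_runs(zero[idx], rules.nonwear_run_min)
    return ~nonwear


def impute_nonwear(minutes: pd.DataFrame, rules: WearRules | None = None) -> pd.DataFrame:
    """Expand minute records to full 1440-minute days, imputing non-wear METs.

    ``minutes`` must carry a boolean ``wear`` column (from
    :func:`detect_nonwear` or generator ground truth). Non-wear minutes
    — flagged or simply absent from the record — receive the imputation
    MET value (default 0.9); wear minutes are untouched. Every day
    present in the input is returned with exactly 1440 records.
    """
    rules = rules or WearRules()
    if "wear" not in minutes.columns:
        raise InputError("minute records must carry a 'wear' column")
    days = np.sort(minutes["day"].unique())
    full_index = pd.MultiIndex.from_product(
        [days, np.arange(MINUTES_PER_DAY)], names=["day", "minute_of_day"]
    )
    out = (
        minutes.set_index(["day", "minute_of_day"])
        .reindex(full_index)
        .reset_index()
    )
    out["wear"] = np.where(out["wear"].isna(), False, out["wear"]).astype(bool)
    out.loc[~out["wear"], "mets"] = rules.nonwear_met
    return out


def day_summaries(
    minutes: pd.DataFrame,
    rules: WearRules | None = None,
    cutoffs: IntensityCutoffs | None = None,
) -> pd.DataFrame:
    """Per-day wear time, mean METs and intensity-minute tallies.

    Expects imputed full-day records (1440 minutes per day with ``wear``
    and ``mets``). Mean METs covers the whole day (imputed minutes
    included); intensity minutes are tallied over wear time only, since
    imputed minutes are an assumption rather than observed behaviour.
    """
    rules = rules or WearRules()
    cutoffs = cutoffs or IntensityCutoffs()
    rows = []
    for day, grp in minutes.groupby("day", sort=True):
        if len(grp) != MINUTES_PER_DAY:
            raise InputError(
                f"day {day} has {len(grp)} minute records; impute to 1440 first"
            )
        wear = grp["wear"].to_numpy(dtype=bool)
        mets = grp["mets"].to_numpy(dtype=float)
        cats = intensity_category(mets[wear], cutoffs)
        rows.append(
            {
                "day": day,
                "wear_minutes": int(wear.sum()),
                "mean_mets": float(mets.mean()),
                "sedentary_min": int((cats == "sedentary").sum()),
                "light_min": int((cats == "light").sum()),
                "mvpa_min": int((cats == "mvpa").sum()),
            }
        )
    out = pd.DataFrame(rows)
    out["valid"] = out["wear_minutes"] >= rules.valid_day_min
    return out


def select_valid(days: pd.DataFrame, rules: WearRules | None = None):
    """Valid-day subset and participant retention decision.

    Returns ``(valid_days, retained)`` where ``retained`` is True when the
    participant has at least ``rules.min_valid_days`` valid days.
    """
    rules = rules or WearRules()
    if len(days) == 0:
        raise InputError("at least one day record is required")
    valid = days[days["wear_minutes"] >= rules.valid_day_min].copy()
    return valid, len(valid) >= rules.min_valid_days
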