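"""CSV interchange formats and schedule/config file parsing.

All interchange is plain CSV with headers, UTF-8, decimal point:

* raw signal:  time_s, ax_mg, ay_mg, az_mg
* epochs:      epoch_index, ac_fil_mg, ac_unfil_mg (+ columns appended
               by MET annotation)
* minutes:     day, minute_of_day, mets, wear
* cohort:      id, sex, age_y, stature_cm, weight_kg,
               measured_bmr_kcal_d, measured_tee_kcal_d
* schedules:   YAML list of {kind, duration_s, amplitude_mg?, ...}

Readers validate the header and unit invariants; a malformed file raises
a :class:`ParseError` naming the offending column or row rather than
silently defaulting.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .energy import Anthropometry, MeasuredEnergy
from .epochs import RawTriaxialSignal
from .exceptions import InputError, ParseError
from .synthetic import ActivitySegment

__all__ = [
    "read_raw_signal",
    "write_raw_signal",
    "read_epochs",
    "write_epochs",
    "read_minutes",
    "write_minutes",
    "read_cohort",
    "write_cohort",
    "read_schedule",
]

SIGNAL_COLS = ["time_s", "ax_mg", "ay_mg", "az_mg"]
EPOCH_COLS = ["epoch_index", "ac_fil_mg", "ac_unfil_mg"]
MINUTE_COLS = ["day", "minute_of_day", "mets", "wear"]
COHORT_COLS = [
    "id", "sex", "age_y", "stature_cm", "weight_kg",
    "measured_bmr_kcal_d", "measured_tee_kcal_d",
]


def _read_checked(path, required) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pandas raises several parse exception types
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_raw_signal(path) -> RawTriaxialSignal:
    """Load a raw triaxial stream; the sampling rate is inferred from time_s."""
    df = _read_checked(path, SIGNAL_COLS)
    if len(df) < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    dt = np.diff(df["time_s"].to_numpy())
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
        raise ParseError(f"{path}: time_s must be uniformly increasing")
    fs = 1.0 / dt[0]
    return RawTriaxialSignal(df[["ax_mg", "ay_mg", "az_mg"]].to_numpy(), sampling_rate_hz=fs)


def write_raw_signal(sig: RawTriaxialSignal, path) -> None:
    t = np.arange(sig.n_samples) / sig.sampling_rate_hz
    pd.DataFrame(
        {"time_s": t, "ax_mg": sig.data[:, 0], "ay_mg": sig.data[:, 1], "az_mg": sig.data[:, 2]}
    ).to_csv(path, index=False)


def read_epochs(path) -> pd.DataFrame:
    df = _read_checked(path, EPOCH_COLS)
    bad = df.index[(df["ac_fil_mg"] < 0) | (df["ac_unfil_mg"] < 0)]
    if len(bad):
        raise ParseError(f"{path}: negative acceleration at row {int(bad[0]) + 2}")
    return df


def write_epochs(epochs: pd.DataFrame, path) -> None:
    epochs.to_csv(path, index=False)


def read_minutes(path) -> pd.DataFrame:
    df = _read_checked(path, MINUTE_COLS)
    df["wear"] = df["wear"].astype(bool)
    return df


def write_minutes(minutes: pd.DataFrame, path) -> None:
    minutes.to_csv(path, index=False)


def read_cohort(path) -> list[tuple[str, Anthropometry, MeasuredEnergy]]:
    """Load a cohort table as (id, anthropometry, measured) triplets.

    Unit invariants (age, stature, weight ranges; positive energies) are
    enforced row by row.
    """
    df = _read_checked(path, COHORT_COLS)
    out = []
    for i, row in df.iterrows():
        try:
            anthro = Anthropometry(
                sex=str(row["sex"]),
                age_y=float(row["age_y"]),
                stature_cm=float(row["stature_cm"]),
                weight_kg=float(row["weight_kg"]),
            )
            measured = MeasuredEnergy(
                bmr_kcal_d=float(row["measured_bmr_kcal_d"]),
                tee_kcal_d=float(row["measured_tee_kcal_d"]),
            )
        except (InputError, ValueError) as exc:
            raise ParseError(f"{path}: row {int(i) + 2}: {exc}") from exc
        out.append((str(row["id"]), anthro, measured))
    return out


def write_cohort(cohort: pd.DataFrame, path) -> None:
    missing = [c for c in COHORT_COLS if c not in cohort.columns]
    if missing:
        raise InputError(f"cohort table missing column(s) {missing}")
    cohort[COHORT_COLS].to_csv(path, index=False)


def read_schedule(path) -> list[ActivitySegment]:
    """Parse a YAML schedule file into activity segments."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ParseError(f"{path}: schedule must be a non-empty YAML list")
    allowed = {"kind", "duration_s", "amplitude_mg", "fundamental_hz", "low_freq_fraction"}
    segs = []
    for i, item in enumerate(raw):
        if not isinstance(item, dict):
            raise ParseError(f"{path}: entry {i} is not a mapping")
        unknown = set(item) - allowed
        if unknown:
            raise ParseError(f"{path}: entry {i} has unknown key(s) {sorted(unknown)}")
        try:
            segs.append(ActivitySegment(**item))
        except (InputError, TypeError) as exc:
            raise ParseError(f"{path}: entry {i}: {exc}") from exc
    return segs
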