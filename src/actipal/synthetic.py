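"""Synthetic raw signals, activity schedules and cohorts with known ground truth.

Two generators make every downstream stage testable without device data:

``gen_activity_signal``
    Turns a schedule of activity segments into a 32 Hz triaxial stream
    quantized to 3 mG. Segment designs are minimal signals engineered to
    land robustly on the intended side of the classifier's thresholds:

    * locomotive — a sinusoid at the gait fundamental (default 2 Hz,
      above the 0.7 Hz filter cutoff) on the vertical axis plus white
      sensor noise: the filter passes nearly everything, so the
      unfiltered/filtered ratio sits near 1, well below 1.16;
    * non-locomotive — the same carrier with a 0.2 Hz low-frequency
      component (default half the amplitude budget): the slow component
      survives only in the unfiltered epoch value, pushing the ratio
      above 1.16;
    * sedentary — white noise of small amplitude (default 5 mG), keeping
      the filtered epoch magnitude far below the 29.9 mG threshold;
    * non-wear — exact zeros on all axes.

``gen_cohort``
    Draws anthropometry from per-sex truncated normal distributions,
    builds each participant a multi-day minute-level MET stream from a
    random daily schedule (a long overnight non-wear block plus a
    sedentary/light/MVPA wear mixture that varies between participants
    and days), computes the monitor-predicted PAL through the actual
    energy model, and generates the "measured" reference values from a
    known linear truth: measured PAL = slope x predicted PAL + intercept
    + Normal(0, resid_sd); measured BMR = Ganpule prediction with
    multiplicative noise (default CV 7 %, typical indirect-calorimetry
    repeatability); measured TEE = measured PAL x measured BMR.

All randomness derives from a single top-level seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .energy import Anthropometry, MeasuredEnergy, ganpule_bmr, pal_from_minutes
from .exceptions import InputError
from .params import EnergyParams, MetAlgorithmParams
from .wear import MINUTES_PER_DAY

__all__ = [
    "ActivitySegment",
    "AnthroDistribution",
    "CohortSpec",
    "SyntheticParticipant",
    "gen_activity_signal",
    "gen_cohort",
    "cohort_frame",
    "WOMEN_TABLE",
    "MEN_TABLE",
]

SEGMENT_KINDS = ("sedentary", "locomotive", "non_locomotive", "non_wear")

#: sensor noise floor added to worn segments, mG (order of the 3 mG resolution)
SENSOR_NOISE_MG = 5.0


@dataclass(frozen=True)
class ActivitySegment:
    """One scheduled block of a synthetic recording."""

    kind: str
    duration_s: float
    amplitude_mg: float | None = None
    fundamental_hz: float = 2.0
    low_freq_fraction: float = 0.5

    _DEFAULT_AMPLITUDE = {
        "sedentary": 5.0,
        "locomotive": 200.0,
        "non_locomotive": 200.0,
        "non_wear": 0.0,
    }

    def __post_init__(self):
        if self.kind not in SEGMENT_KINDS:
            raise InputError(f"unknown segment kind {self.kind!r}")
        if self.duration_s <= 0:
            raise InputError("segment duration must be positive")
        if self.amplitude_mg is None:
            object.__setattr__(
                self, "amplitude_mg", self._DEFAULT_AMPLITUDE[self.kind]
            )
        if self.amplitude_mg < 0:
            raise InputError("amplitude must be non-negative")
        if self.kind == "non_wear" and self.amplitude_mg != 0:
            raise InputError("non_wear segments must have zero amplitude")
        if not 0 <= self.low_freq_fraction <= 1:
            raise InputError("low_freq_fraction must lie in [0, 1]")


def _segment_samples(seg: ActivitySegment, fs: float, rng: np.random.Generator) -> np.ndarray:
    n = int(round(seg.duration_s * fs))
    if seg.kind == "non_wear":
        return np.zeros((n, 3))
    if seg.kind == "sedentary":
        # pure sensor noise at the segment amplitude
        return rng.normal(0.0, seg.amplitude_mg, (n, 3))
    out = rng.normal(0.0, SENSOR_NOISE_MG, (n, 3))
    t = np.arange(n) / fs
    if seg.kind == "locomotive":
        phase = rng.uniform(0, 2 * np.pi)
        out[:, 2] += seg.amplitude_mg * np.sin(2 * np.pi * seg.fundamental_hz * t + phase)
    elif seg.kind == "non_locomotive":
        f = seg.low_freq_fraction
        phase1 = rng.uniform(0, 2 * np.pi)
        phase2 = rng.uniform(0, 2 * np.pi)
        out[:, 2] += (1 - f) * seg.amplitude_mg * np.sin(
            2 * np.pi * seg.fundamental_hz * t + phase1
        )
        out[:, 2] += f * seg.amplitude_mg * np.sin(2 * np.pi * 0.2 * t + phase2)
    return out


def gen_activity_signal(
    schedule,
    params: MetAlgorithmParams | None = None,
    seed: int = 0,
    quantize: bool = True,
):
    """Render a schedule of :class:`ActivitySegment` into a raw triaxial signal.

    Output is sampled at the device rate (default 32 Hz) and, unless
    ``quantize=False``, rounded to the device resolution grid (3 mG).
    Non-wear segments are exactly zero after quantization. Identical
    (schedule, seed) pairs give bit-identical output.
    """
    from .epochs import RawTriaxialSignal  # local import to avoid cycle at module load

    params = params or MetAlgorithmParams()
    if not schedule:
        raise InputError("schedule must contain at least one segment")
    rng = np.random.default_rng(seed)
    parts = [_segment_samples(seg, params.sampling_rate_hz, rng) for seg in schedule]
    sig = RawTriaxialSignal(
        np.concatenate(parts, axis=0),
        sampling_rate_hz=params.sampling_rate_hz,
        resolution_mg=params.resolution_mg,
    )
    return sig.quantize() if quantize else sig


@dataclass(frozen=True)
class AnthroDistribution:
    """Per-sex normal anthropometry distribution (mean, SD) triplets."""

    age_mean: float
    age_sd: float
    stature_mean: float
    stature_sd: float
    weight_mean: float
    weight_sd: float

    def __post_init__(self):
        if min(self.age_sd, self.stature_sd, self.weight_sd) < 0:
            raise InputError("all SDs must be non-negative")


#: Anthropometry of the community-dwelling older Japanese validation cohort.
WOMEN_TABLE = AnthroDistribution(74.0, 6.0, 149.4, 6.6, 52.5, 9.8)
MEN_TABLE = AnthroDistribution(75.0, 5.0, 162.0, 4.8, 62.7, 9.4)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic validation cohort with known linear truth."""

    n_women: int = 47
    n_men: int = 22
    women: AnthroDistribution = WOMEN_TABLE
    men: AnthroDistribution = MEN_TABLE
    true_slope: float = 0.949
    true_intercept: float = 0.205
    resid_sd: float = 0.20
    bmr_noise_cv: float = 0.07
    n_days: int = 7
    seed: int = 0

    def __post_init__(self):
        if self.n_women < 0 or self.n_men < 0:
            raise InputError("participant counts must be non-negative")
        if self.n_women + self.n_men == 0:
            raise InputError("cohort must contain at least one participant")
        if self.resid_sd < 0 or self.bmr_noise_cv < 0:
            raise InputError("noise SDs must be non-negative")
        if self.n_days < 1:
            raise InputError("n_days must be at least 1")


@dataclass
class SyntheticParticipant:
    """One simulated participant: covariates, reference values, minute stream, truth."""

    pid: str
    anthropometry: Anthropometry
    measured: MeasuredEnergy
    minutes: pd.DataFrame  # day, minute_of_day, mets, wear
    truth: dict


def _truncated_normal(rng, mean, sd, lo, hi, n):
    """Normal draw truncated at +-3 SD and clipped into the physical range."""
    x = rng.normal(mean, sd, n)
    if sd > 0:
        x = np.clip(x, mean - 3 * sd, mean + 3 * sd)
    return np.clip(x, lo, hi)


def _minute_stream(rng, trait: float, n_days: int):
    """Minute METs + wear flags for one participant.

    Each day: an overnight non-wear block (~8 h), then wear minutes drawn
    from a sedentary/light/MVPA mixture whose composition shifts with the
    participant's activity trait and a small day-to-day wobble.
    """
    mets = np.full((n_days, MINUTES_PER_DAY), np.nan)
    wear = np.ones((n_days, MINUTES_PER_DAY), dtype=bool)
    for d in range(n_days):
        sleep = int(np.clip(rng.normal(480, 45), 300, 700))
        wear[d, :sleep] = False
        n_wear = MINUTES_PER_DAY - sleep
        p_mvpa = float(np.clip(0.06 + 0.03 * trait + 0.015 * rng.normal(), 0.005, 0.25))
        p_light = float(np.clip(0.35 + 0.08 * trait + 0.03 * rng.normal(), 0.05, 0.70))
        p_sed = max(1.0 - p_mvpa - p_light, 0.0)
        probs = np.array([p_sed, p_light, p_mvpa])
        probs /= probs.sum()
        cat = rng.choice(3, size=n_wear, p=probs)
        vals = np.empty(n_wear)
        vals[cat == 0] = rng.uniform(0.9, 1.5, (cat == 0).sum())
        vals[cat == 1] = rng.uniform(1.6, 2.9, (cat == 1).sum())
        vals[cat == 2] = rng.uniform(3.0, 6.0, (cat == 2).sum())
        mets[d, sleep:] = vals
    return mets, wear


def gen_cohort(spec: CohortSpec | None = None) -> list[SyntheticParticipant]:
    """Simulate a cohort under the configured linear measured-vs-predicted truth."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    energy_params = EnergyParams()
    participants: list[SyntheticParticipant] = []
    groups = [("F", spec.n_women, spec.women), ("M", spec.n_men, spec.men)]
    counter = 0
    for sex, n, dist in groups:
        ages = _truncated_normal(rng, dist.age_mean, dist.age_sd, 18, 110, n)
        statures = _truncated_normal(rng, dist.stature_mean, dist.stature_sd, 100, 220, n)
        weights = _truncated_normal(rng, dist.weight_mean, dist.weight_sd, 25, 200, n)
        for i in range(n):
            counter += 1
            anthro = Anthropometry(
                sex=sex,
                age_y=float(ages[i]),
                stature_cm=float(statures[i]),
                weight_kg=float(weights[i]),
            )
            trait = float(rng.normal())
            met_mat, wear_mat = _minute_stream(rng, trait, spec.n_days)
            imputed = np.where(wear_mat, met_mat, 0.9)
            bmr_pred = ganpule_bmr(anthro)
            _, _, pal_pred = pal_from_minutes(imputed, bmr_pred, energy_params)
            noise = float(rng.normal(0.0, spec.resid_sd))
            pal_meas = spec.true_slope * pal_pred + spec.true_intercept + noise
            pal_meas = max(pal_meas, 1.05)  # PAL below ~1 is nonphysical
            bmr_meas = bmr_pred * max(
                1.0 + float(rng.normal(0.0, spec.bmr_noise_cv)), 0.5
            )
            measured = MeasuredEnergy(bmr_kcal_d=bmr_meas, tee_kcal_d=pal_meas * bmr_meas)
            minutes = pd.DataFrame(
                {
                    "day": np.repeat(np.arange(spec.n_days), MINUTES_PER_DAY),
                    "minute_of_day": np.tile(np.arange(MINUTES_PER_DAY), spec.n_days),
                    "mets": met_mat.ravel(),
                    "wear": wear_mat.ravel(),
                }
            )
            participants.append(
                SyntheticParticipant(
                    pid=f"{sex}{counter:03d}",
                    anthropometry=anthro,
                    measured=measured,
                    minutes=minutes,
                    truth={
                        "pal_pred": pal_pred,
                        "pal_noise": noise,
                        "trait": trait,
                    },
                )
            )
    return participants


def cohort_frame(participants: list[SyntheticParticipant]) -> pd.DataFrame:
    """Cohort table in the interchange schema (one row per participant)."""
    return pd.DataFrame(
        {
            "id": [p.pid for p in participants],
            "sex": [p.anthropometry.sex for p in participants],
            "age_y": [p.anthropometry.age_y for p in participants],
            "stature_cm": [p.anthropometry.stature_cm for p in participants],
            "weight_kg": [p.anthropometry.weight_kg for p in participants],
            "measured_bmr_kcal_d": [p.measured.bmr_kcal_d for p in participants],
            "measured_tee_kcal_d": [p.measured.tee_kcal_d for p in participants],
        }
    )
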