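"""Parameter sets of the activity-monitor processing chain and energy model.

All numerical defaults are the constants of the Active style Pro (ASP)
waist-worn triaxial accelerometer algorithm and of the downstream
BMR/TEE/PAL energy model for Japanese adults: the 29.9 mG sedentary
threshold, the 1.16 unfiltered/filtered acceleration ratio separating
non-locomotive (household-type) from locomotive (ambulatory) activity,
the three linear MET equations, the Ganpule basal-metabolic-rate
equation, the x1.1 resting-metabolic-rate factor and the x10/9
diet-induced-thermogenesis factor, the Nagayoshi older-adult MET
adjustment, and the sex-specific PAL correction equations fitted on
community-dwelling older adults.
"""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "LinearMetEquation",
    "MetAlgorithmParams",
    "NagayoshiModel",
    "IntensityCutoffs",
    "WearRules",
    "GanpuleParams",
    "EnergyParams",
    "CorrectionModel",
    "WOMEN_CORRECTION",
    "MEN_CORRECTION",
]


@dataclass(frozen=True)
class LinearMetEquation:
    """METs as an affine function of the filtered synthesized acceleration (mG)."""

    intercept: float
    slope: float

    def __call__(self, ac_fil):
        return self.intercept + self.slope * ac_fil


@dataclass(frozen=True)
class MetAlgorithmParams:
    """Constants of the epoch classifier and the three MET equations.

    ``sed_threshold_mg``
        Filtered acceleration at or below which an epoch is sedentary.
    ``ratio_threshold``
        ACunfil/ACfil ratio at or above which a non-sedentary epoch is
        non-locomotive; below it, locomotive.
    """

    sed_threshold_mg: float = 29.9
    ratio_threshold: float = 1.16
    sedentary: LinearMetEquation = LinearMetEquation(0.8823, 0.0351)
    non_locomotive: LinearMetEquation = LinearMetEquation(1.3435, 0.0196)
    locomotive: LinearMetEquation = LinearMetEquation(1.1128, 0.0086)
    cutoff_hz: float = 0.7
    filter_order: int = 4
    epoch_s: float = 10.0
    sampling_rate_hz: float = 32.0
    resolution_mg: float = 3.0


@dataclass(frozen=True)
class NagayoshiModel:
    """Older-adult MET adjustment: adjusted = slope * METs + intercept."""

    slope: float = 1.191
    intercept: float = 0.106


@dataclass(frozen=True)
class IntensityCutoffs:
    """MET cut-points of the intensity categories (sedentary / light / MVPA)."""

    sedentary_max: float = 1.5
    mvpa_min: float = 3.0

    def __post_init__(self):
        if not self.sedentary_max < self.mvpa_min:
            raise ValueError("sedentary_max must be below mvpa_min")


@dataclass(frozen=True)
class WearRules:
    """Non-wear detection, valid-day and participant-inclusion rules.

    A maximal run of >= ``nonwear_run_min`` consecutive zero-count minutes
    is non-wear; a day is valid with >= ``valid_day_min`` wear minutes; a
    participant is retained with >= ``min_valid_days`` valid days. Non-wear
    minutes are imputed at ``nonwear_met`` METs. ``span_midnight`` controls
    whether zero runs may cross a day boundary (the device-macro convention
    of breaking runs at midnight is the default).
    """

    nonwear_run_min: int = 60
    valid_day_min: int = 600
    min_valid_days: int = 3
    nonwear_met: float = 0.9
    span_midnight: bool = False


@dataclass(frozen=True)
class GanpuleParams:
    """Coefficients of the Ganpule BMR equation for Japanese adults (MJ/day)."""

    c0: float = 0.1238
    c_weight: float = 0.0481  # per kg
    c_stature: float = 0.0234  # per cm
    c_age: float = 0.0138  # per year
    sex_coef: float = 0.5473  # x1 for men, x2 for women
    mj_to_kcal: float = 1000.0 / 4.186


@dataclass(frozen=True)
class EnergyParams:
    """Energy-model factors: RMR = rmr_factor x BMR; TEE = (BMR + AEE) x dit_factor."""

    rmr_factor: float = 1.1
    dit_factor: float = 10.0 / 9.0
    minutes_per_day: int = 1440


@dataclass(frozen=True)
class CorrectionModel:
    """Sex-specific linear map from monitor-predicted PAL (X) to actual PAL (Y)."""

    sex: str
    slope: float
    intercept: float
    resid_sd: float = 0.0

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be non-negative")

    def __call__(self, pal_pred):
        return self.slope * pal_pred + self.intercept


#: Published correction equations for community-dwelling older adults.
WOMEN_CORRECTION = CorrectionModel(sex="F", slope=0.949, intercept=0.205, resid_sd=0.20)
MEN_CORRECTION = CorrectionModel(sex="M", slope=0.899, intercept=0.371, resid_sd=0.17)
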