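"""BMR, activity energy expenditure, TEE and PAL prediction.

The energy model stacks:

* Ganpule BMR (MJ/day, converted to kcal/day by x1000/4.186)::

      BMR = (0.1238 + 0.0481 x weight_kg + 0.0234 x stature_cm
             - 0.0138 x age_y - 0.5473 x {1 men, 2 women}) x 1000/4.186

* activity energy expenditure from minute-by-minute METs against a
  resting metabolic rate of 1.1 x predicted BMR::

      AEE = sum_minutes (METs - 1) x (1.1 x BMR / 1440)

  Imputed non-wear minutes (0.9 METs) contribute small negative terms;
  they are retained. The (METs - 1) form is the convention of this
  device family's validation literature: multiplying raw METs by the
  full RMR would double-count basal expenditure and implies a
  physiologically impossible 24-h MET average when back-calculated from
  published TEE values. The alternative is available for sensitivity
  analysis via ``daily_aee(..., subtract_rest=False)``.

* TEE = (BMR + AEE) x 10/9 — diet-induced thermogenesis is one tenth of
  TEE — and PAL = TEE / BMR.

* the sex-specific PAL correction, Y = slope x X + intercept, mapping
  the monitor-predicted PAL for young adults onto the actual PAL of
  older adults, and corrected TEE = corrected PAL x BMR (predicted or
  measured, caller's choice).

Multi-day recordings are handled by computing AEE/TEE/PAL per valid day
and averaging across valid days with equal weights.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InputError
from .mets import nagayoshi_adjust
from .params import (
    CorrectionModel,
    EnergyParams,
    GanpuleParams,
    NagayoshiModel,
    WearRules,
)

__all__ = [
    "Anthropometry",
    "MeasuredEnergy",
    "PredictedEnergy",
    "ganpule_bmr",
    "daily_aee",
    "tee_and_pal",
    "correct_pal",
    "corrected_tee",
    "pal_from_minutes",
    "participant_energy",
]


@dataclass(frozen=True)
class Anthropometry:
    """Sex and body measures used by the Ganpule BMR equation."""

    sex: str  # 'F' or 'M'
    age_y: float
    stature_cm: float
    weight_kg: float

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise InputError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not 18 <= self.age_y <= 110:
            raise InputError(f"age {self.age_y} outside [18, 110] years")
        if not 100 <= self.stature_cm <= 220:
            raise InputError(f"stature {self.stature_cm} outside [100, 220] cm")
        if not 25 <= self.weight_kg <= 200:
            raise InputError(f"weight {self.weight_kg} outside [25, 200] kg")


@dataclass(frozen=True)
class MeasuredEnergy:
    """Reference BMR and TEE (indirect calorimetry / doubly labeled water style)."""

    bmr_kcal_d: float
    tee_kcal_d: float

    def __post_init__(self):
        if self.bmr_kcal_d <= 0 or self.tee_kcal_d <= 0:
            raise InputError("measured energies must be positive")

    @property
    def pal(self) -> float:
        return self.tee_kcal_d / self.bmr_kcal_d


@dataclass
class PredictedEnergy:
    """The predicted energy stack for one participant."""

    bmr_pred: float
    aee_pred: float
    tee_pred: float
    pal_pred: float
    pal_nagayoshi: float
    tee_nagayoshi: float
    pal_corrected: float | None = None
    tee_corrected: float | None = None


def ganpule_bmr(anthro: Anthropometry, params: GanpuleParams | None = None) -> float:
    """Predicted basal metabolic rate in kcal/day from the Ganpule equation."""
    p = params or GanpuleParams()
    sex_term = p.sex_coef * (2.0 if anthro.sex == "F" else 1.0)
    mj = (
        p.c0
        + p.c_weight * anthro.weight_kg
        + p.c_stature * anthro.stature_cm
        - p.c_age * anthro.age_y
        - sex_term
    )
    kcal = mj * p.mj_to_kcal
    if kcal <= 0:
        raise InputError("BMR prediction is non-positive for the given anthropometry")
    return kcal


def daily_aee(
    minute_mets,
    bmr_pred: float,
    params: EnergyParams | None = None,
    subtract_rest: bool = True,
):
    """Activity energy expenditure of full 1440-minute days, kcal/day.

    ``minute_mets`` is a length-1440 vector or an (n_days, 1440) matrix of
    imputed minute METs. Each minute contributes
    ``(METs - 1) x rmr_factor x BMR / 1440``; minutes below 1 MET
    (e.g. imputed 0.9) contribute negatively. ``subtract_rest=False``
    switches to the literal raw-METs x RMR reading for sensitivity
    analysis.
    """
    p = params or EnergyParams()
    m = np.atleast_2d(np.asarray(minute_mets, dtype=float))
    if m.shape[-1] != p.minutes_per_day:
        raise InputError(
            f"expected {p.minutes_per_day} minutes per day, got {m.shape[-1]}"
        )
    if bmr_pred <= 0:
        raise InputError("bmr_pred must be positive")
    rmr_per_min = p.rmr_factor * bmr_pred / p.minutes_per_day
    base = m - 1.0 if subtract_rest else m
    aee = (base * rmr_per_min).sum(axis=1)
    return float(aee[0]) if np.asarray(minute_mets).ndim == 1 else aee


def tee_and_pal(bmr_pred: float, aee_pred, params: EnergyParams | None = None):
    """TEE = (BMR + AEE) x 10/9 and PAL = TEE / BMR."""
    p = params or EnergyParams()
    if bmr_pred <= 0:
        raise InputError("bmr_pred must be positive")
    tee = (bmr_pred + np.asarray(aee_pred, dtype=float)) * p.dit_factor
    pal = tee / bmr_pred
    if np.ndim(aee_pred) == 0:
        return float(tee), float(pal)
    return tee, pal


def correct_pal(pal_pred: float, model: CorrectionModel) -> float:
    """Apply the sex-specific PAL correction Y = slope x X + intercept."""
    if model is None:
        raise InputError("a sex-specific correction model is required")
    return model(pal_pred)


def corrected_tee(pal_corrected: float, bmr_kcal_d: float) -> float:
    """TEE from a corrected PAL and a BMR (predicted or measured)."""
    if bmr_kcal_d <= 0:
        raise InputError("BMR must be positive")
    return pal_corrected * bmr_kcal_d


def pal_from_minutes(
    minute_mets,
    bmr_pred: float,
    params: EnergyParams | None = None,
):
    """Mean (AEE, TEE, PAL) over the supplied full days, equally weighted.

    ``minute_mets``: (n_days, 1440) matrix of imputed minute METs for the
    valid days only.
    """
    m = np.atleast_2d(np.asarray(minute_mets, dtype=float))
    aee = daily_aee(m, bmr_pred, params)
    tee, pal = tee_and_pal(bmr_pred, aee, params)
    return float(np.mean(aee)), float(np.mean(tee)), float(np.mean(pal))


def _valid_day_matrix(minutes: pd.DataFrame, rules: WearRules) -> np.ndarray:
    """(n_valid_days, 1440) MET matrix from imputed minute records."""
    p = EnergyParams()
    days = []
    for _, grp in minutes.groupby("day", sort=True):
        if len(grp) != p.minutes_per_day:
            raise InputError("minutes must be imputed to full 1440-minute days")
        if int(grp["wear"].sum()) >= rules.valid_day_min:
            days.append(grp.sort_values("minute_of_day")["mets"].to_numpy())
    if not days:
        raise InputError("no valid days for this participant")
    return np.vstack(days)


def participant_energy(
    minutes: pd.DataFrame,
    anthro: Anthropometry,
    rules: WearRules | None = None,
    energy_params: EnergyParams | None = None,
    nagayoshi: NagayoshiModel | None = None,
    correction: CorrectionModel | None = None,
    bmr_for_corrected_tee: float | None = None,
) -> PredictedEnergy:
    """Full predicted energy stack from imputed minute records.

    AEE/TEE/PAL are computed per valid day and averaged. The Nagayoshi
    variant adjusts wear-minute METs only; imputed non-wear minutes keep
    their 0.9 MET assignment (the imputation encodes assumed rest, not a
    device reading to be recalibrated). If ``correction`` is given, the
    corrected PAL and TEE are filled in, the latter against
    ``bmr_for_corrected_tee`` (defaults to the predicted BMR).
    """
    rules = rules or WearRules()
    nagayoshi = nagayoshi or NagayoshiModel()
    bmr = ganpule_bmr(anthro)
    mat = _valid_day_matrix(minutes, rules)
    aee, tee, pal = pal_from_minutes(mat, bmr, energy_params)

    wear_mat = np.vstack(
        [
            grp.sort_values("minute_of_day")["wear"].to_numpy(dtype=bool)
            for _, grp in minutes.groupby("day", sort=True)
            if int(grp["wear"].sum()) >= rules.valid_day_min
        ]
    )
    adj = np.where(wear_mat, nagayoshi_adjust(mat, nagayoshi), mat)
    _, tee_nag, pal_nag = pal_from_minutes(adj, bmr, energy_params)

    pred = PredictedEnergy(
        bmr_pred=bmr,
        aee_pred=aee,
        tee_pred=tee,
        pal_pred=pal,
        pal_nagayoshi=pal_nag,
        tee_nagayoshi=tee_nag,
    )
    if correction is not None:
        if correction.sex != anthro.sex:
            raise InputError(
                f"correction model sex {correction.sex!r} does not match participant {anthro.sex!r}"
            )
        pred.pal_corrected = correct_pal(pal, correction)
        pred.tee_corrected = corrected_tee(
            pred.pal_corrected, bmr_for_corrected_tee or bmr
        )
    return pred
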