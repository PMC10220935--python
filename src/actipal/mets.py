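"""Epoch classification and MET assignment.

The device's algorithm is three printed conditionals on the synthesized
filtered acceleration (ACfil, mG) and the unfiltered/filtered ratio:

* ACfil below 29.9 mG -> sedentary,  MET = 0.8823 + 0.0351 x ACfil
* else ratio >= 1.16  -> non-locomotive, MET = 1.3435 + 0.0196 x ACfil
* else                -> locomotive,     MET = 1.1128 + 0.0086 x ACfil

Equality at 29.9 mG is unassigned in the printed algorithm and resolved
here to sedentary: at that point the sedentary and non-locomotive
equations differ by less than 0.01 MET, so the assignment is continuous
for all practical purposes. When ACfil = 0 the ratio is undefined; such
epochs are sedentary by the first branch and the ratio is never formed.

Also provided: the Nagayoshi older-adult MET adjustment (an affine map
applied to device METs) and the intensity categorization on the
continuous MET scale (sedentary <= 1.5, light in (1.5, 3.0), MVPA >= 3.0).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InputError
from .params import IntensityCutoffs, MetAlgorithmParams, NagayoshiModel

__all__ = [
    "classify_epoch",
    "met_value",
    "nagayoshi_adjust",
    "intensity_category",
    "annotate_epochs",
]

CLASSES = ("sedentary", "locomotive", "non_locomotive")
INTENSITIES = ("sedentary", "light", "mvpa")


def _as_array(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def classify_epoch(ac_fil, ac_unfil, params: MetAlgorithmParams | None = None):
    """Activity class of one epoch (or elementwise of arrays of epochs).

    Total and deterministic: every (ac_fil, ac_unfil) pair with
    non-negative entries maps to exactly one of ``sedentary``,
    ``locomotive``, ``non_locomotive``.
    """
    params = params or MetAlgorithmParams()
    fil, scalar = _as_array(ac_fil)
    unfil, _ = _as_array(ac_unfil)
    fil, unfil = np.broadcast_arrays(fil, unfil)
    if np.any(fil < 0) or np.any(unfil < 0):
        raise InputError("synthesized accelerations must be non-negative")
    sed = fil <= params.sed_threshold_mg
    # ratio guarded: sedentary epochs (including ac_fil == 0) never evaluate it
    ratio = np.divide(unfil, fil, out=np.zeros_like(unfil), where=~sed)
    out = np.select(
        [sed, ratio >= params.ratio_threshold],
        ["sedentary", "non_locomotive"],
        default="locomotive",
    )
    return out.item() if scalar else out


def met_value(activity_class, ac_fil, params: MetAlgorithmParams | None = None):
    """MET value from the class-specific linear equation."""
    params = params or MetAlgorithmParams()
    fil, scalar = _as_array(ac_fil)
    cls = np.asarray(activity_class)
    cls, fil = np.broadcast_arrays(cls, fil)
    if np.any(fil < 0):
        raise InputError("ac_fil must be non-negative")
    known = np.isin(cls, CLASSES)
    if not known.all():
        bad = np.unique(cls[~known])
        raise InputError(f"unknown activity class(es): {bad.tolist()}")
    mets = np.select(
        [cls == "sedentary", cls == "non_locomotive"],
        [params.sedentary(fil), params.non_locomotive(fil)],
        default=params.locomotive(fil),
    )
    return float(mets) if scalar else mets


def nagayoshi_adjust(mets, model: NagayoshiModel | None = None):
    """Older-adult MET adjustment: adjusted = 1.191 x METs + 0.106.

    Monotone affine map; applied per epoch or per minute.
    """
    model = model or NagayoshiModel()
    arr, scalar = _as_array(mets)
    out = model.slope * arr + model.intercept
    return float(out) if scalar else out


def intensity_category(mets, cutoffs: IntensityCutoffs | None = None):
    """Intensity label on the continuous MET scale.

    ``sedentary`` at or below 1.5 METs, ``light`` strictly between 1.5 and
    3.0, ``mvpa`` at or above 3.0. The conventional "1.6-2.9" labelling of
    light activity is the discrete reading of the open interval.
    """
    cutoffs = cutoffs or IntensityCutoffs()
    arr, scalar = _as_array(mets)
    out = np.select(
        [arr <= cutoffs.sedentary_max, arr >= cutoffs.mvpa_min],
        ["sedentary", "mvpa"],
        default="light",
    )
    return out.item() if scalar else out


def annotate_epochs(
    epochs: pd.DataFrame,
    params: MetAlgorithmParams | None = None,
    nagayoshi: NagayoshiModel | None = None,
    cutoffs: IntensityCutoffs | None = None,
) -> pd.DataFrame:
    """Append activity_class, mets, mets_adjusted and intensity columns.

    ``epochs`` must carry ``ac_fil_mg`` and ``ac_unfil_mg`` (the output of
    :func:`actipal.epochs.epochize`).
    """
    params = params or MetAlgorithmParams()
    out = epochs.copy()
    fil = out["ac_fil_mg"].to_numpy()
    unfil = out["ac_unfil_mg"].to_numpy()
    out["activity_class"] = classify_epoch(fil, unfil, params)
    out["mets"] = met_value(out["activity_class"].to_numpy(), fil, params)
    out["mets_adjusted"] = nagayoshi_adjust(out["mets"].to_numpy(), nagayoshi)
    out["intensity"] = intensity_category(out["mets"].to_numpy(), cutoffs)
    return out
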