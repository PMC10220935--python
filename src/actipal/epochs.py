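"""Raw-signal conditioning: high-pass filtering and 10-s epoch synthesis.

The device samples three acceleration axes at 32 Hz with 3 mG resolution.
Each axis is passed through a 0.7 Hz high-pass filter to strip gravity,
the mean absolute value of each axis is taken over 10-s epochs, and the
three per-axis values are synthesized into a single magnitude. The ratio
of the unfiltered to the filtered synthesized acceleration carries the
low-frequency (< 0.7 Hz) content that distinguishes non-locomotive from
locomotive movement.

Conventions the device documentation leaves open, fixed here and exposed
as parameters:

* the filter is a 4th-order Butterworth applied forward-backward
  (zero phase), so class boundaries are not smeared by phase lag;
* "synthesized" means the Euclidean norm of the three per-axis
  mean-absolute values;
* the unfiltered epoch value removes the per-epoch, per-axis mean (the
  static gravity component) before taking absolute values — otherwise
  the ~1000 mG gravity vector would dominate ACunfil and the 1.16 ratio
  threshold could never operate;
* trailing partial epochs are dropped, never padded.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .exceptions import InputError
from .params import MetAlgorithmParams

__all__ = ["RawTriaxialSignal", "highpass_filter", "epochize", "process_signal"]


@dataclass
class RawTriaxialSignal:
    """A 3-axis acceleration stream in mG.

    ``data`` has shape (n_samples, 3); axes are x, y, z.
    """

    data: np.ndarray
    sampling_rate_hz: float = 32.0
    resolution_mg: float = 3.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise InputError(
                f"signal data must have shape (n, 3), got {self.data.shape}"
            )
        if self.sampling_rate_hz <= 0:
            raise InputError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def quantize(self) -> "RawTriaxialSignal":
        """Round to the device's resolution grid (default 3 mG)."""
        q = self.resolution_mg
        return RawTriaxialSignal(
            np.round(self.data / q) * q, self.sampling_rate_hz, self.resolution_mg
        )


def highpass_filter(
    sig: RawTriaxialSignal, cutoff_hz: float = 0.7, order: int = 4
) -> RawTriaxialSignal:
    """Zero-phase Butterworth high-pass on each axis.

    Removes the gravitational (DC and sub-``cutoff_hz``) component. The
    forward-backward pass squares the magnitude response, steepening the
    roll-off below the cutoff.
    """
    nyq = sig.sampling_rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise InputError(
            f"cutoff must lie in (0, {nyq}) Hz for fs={sig.sampling_rate_hz} Hz"
        )
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=sig.sampling_rate_hz, output="sos")
    out = sps.sosfiltfilt(sos, sig.data, axis=0)
    return RawTriaxialSignal(out, sig.sampling_rate_hz, sig.resolution_mg)


def _epoch_magnitude(block: np.ndarray, remove_dc: bool) -> np.ndarray:
    """Euclidean norm across axes of per-axis mean |acceleration|.

    ``block`` has shape (n_epochs, samples_per_epoch, 3).
    """
    if remove_dc:
        block = block - block.mean(axis=1, keepdims=True)
    per_axis = np.abs(block).mean(axis=1)  # (n_epochs, 3)
    return np.linalg.norm(per_axis, axis=1)


def epochize(
    raw: RawTriaxialSignal,
    filtered: RawTriaxialSignal,
    epoch_s: float = 10.0,
) -> pd.DataFrame:
    """Reduce aligned raw and filtered streams to per-epoch synthesized accelerations.

    Returns a DataFrame with columns ``epoch_index``, ``ac_fil_mg``,
    ``ac_unfil_mg``. The unfiltered value is computed after removing the
    per-epoch, per-axis mean (static gravity); the filtered value directly
    from the high-passed stream. Trailing partial epochs are dropped.
    """
    if raw.n_samples != filtered.n_samples:
        raise InputError("raw and filtered signals must have equal length")
    if raw.sampling_rate_hz != filtered.sampling_rate_hz:
        raise InputError("raw and filtered signals must share a sampling rate")
    n_per = epoch_s * raw.sampling_rate_hz
    if abs(n_per - round(n_per)) > 1e-9:
        raise InputError("epoch_s x sampling rate must be a whole number of samples")
    n_per = int(round(n_per))
    n_epochs = raw.n_samples // n_per
    raw_blocks = raw.data[: n_epochs * n_per].reshape(n_epochs, n_per, 3)
    fil_blocks = filtered.data[: n_epochs * n_per].reshape(n_epochs, n_per, 3)
    return pd.DataFrame(
        {
            "epoch_index": np.arange(n_epochs),
            "ac_fil_mg": _epoch_magnitude(fil_blocks, remove_dc=False),
            "ac_unfil_mg": _epoch_magnitude(raw_blocks, remove_dc=True),
        }
    )


def process_signal(
    sig: RawTriaxialSignal, params: MetAlgorithmParams | None = None
) -> pd.DataFrame:
    """Filter and epochize a raw signal with the device's parameter set."""
    params = params or MetAlgorithmParams()
    filtered = highpass_filter(sig, params.cutoff_hz, params.filter_order)
    return epochize(sig, filtered, params.epoch_s)
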