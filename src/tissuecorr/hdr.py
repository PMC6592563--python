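"""High-dynamic-range (HDR) reconstruction of a linear reporter signal.

Imaging records each cell in two channels: channel 1 is sensitive but clips
above a saturation level, channel 2 is linear but coarse.  Where channel 1 is
unsaturated the two are linearly related, I2 = alpha + beta * I1.  Fitting
(alpha, beta) on the unsaturated range lets the saturated stretch of channel 1
be replaced by the rescaled channel 2, restoring one signal that is linear in
the underlying fluorophore population:

    I = I1                      if I1 <= I1_min
      = (I2 - alpha) / beta     if I1 >  I1_min
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import CalibrationError, InvalidConfigError

__all__ = ["HDRCalibration", "fit_linear_range", "reconstruct"]


@dataclass(frozen=True)
class HDRCalibration:
    """Linear map between channels and the channel-1 saturation threshold."""

    alpha: float  # intensity offset (a.u.)
    beta: float  # dimensionless gain, > 0
    i1_min: float  # channel-1 intensities above this are treated as saturated

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise InvalidConfigError("beta must be positive")


def fit_linear_range(
    i1: np.ndarray,
    i2: np.ndarray,
    saturation_onset: float | None = None,
    onset_fraction: float = 0.95,
) -> HDRCalibration:
    """Fit I2 = alpha + beta * I1 on the unsaturated part of channel 1.

    The saturation onset defaults to ``onset_fraction`` of the observed
    channel-1 maximum -- a deliberately conservative cut that discards a thin
    band below the hard clip.  Pass ``saturation_onset`` to override when the
    detector's clip level is known.

    Requires at least 10 points below the onset.
    """
    i1 = np.asarray(i1, dtype=float).ravel()
    i2 = np.asarray(i2, dtype=float).ravel()
    if i1.shape != i2.shape:
        raise InvalidConfigError("channel series must have equal length")
    onset = (
        float(saturation_onset)
        if saturation_onset is not None
        else onset_fraction * float(np.nanmax(i1))
    )
    mask = i1 < onset
    if mask.sum() < 10:
        raise CalibrationError(
            f"only {int(mask.sum())} unsaturated points below onset {onset:.3g}; "
            "need >= 10 for calibration"
        )
    fit = stats.linregress(i1[mask], i2[mask])
    if fit.slope <= 0:
        raise CalibrationError("fitted channel gain is non-positive")
    return HDRCalibration(alpha=float(fit.intercept), beta=float(fit.slope), i1_min=onset)


def reconstruct(i1: np.ndarray, i2: np.ndarray, cal: HDRCalibration) -> np.ndarray:
    """Merge the two channels into one linear signal (piecewise rule above)."""
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if i1.shape != i2.shape:
        raise InvalidConfigError("channel series must have equal shape")
    return np.where(i1 <= cal.i1_min, i1, (i2 - cal.alpha) / cal.beta)
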