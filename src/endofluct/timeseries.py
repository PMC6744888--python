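"""Single-ROI BOLD time-series container and the canonical HRF."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .errors import InputError


@dataclass(frozen=True)
class BoldTimeSeries:
    """A regularly sampled single-ROI BOLD signal.

    ``values[i]`` is the sample acquired at ``origin_time_s + i * tr_seconds``.
    """

    values: np.ndarray
    tr_seconds: float
    origin_time_s: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) < 1:
            raise InputError("BOLD series must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise InputError("BOLD series contains non-finite samples")
        if self.tr_seconds <= 0:
            raise InputError("tr_seconds must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return self.origin_time_s + np.arange(len(self.values)) * self.tr_seconds

    @property
    def duration_s(self) -> float:
        return len(self.values) * self.tr_seconds


# Canonical double-gamma HRF: peak at 6 s, undershoot at 16 s, undershoot
# amplitude 1/6 of the peak, rescaled to unit peak height.  Gamma shapes of
# 7 and 17 (unit scale) put the density modes exactly at 6 and 16 s; each
# component is normalised to unit mode so the 1/6 ratio applies to
# amplitudes, not densities.
_HRF_PEAK_SHAPE = 7.0
_HRF_UNDER_SHAPE = 17.0
_HRF_UNDER_RATIO = 1.0 / 6.0
_P1 = float(gamma_dist.pdf(6.0, _HRF_PEAK_SHAPE))
_P2 = float(gamma_dist.pdf(16.0, _HRF_UNDER_SHAPE))

_grid = np.linspace(0.0, 32.0, 3201)
_raw = gamma_dist.pdf(_grid, _HRF_PEAK_SHAPE) / _P1 - _HRF_UNDER_RATIO * (
    gamma_dist.pdf(_grid, _HRF_UNDER_SHAPE) / _P2
)
_HRF_SCALE = 1.0 / _raw.max()
del _grid, _raw


def hrf(t) -> np.ndarray:
    """Double-gamma hemodynamic response at times ``t`` (s); zero for t < 0."""
    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, _HRF_PEAK_SHAPE) / _P1 - _HRF_UNDER_RATIO * (
        gamma_dist.pdf(t, _HRF_UNDER_SHAPE) / _P2
    )
    return np.where(t >= 0, h * _HRF_SCALE, 0.0)


#: Time (s) after which the response is numerically negligible.
HRF_SUPPORT_S = 48.0
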