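"""Online activity-triggered trial scheduling and real-time nuisance regression.

The trigger watches a denoised single-ROI BOLD stream and classifies each
moment as *low* or *high* endogenous activity: the mean of the most recent 2
volumes is located, via a normal CDF, within the distribution of the 69
volumes immediately preceding them.  Percentiles at or below 0.15 trigger a
low-activity trial, at or above 0.85 a high-activity trial.  A minimum
intertrial interval of 20 s lets the hemodynamic response return toward
baseline; if neither threshold is met within 55 s the trial is presented
anyway (*forced*) and labelled by whether the recent mean sits below or above
the window mean.

The sliding-window percentile is robust to slow scanner drift and to changes
in signal variance over the session, which is why it is preferred over a
fixed threshold on the raw signal.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError
from .timeseries import BoldTimeSeries

__all__ = [
    "TriggerConfig",
    "WindowState",
    "TriggerEvent",
    "percentile_of_recent",
    "step",
    "run_session",
    "IncrementalNuisanceRegressor",
]


@dataclass(frozen=True)
class TriggerConfig:
    """Parameters of the sliding-window trigger."""

    window_volumes: int = 69
    recent_volumes: int = 2
    low_threshold: float = 0.15
    high_threshold: float = 0.85
    min_iti_s: float = 20.0
    timeout_s: float = 55.0
    tr_seconds: float = 1.75

    def __post_init__(self) -> None:
        if not (0.0 < self.low_threshold < self.high_threshold < 1.0):
            raise ConfigError("thresholds must satisfy 0 < low < high < 1")
        if self.recent_volumes < 1:
            raise ConfigError("recent_volumes must be >= 1")
        if self.window_volumes <= self.recent_volumes:
            raise ConfigError("window_volumes must exceed recent_volumes")
        if not (0 < self.min_iti_s < self.timeout_s):
            raise ConfigError("require 0 < min_iti_s < timeout_s")
        if self.tr_seconds <= 0:
            raise ConfigError("tr_seconds must be positive")

    @property
    def warmup_volumes(self) -> int:
        return self.window_volumes + self.recent_volumes


@dataclass
class WindowState:
    """Running buffer of the last window + recent samples."""

    config: TriggerConfig
    buffer: deque = field(init=False)
    volumes_seen: int = 0
    last_trial_volume: int | None = None

    def __post_init__(self) -> None:
        self.buffer = deque(maxlen=self.config.warmup_volumes)

    @property
    def warmed_up(self) -> bool:
        return self.volumes_seen >= self.config.warmup_volumes

    def append(self, value: float) -> None:
        if not math.isfinite(value):
            raise InputError(f"non-finite BOLD sample: {value}")
        self.buffer.append(float(value))
        self.volumes_seen += 1

    def _split(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.array(self.buffer)
        r = self.config.recent_volumes
        return arr[:-r], arr[-r:]


@dataclass(frozen=True)
class TriggerEvent:
    """One scheduled trial: when it fired, its label, and why."""

    volume_index: int
    time_s: float
    label: str  # "low" | "high"
    forced: bool
    percentile: float


def _normal_cdf(z: float) -> float:
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


def percentile_of_recent(state: WindowState) -> float | None:
    """Percentile of the recent mean within the preceding window, or None in warm-up.

    Returns Phi((m - mu_w) / sd_w) with m the mean of the most recent
    ``recent_volumes`` samples and mu_w, sd_w the mean and sample SD (n-1) of
    the ``window_volumes`` samples before them.  A zero-variance window maps
    to 0.5.
    """
    if not state.warmed_up:
        return None
    window, recent = state._split()
    m = recent.mean()
    mu_w = window.mean()
    sd_w = window.std(ddof=1)
    # guard against catastrophic cancellation on (near-)constant windows
    if sd_w <= 1e-12 * max(1.0, abs(mu_w)):
        return 0.5
    return _normal_cdf((m - mu_w) / sd_w)


def step(
    state: WindowState,
    new_value: float,
    config: TriggerConfig,
    elapsed_since_last_trial_s: float,
) -> TriggerEvent | None:
    """Feed one volume into the trigger; return an event if a trial fires.

    Ordering of the rules: the ITI lockout dominates everything; then the
    percentile thresholds (closed: <= low or >= high); then the timeout,
    which forces a trial labelled low when the recent mean is below the
    window mean and high otherwise.
    """
    state.append(new_value)
    if not state.warmed_up:
        return None
    pct = percentile_of_recent(state)
    if elapsed_since_last_trial_s < config.min_iti_s:
        return None
    label = None
    forced = False
    if pct <= config.low_threshold:
        label = "low"
    elif pct >= config.high_threshold:
        label = "high"
    elif elapsed_since_last_trial_s >= config.timeout_s:
        window, recent = state._split()
        label = "low" if recent.mean() < window.mean() else "high"
        forced = True
    if label is None:
        return None
    idx = state.volumes_seen - 1
    state.last_trial_volume = idx
    return TriggerEvent(
        volume_index=idx,
        time_s=idx * config.tr_seconds,
        label=label,
        forced=forced,
        percentile=pct,
    )


def run_session(
    bold: BoldTimeSeries, config: TriggerConfig | None = None
) -> list[TriggerEvent]:
    """Deterministic offline replay of the online trigger over a full series.

    The intertrial clock starts when the warm-up window first fills and is
    reset by every event, so consecutive events are always separated by at
    least ``min_iti_s`` seconds.
    """
    config = config or TriggerConfig(tr_seconds=bold.tr_seconds)
    state = WindowState(config)
    events: list[TriggerEvent] = []
    anchor: float | None = None  # time the ITI clock last reset
    for i, v in enumerate(bold.values):
        t = i * config.tr_seconds
        elapsed = t - anchor if anchor is not None else -math.inf
        ev = step(state, float(v), config, elapsed)
        if anchor is None and state.warmed_up:
            anchor = t
        if ev is not None:
            events.append(ev)
            anchor = t
    return events


class IncrementalNuisanceRegressor:
    """Expanding-window least squares for real-time nuisance removal.

    Regresses the incoming ROI signal on nuisance regressors (plus an
    intercept) using all samples seen so far, returning the current residual
    for each new sample.  After a full pass the coefficients equal the batch
    least-squares solution on the same data; collinear regressors fall back
    to the minimum-norm solution and set ``rank_deficient``.
    """

    def __init__(self, n_regressors: int):
        if n_regressors < 0:
            raise InputError("n_regressors must be non-negative")
        k = n_regressors + 1
        self._k = k
        self._xtx = np.zeros((k, k))
        self._xty = np.zeros(k)
        self.n_samples = 0
        self.coefficients = np.zeros(k)
        self.rank_deficient = False

    def process(self, y_value: float, x_values=()) -> float:
        """Ingest one (y, x) sample, refit, and return the residual of y."""
        x = np.concatenate([[1.0], np.asarray(x_values, dtype=float)])
        if x.size != self._k:
            raise InputError(f"expected {self._k - 1} regressors, got {x.size - 1}")
        self._xtx += np.outer(x, x)
        self._xty += x * y_value
        self.n_samples += 1
        if np.linalg.matrix_rank(self._xtx, hermitian=True) < self._k:
            # underdetermined during the first k samples is expected and not
            # flagged; persistent deficiency afterwards means collinearity
            if self.n_samples >= self._k:
                self.rank_deficient = True
            beta = np.linalg.pinv(self._xtx, hermitian=True) @ self._xty
        else:
            beta = np.linalg.solve(self._xtx, self._xty)
        self.coefficients = beta
        return float(y_value - x @ beta)

    def process_series(self, y, x=None) -> np.ndarray:
        """Vector convenience wrapper: one residual per input sample."""
        y = np.asarray(y, dtype=float)
        if x is None:
            x = np.empty((len(y), 0))
        x = np.asarray(x, dtype=float)
        return np.array([self.process(yi, xi) for yi, xi in zip(y, x)])
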