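"""Gambling-task design: calibration offer sets and indifference-point placement.

The task offers a choice between a risky gamble (equal chance of a prize
``gain`` in {£6, £9, £12} or £0) and a certain (safe) amount.  Calibration
sessions span a wide range of safe amounts derived by dividing the gamble's
expected value by a fixed set of divisors.  For the scanner session, the
fitted utility model is inverted so that safe amounts sit at target gamble
probabilities around each subject's indifference point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

if TYPE_CHECKING:  # pragma: no cover
    from .models import DecisionParams

#: Default prize magnitudes (£) of the risky option.
GAINS = (6.0, 9.0, 12.0)

#: Divisors applied to the gamble's expected value to produce the safe amounts
#: of the calibration task; chosen to span a wide range of risk sensitivity.
DIVISORS = (0.82, 0.87, 0.93, 1.0, 1.1, 1.23, 1.4, 1.6, 1.9, 2.25, 2.75, 3.5)


@dataclass(frozen=True)
class GambleOffer:
    """One offer: a 50/50 gamble between ``gain`` and £0 versus ``safe`` for sure."""

    gain: float
    safe: float
    p_gain: float = 0.5
    loss_outcome: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.safe < self.gain):
            raise InputError(
                f"safe amount must lie in (0, gain); got safe={self.safe}, gain={self.gain}"
            )


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the calibration and scanner-session offer sets."""

    gains: tuple = GAINS
    divisors: tuple = DIVISORS
    day1_repeats: int = 5
    day2_repeats: int = 3
    p_bins_group1: tuple = tuple(np.linspace(0.3, 0.7, 5))
    p_bins_group2: tuple = tuple(np.linspace(0.1, 0.9, 5))
    trials_per_gain_rt: int = 30
    per_condition_rt: int = 15

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.divisors):
            raise ConfigError("divisors must be positive")
        for bins in (self.p_bins_group1, self.p_bins_group2):
            if any(not (0.0 < p < 1.0) for p in bins):
                raise ConfigError("probability bins must lie strictly inside (0, 1)")

    def p_bins(self, group: int) -> tuple:
        if group == 1:
            return self.p_bins_group1
        if group == 2:
            return self.p_bins_group2
        raise ConfigError(f"group must be 1 or 2, got {group}")


def _round_pennies(x: float) -> float:
    """Round half away from zero to the nearest £0.01."""
    return math.floor(x * 100.0 + 0.5) / 100.0


def certain_amount(gain: float, divisor: float) -> float:
    """Safe amount for a calibration trial: EV of the gamble over the divisor.

    The expected value of a 50/50 gamble between ``gain`` and £0 is
    ``0.5 * gain``; dividing by ``divisor`` and rounding to pennies yields the
    certain alternative (e.g. gain £6, divisor 3.5 -> £0.86).
    """
    if divisor <= 0:
        raise InputError(f"divisor must be positive, got {divisor}")
    return _round_pennies(0.5 * gain / divisor)


def build_calibration_trials(
    config: DesignConfig | None = None,
    repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Full factorial calibration set: every (gain, divisor) pair, repeated and shuffled.

    Returns a DataFrame with columns ``trial_index, gain, divisor, safe``;
    the default 3 gains x 12 divisors x 5 repeats gives 180 trials.
    """
    config = config or DesignConfig()
    rows = [
        (g, d, certain_amount(g, d))
        for _ in range(repeats)
        for g in config.gains
        for d in config.divisors
    ]
    df = pd.DataFrame(rows, columns=["gain", "divisor", "safe"])
    rng = np.random.default_rng(seed)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "trial_index", np.arange(len(df)))
    return df


def safe_values_for_pbins(
    params: "DecisionParams",
    gain: float,
    p_targets: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the softmax to place safe amounts at target gamble probabilities.

    For target probability p the certain utility solving the softmax is
    ``U_c = U_g + kappa - ln(p / (1 - p)) / mu`` which is mapped back to money
    through the inverse utility ``V = U_c ** (1 / alpha)``, rounded to pennies
    and clipped to (£0.01, gain - £0.01).

    Returns ``(values, clipped)`` where ``clipped`` marks targets whose exact
    solution fell outside the representable money range.
    """
    if params.mu <= 0 or params.alpha <= 0:
        raise InputError("alpha and mu must be positive for design inversion")
    p = np.asarray(p_targets, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise InputError("target probabilities must lie strictly inside (0, 1)")
    u_gamble = 0.5 * gain**params.alpha
    u_certain = u_gamble + params.kappa - np.log(p / (1.0 - p)) / params.mu
    lo, hi = 0.01, gain - 0.01
    clipped = u_certain <= 0
    values = np.where(clipped, lo, np.maximum(u_certain, 1e-12) ** (1.0 / params.alpha))
    values = np.array([_round_pennies(v) for v in values])
    clipped = clipped | (values < lo) | (values > hi)
    values = np.clip(values, lo, hi)
    return values, clipped


def build_realtime_trials(
    params: "DecisionParams",
    config: DesignConfig | None = None,
    group: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Offer set for the scanner session with balanced condition slots.

    Per gain level: one safe value per probability bin, each repeated
    ``day2 repeats x 2`` times and split equally between ``low`` and ``high``
    condition slots, so the two endogenous-activity conditions face identical
    offer multisets (90 trials, 45 per condition, by default).

    Columns: ``trial_index, gain, safe, p_target, condition_slot, clipped``.
    """
    config = config or DesignConfig()
    p_targets = config.p_bins(group)
    repeats_per_cell = config.trials_per_gain_rt // len(p_targets)  # 30 / 5 = 6
    half = repeats_per_cell // 2
    rows = []
    for gain in config.gains:
        safes, clip = safe_values_for_pbins(params, gain, p_targets)
        for safe, p, c in zip(safes, p_targets, clip):
            for slot in ["low"] * half + ["high"] * (repeats_per_cell - half):
                rows.append((gain, safe, p, slot, bool(c)))
    df = pd.DataFrame(
        rows, columns=["gain", "safe", "p_target", "condition_slot", "clipped"]
    )
    rng = np.random.default_rng(seed)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df.insert(0, "trial_index", np.arange(len(df)))
    return df
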