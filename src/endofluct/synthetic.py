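"""Seeded synthetic data: endogenous BOLD, evoked responses, choices and RTs.

This module stands in for the study's fMRI and behavioral recordings so that
every downstream stage — trigger replay, model fitting, evoked-response and
mediation statistics — can be exercised and validated by simulation alone.

The generative structure mirrors the phenomena under test:

* endogenous ROI activity is AR(1) noise around a raw-signal mean plus slow
  cosine drift (scanner-like, < 0.01 Hz);
* offer presentation adds a canonical double-gamma evoked response whose
  amplitude falls linearly with the prestimulus percentile (negative
  coupling: low-activity trials get the larger phasic response);
* the agent's gambling bias on each trial follows the evoked amplitude, so
  that low-activity trials carry a higher mean bias (kappa_low > kappa_high)
  and the activity -> evoked response -> choice chain is a genuine mediation
  pathway rather than a pair of parallel condition effects;
* reaction times are log-normal with a faster mean in the high-activity
  condition.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from scipy.special import expit

from .design import DesignConfig, build_realtime_trials
from .errors import ConfigError, InputError
from .models import DecisionParams, p_gamble, utility
from .timeseries import BoldTimeSeries, hrf


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative settings for one synthetic scanning session.

    ``noise_sd`` is the AR(1) innovation SD; ``signal_mean`` sets the raw
    signal level so that percent signal change is well defined.  Amplitudes
    are in raw signal units (1 unit on a mean of 100 is 1% signal change).
    ``evoked_coupling_slope`` < 0 sets the coupling direction: smaller
    phasic responses when prestimulus activity is high.
    """

    n_volumes: int = 1800
    tr_seconds: float = 1.75
    ar_coefficient: float = 0.8
    drift_amplitude: float = 1.0
    noise_sd: float = 1.0
    signal_mean: float = 100.0
    evoked_base_amplitude: float = 1.0
    evoked_coupling_slope: float = -1.0
    evoked_amplitude_sd: float = 0.5
    kappa_low: float = 0.2
    kappa_high: float = -0.2
    alpha: float = 0.9
    mu: float = 3.0
    rt_mean_low_s: float = 1.72
    rt_mean_high_s: float = 1.67
    rt_sigma_log: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes <= 0:
            raise ConfigError("n_volumes must be positive")
        if self.tr_seconds <= 0:
            raise ConfigError("tr_seconds must be positive")
        if not (0.0 <= self.ar_coefficient < 1.0):
            raise ConfigError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.rt_mean_low_s <= 0 or self.rt_mean_high_s <= 0:
            raise ConfigError("RT means must be positive")
        if self.mu <= 0 or self.alpha <= 0:
            raise ConfigError("alpha and mu must be positive")


@dataclass(frozen=True)
class SubjectDataset:
    """One simulated subject: BOLD series, trial table, and ground truth."""

    subject_id: int
    bold: BoldTimeSeries
    trials: pd.DataFrame
    true_params_low: DecisionParams
    true_params_high: DecisionParams
    seed: int

    def __post_init__(self) -> None:
        if len(self.trials):
            if not set(self.trials["condition"]) <= {"low", "high"}:
                raise InputError("trial conditions must be 'low' or 'high'")
            if self.trials["onset_s"].max() >= self.bold.duration_s:
                raise InputError("trial onset outside the BOLD series")


# ---------------------------------------------------------------------------
# BOLD generators


def gen_endogenous_bold(config: SyntheticConfig) -> BoldTimeSeries:
    """AR(1) fluctuations plus slow cosine drift around the raw signal mean.

    The drift is a sum of 3 cosines with periods of at least 100 s (below
    0.01 Hz) and seeded random phases, mimicking slow scanner drift without
    modelling its physics.  The AR(1) chain is burned in so the series starts
    in its stationary regime.  Identical config (including seed) gives a
    bit-identical series.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_volumes
    t = np.arange(n) * config.tr_seconds

    drift = np.zeros(n)
    # Draw drift randomness unconditionally so the noise stream does not
    # depend on whether drift is enabled.
    periods = rng.uniform(100.0, 600.0, size=3)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    amps = rng.uniform(0.5, 1.5, size=3) * (config.drift_amplitude / 3.0)
    if config.drift_amplitude > 0:
        for per, ph, a in zip(periods, phases, amps):
            drift += a * np.cos(2.0 * np.pi * t / per + ph)

    burn = 200
    eps = rng.normal(0.0, config.noise_sd, size=n + burn)
    noise = np.empty(n + burn)
    noise[0] = eps[0]
    phi = config.ar_coefficient
    for i in range(1, n + burn):
        noise[i] = phi * noise[i - 1] + eps[i]
    values = config.signal_mean + drift + noise[burn:]
    return BoldTimeSeries(values=values, tr_seconds=config.tr_seconds)


def evoked_amplitude(prestim_percentile, config: SyntheticConfig) -> np.ndarray:
    """Evoked-response peak amplitude as a linear function of prestimulus level."""
    p = np.asarray(prestim_percentile, dtype=float)
    return config.evoked_base_amplitude + config.evoked_coupling_slope * (p - 0.5)


def add_evoked_responses(
    ts: BoldTimeSeries,
    onsets_s: Sequence[float],
    prestim_percentiles: Sequence[float],
    config: SyntheticConfig,
    amplitudes: Sequence[float] | None = None,
) -> BoldTimeSeries:
    """Superimpose one HRF-shaped response per onset, amplitude coupled to baseline.

    Each response is the unit-peak double-gamma HRF scaled by
    ``evoked_base_amplitude + evoked_coupling_slope * (percentile - 0.5)``,
    or by ``amplitudes`` when given (used to inject trial-to-trial response
    variability).  The input series is returned unchanged outside the
    response supports.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    pcts = np.asarray(prestim_percentiles, dtype=float)
    if onsets.shape != pcts.shape:
        raise InputError("onsets and percentiles must have equal length")
    if len(onsets) and (onsets.min() < 0 or onsets.max() >= ts.duration_s):
        raise InputError("onset outside the BOLD series duration")
    values = ts.values.copy()
    times = ts.times
    amps = (
        evoked_amplitude(pcts, config)
        if amplitudes is None
        else np.asarray(amplitudes, dtype=float)
    )
    if amps.shape != onsets.shape:
        raise InputError("amplitudes must have one value per onset")
    for onset, amp in zip(onsets, amps):
        rel = times - (ts.origin_time_s + onset)
        values += amp * hrf(rel)
    return BoldTimeSeries(
        values=values, tr_seconds=ts.tr_seconds, origin_time_s=ts.origin_time_s
    )


# ---------------------------------------------------------------------------
# Choice / RT generator


def gen_agent_choices(
    offers: pd.DataFrame,
    params: DecisionParams,
    rt_mean_s: float,
    seed: int = 0,
    kappa_per_trial: np.ndarray | None = None,
    rt_sigma_log: float = 0.3,
) -> pd.DataFrame:
    """Simulate choices and reaction times for a sequence of offers.

    Each choice is a Bernoulli draw from the softmax gamble probability;
    ``kappa_per_trial`` (optional) overrides the scalar gambling bias with a
    per-trial value, used when the bias is driven by the evoked response.
    RTs are log-normal with the requested arithmetic mean and log-scale SD.
    """
    if params.mu <= 0:
        raise InputError("mu must be positive")
    if rt_mean_s <= 0:
        raise InputError("rt_mean_s must be positive")
    rng = np.random.default_rng(seed)
    out = offers.copy()
    gain = out["gain"].to_numpy(float)
    safe = out["safe"].to_numpy(float)
    if kappa_per_trial is None:
        p = p_gamble(params, gain, safe)
    else:
        kap = np.asarray(kappa_per_trial, dtype=float)
        if kap.shape != gain.shape:
            raise InputError("kappa_per_trial must match the number of offers")
        u_g, u_c = utility(gain, safe, params.alpha)
        p = expit(params.mu * (u_g - u_c + kap))
    out["p_gamble"] = p
    out["choice"] = (rng.random(len(out)) < p).astype(float)
    # log-normal with arithmetic mean rt_mean_s: E = exp(m + s^2/2)
    m = np.log(rt_mean_s) - 0.5 * rt_sigma_log**2
    out["rt_s"] = rng.lognormal(mean=m, sigma=rt_sigma_log, size=len(out))
    return out


# ---------------------------------------------------------------------------
# Whole-subject and cohort simulation


def _spawn_seed(*entropy: int) -> int:
    """Stable derived seed (< 2^31) from a tuple of integers."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


def _jitter(rng: np.random.Generator, value: float, lo: float, hi: float) -> float:
    """Gaussian jitter with SD = 10% of the value, truncated to [lo, hi]."""
    return float(np.clip(rng.normal(value, 0.1 * abs(value)), lo, hi))


def simulate_subject(
    subject_id: int,
    config: SyntheticConfig,
    trigger_config=None,
    design_config: DesignConfig | None = None,
    group: int = 2,
) -> SubjectDataset:
    """Simulate one subject end to end: BOLD, trigger replay, offers, choices.

    Pipeline: generate endogenous BOLD; replay the online trigger to obtain
    low/high events; assign the balanced scanner offer set to events by
    condition until each condition's quota is exhausted; draw choices with a
    per-trial gambling bias that tracks the trial's evoked amplitude
    (calibrated so condition-mean biases equal the subject's kappa_low and
    kappa_high); draw condition-dependent RTs; and superimpose the evoked
    responses on the BOLD series.
    """
    from .trigger import TriggerConfig, run_session  # deferred: avoid cycle

    trigger_config = trigger_config or TriggerConfig(tr_seconds=config.tr_seconds)
    design_config = design_config or DesignConfig()

    seed = _spawn_seed(config.seed, subject_id)
    rng = np.random.default_rng(_spawn_seed(seed, 0))

    # Per-subject true parameters: 10% Gaussian jitter, truncated to validity.
    alpha_s = _jitter(rng, config.alpha, 0.2, 2.0)
    mu_s = _jitter(rng, config.mu, 0.2, 20.0)
    kappa_low_s = _jitter(rng, config.kappa_low, -5.0, 5.0)
    kappa_high_s = _jitter(rng, config.kappa_high, -5.0, 5.0)
    params_low = DecisionParams(alpha_s, mu_s, kappa_low_s)
    params_high = DecisionParams(alpha_s, mu_s, kappa_high_s)
    base_params = DecisionParams(alpha_s, mu_s, 0.0)

    endo = gen_endogenous_bold(
        dataclasses.replace(config, seed=_spawn_seed(seed, 1))
    )
    events = run_session(endo, trigger_config)

    offers = build_realtime_trials(
        base_params, design_config, group=group, seed=_spawn_seed(seed, 2)
    )
    queues = {
        cond: offers[offers["condition_slot"] == cond].to_dict("records")
        for cond in ("low", "high")
    }
    rows = []
    for ev in events:
        if not queues[ev.label]:
            continue
        offer = queues[ev.label].pop(0)
        rows.append(
            {
                "subject_id": subject_id,
                "onset_s": ev.time_s,
                "volume_index": ev.volume_index,
                "condition": ev.label,
                "forced": ev.forced,
                "percentile": ev.percentile,
                "gain": offer["gain"],
                "safe": offer["safe"],
                "p_target": offer["p_target"],
            }
        )
    trials = pd.DataFrame(rows)
    if len(trials) == 0:
        raise InputError(
            "no trials could be scheduled; BOLD series too short for the trigger"
        )
    trials.insert(1, "trial_index", np.arange(len(trials)))

    # Per-trial gambling bias follows the *realized* evoked amplitude —
    # baseline coupling plus independent trial-to-trial response variability
    # — rescaled so the condition means of the bias equal kappa_low /
    # kappa_high.  This routes the condition effect on choice through the
    # phasic response (a genuine mediation pathway: conditional on the
    # prestimulus level, the response still carries choice information)
    # while preserving the per-condition model parameters in expectation.
    amp_rng = np.random.default_rng(_spawn_seed(seed, 5))
    amp = evoked_amplitude(
        trials["percentile"].to_numpy(), config
    ) + amp_rng.normal(0.0, config.evoked_amplitude_sd, size=len(trials))
    is_low = (trials["condition"] == "low").to_numpy()
    if is_low.any() and (~is_low).any():
        amp_low, amp_high = amp[is_low].mean(), amp[~is_low].mean()
    else:
        amp_low, amp_high = 1.0, 0.0  # degenerate: single condition present
    if amp_low == amp_high:
        kappa_trial = np.where(is_low, kappa_low_s, kappa_high_s)
    else:
        w = (kappa_low_s - kappa_high_s) / (amp_low - amp_high)
        kappa_trial = kappa_high_s + w * (amp - amp_high)

    choice_seed = _spawn_seed(seed, 3)
    trials = gen_agent_choices(
        trials,
        base_params,
        rt_mean_s=config.rt_mean_low_s,
        seed=choice_seed,
        kappa_per_trial=kappa_trial,
        rt_sigma_log=config.rt_sigma_log,
    )
    # Redraw RTs with condition-specific means (choices above used a single
    # placeholder mean; RT streams are independent of the choice stream).
    rt_rng = np.random.default_rng(_spawn_seed(seed, 4))
    sig = config.rt_sigma_log
    means = np.where(is_low, config.rt_mean_low_s, config.rt_mean_high_s)
    trials["rt_s"] = rt_rng.lognormal(
        mean=np.log(means) - 0.5 * sig**2, sigma=sig
    )
    trials["true_kappa_trial"] = kappa_trial
    trials["true_evoked_amp"] = amp

    bold = add_evoked_responses(
        endo,
        trials["onset_s"].to_numpy(),
        trials["percentile"].to_numpy(),
        config,
        amplitudes=amp,
    )
    return SubjectDataset(
        subject_id=subject_id,
        bold=bold,
        trials=trials,
        true_params_low=params_low,
        true_params_high=params_high,
        seed=seed,
    )


def gen_cohort(
    n_subjects: int,
    config: SyntheticConfig,
    trigger_config=None,
    design_config: DesignConfig | None = None,
    group: int = 2,
) -> list[SubjectDataset]:
    """Simulate a cohort; per-subject seeds derive from the master seed."""
    if n_subjects < 0:
        raise InputError("n_subjects must be non-negative")
    return [
        simulate_subject(
            sid,
            config,
            trigger_config=trigger_config,
            design_config=design_config,
            group=group,
        )
        for sid in range(n_subjects)
    ]


def cohort_trials(cohort: Sequence[SubjectDataset]) -> pd.DataFrame:
    """Concatenate trial tables across subjects."""
    if not cohort:
        return pd.DataFrame()
    return pd.concat([s.trials for s in cohort], ignore_index=True)
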