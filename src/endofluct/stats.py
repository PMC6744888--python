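"""Evoked-response, behavioral, and mediation statistics.

Covers the offline analyses of the activity-triggered gambling experiment:
percent-signal-change epochs around option onset, condition contrasts on
evoked time courses via a cluster-extent permutation test, per-subject
behavioral summaries (gamble rates, value-difference bins, RTs),
susceptibility correlations, a reaction-time regression, and a two-stage
multilevel mediation of prestimulus activity -> evoked response -> choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ConfigError, InputError
from .timeseries import BoldTimeSeries

# ---------------------------------------------------------------------------
# Epoch extraction and percent signal change


@dataclass(frozen=True)
class EpochMatrix:
    """Trials x timepoints percent-signal-change table for one ROI.

    ``time_axis`` holds seconds relative to stimulus onset; ``conditions``
    labels each trial row; ``valid`` marks trials with a usable (positive)
    baseline.
    """

    values: np.ndarray
    time_axis: np.ndarray
    conditions: np.ndarray | None = None
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", v)
        t = np.asarray(self.time_axis, dtype=float)
        object.__setattr__(self, "time_axis", t)
        if v.shape[1] != len(t):
            raise InputError("time axis length must match the number of timepoints")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise InputError("time axis must be strictly increasing")


def extract_epochs(
    bold: BoldTimeSeries,
    onsets_s: Sequence[float],
    n_timepoints: int = 8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cut raw per-trial epochs starting at each onset volume.

    Returns ``(raw, time_axis, complete)`` where ``raw`` is trials x
    timepoints and ``complete`` flags trials that fit inside the series
    (incomplete trailing epochs are zero-padded and flagged False).
    """
    onsets = np.asarray(onsets_s, dtype=float)
    idx = np.round((onsets - bold.origin_time_s) / bold.tr_seconds).astype(int)
    if len(idx) and (idx.min() < 0 or idx.max() >= len(bold)):
        raise InputError("onset outside the BOLD series")
    raw = np.zeros((len(idx), n_timepoints))
    complete = np.zeros(len(idx), dtype=bool)
    for row, i in enumerate(idx):
        stop = min(i + n_timepoints, len(bold))
        raw[row, : stop - i] = bold.values[i:stop]
        complete[row] = stop - i == n_timepoints
    time_axis = np.arange(n_timepoints) * bold.tr_seconds
    return raw, time_axis, complete


def percent_signal_change(
    raw_epochs: np.ndarray,
    time_axis: np.ndarray,
    baseline_volumes: int = 2,
    conditions: np.ndarray | None = None,
) -> EpochMatrix:
    """Express each trial's epoch relative to its immediate post-onset baseline.

    PSC(t) = 100 * (x(t) - b) / b with b the mean of the first
    ``baseline_volumes`` samples at/after onset, correcting for differences
    in starting baseline between trials.  Trials with b <= 0 are flagged
    invalid (their rows are NaN).
    """
    raw = np.atleast_2d(np.asarray(raw_epochs, dtype=float))
    if baseline_volumes < 1 or baseline_volumes > raw.shape[1]:
        raise InputError("baseline_volumes must lie within the epoch")
    b = raw[:, :baseline_volumes].mean(axis=1)
    valid = b > 0
    psc = np.full_like(raw, np.nan)
    psc[valid] = 100.0 * (raw[valid] - b[valid, None]) / b[valid, None]
    return EpochMatrix(
        values=psc,
        time_axis=time_axis,
        conditions=None if conditions is None else np.asarray(conditions),
        valid=valid,
    )


def epoch_average(
    epochs: EpochMatrix, window_s: tuple[float, float] = (5.25, 10.5)
) -> np.ndarray:
    """Per-trial mean PSC over the closed time window (default 5.25–10.5 s)."""
    lo, hi = window_s
    mask = (epochs.time_axis >= lo - 1e-9) & (epochs.time_axis <= hi + 1e-9)
    if not mask.any():
        raise InputError(f"window {window_s} contains no sample times")
    return epochs.values[:, mask].mean(axis=1)


# ---------------------------------------------------------------------------
# Cluster-extent permutation test


@dataclass(frozen=True)
class ClusterTestConfig:
    height_threshold_t: float = 2.0
    n_permutations: int = 5000
    alpha: float = 0.01
    statistic: str = "extent"  # or "mass"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")
        if self.statistic not in ("extent", "mass"):
            raise ConfigError("statistic must be 'extent' or 'mass'")


@dataclass(frozen=True)
class Cluster:
    start: int
    stop: int  # exclusive
    extent: int
    mass: float
    sign: int  # sign of t within the cluster
    p_value: float


@dataclass(frozen=True)
class ClusterTestResult:
    t_values: np.ndarray
    clusters: tuple[Cluster, ...]
    config: ClusterTestConfig

    def significant(self, alpha: float | None = None) -> tuple[Cluster, ...]:
        a = self.config.alpha if alpha is None else alpha
        return tuple(c for c in self.clusters if c.p_value < a)


def _paired_t(d: np.ndarray) -> np.ndarray:
    """One-sample t of each column of d against zero."""
    n = d.shape[0]
    m = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def _find_clusters(t: np.ndarray, height: float) -> list[tuple[int, int, int]]:
    """Maximal runs of contiguous |t| >= height with a common sign."""
    supra = np.abs(t) >= height
    sign = np.sign(t).astype(int)
    clusters = []
    i = 0
    T = len(t)
    while i < T:
        if supra[i]:
            j = i
            while j + 1 < T and supra[j + 1] and sign[j + 1] == sign[i]:
                j += 1
            clusters.append((i, j + 1, sign[i]))
            i = j + 1
        else:
            i += 1
    return clusters


def _max_run_lengths(supra: np.ndarray) -> np.ndarray:
    """Row-wise maximum run length of True in a 2-D boolean array (vectorised)."""
    B, T = supra.shape
    run = np.zeros(B, dtype=np.int64)
    best = np.zeros(B, dtype=np.int64)
    for j in range(T):
        run = np.where(supra[:, j], run + 1, 0)
        best = np.maximum(best, run)
    return best


def _max_cluster_extent(t: np.ndarray, height: float) -> np.ndarray:
    """Row-wise maximum sign-consistent supra-threshold run length.

    Positive and negative clusters are formed separately, exactly as in the
    observed-cluster construction; the null statistic is the larger of the
    two polarities' longest runs.
    """
    pos = _max_run_lengths(t >= height)
    neg = _max_run_lengths(t <= -height)
    return np.maximum(pos, neg)


def _max_cluster_mass(t: np.ndarray, height: float) -> np.ndarray:
    """Row-wise maximum summed |t| over sign-consistent supra-threshold runs."""
    B, T = t.shape
    run_pos = np.zeros(B)
    run_neg = np.zeros(B)
    best = np.zeros(B)
    for j in range(T):
        col = t[:, j]
        run_pos = np.where(col >= height, run_pos + col, 0.0)
        run_neg = np.where(col <= -height, run_neg - col, 0.0)
        best = np.maximum(best, np.maximum(run_pos, run_neg))
    return best


def cluster_extent_permutation_test(
    epochs_low: np.ndarray,
    epochs_high: np.ndarray,
    config: ClusterTestConfig | None = None,
    seed: int = 0,
) -> ClusterTestResult:
    """Paired condition contrast on mean time courses with a sign-flip null.

    Inputs are subjects x timepoints mean responses per condition.  A paired
    t statistic is computed at each timepoint; clusters are maximal runs of
    contiguous timepoints with |t| at or above the height threshold.  The
    null distribution of the maximum cluster statistic (extent by default,
    mass optionally) is built by randomly flipping the sign of each subject's
    difference time course; cluster p = (1 + #null >= observed) /
    (1 + n_permutations).
    """
    config = config or ClusterTestConfig()
    low = np.atleast_2d(np.asarray(epochs_low, dtype=float))
    high = np.atleast_2d(np.asarray(epochs_high, dtype=float))
    if low.shape != high.shape:
        raise InputError("condition matrices must have identical shape")
    n, T = low.shape
    if n < 3:
        raise InputError("cluster test requires at least 3 subjects")
    d = low - high
    t_obs = _paired_t(d)
    found = _find_clusters(t_obs, config.height_threshold_t)
    if not found:
        return ClusterTestResult(t_values=t_obs, clusters=(), config=config)

    rng = np.random.default_rng(seed)
    B = config.n_permutations
    signs = rng.choice([-1.0, 1.0], size=(B, n))
    m = (signs @ d) / n  # B x T permuted means
    msq = (d**2).mean(axis=0)  # invariant under sign flips
    var = (msq - m**2) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = m / np.sqrt(var / n)
    t_null = np.nan_to_num(t_null)
    if config.statistic == "extent":
        null_max = _max_cluster_extent(t_null, config.height_threshold_t)
    else:
        null_max = _max_cluster_mass(t_null, config.height_threshold_t)

    clusters = []
    for start, stop, sign in found:
        extent = stop - start
        mass = float(np.abs(t_obs[start:stop]).sum())
        obs = extent if config.statistic == "extent" else mass
        p = (1.0 + np.sum(null_max >= obs)) / (1.0 + B)
        clusters.append(
            Cluster(start=start, stop=stop, extent=extent, mass=mass, sign=sign,
                    p_value=float(p))
        )
    return ClusterTestResult(t_values=t_obs, clusters=tuple(clusters), config=config)


# ---------------------------------------------------------------------------
# Multilevel mediation


@dataclass(frozen=True)
class PathStats:
    """Group-level summary of one mediation path across subjects."""

    per_subject: np.ndarray
    mean: float
    se: float
    t: float
    p: float


def _path_stats(values: np.ndarray) -> PathStats:
    values = np.asarray(values, dtype=float)
    n = len(values)
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    if n > 1 and se > 0:
        t, p = sps.ttest_1samp(values, 0.0)
    else:
        t, p = np.nan, np.nan
    return PathStats(per_subject=values, mean=mean, se=se, t=float(t), p=float(p))


@dataclass(frozen=True)
class MediationResult:
    """Two-stage multilevel mediation X -> M -> Y with subject bootstrap."""

    path_a: PathStats
    path_b: PathStats
    path_c: PathStats
    path_c_prime: PathStats
    indirect_ab: float
    indirect_ci: tuple[float, float]
    n_subjects: int
    n_dropped: int
    y_stage: str


def _fit_logistic(y: np.ndarray, X: np.ndarray) -> np.ndarray | None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:
            return None
    beta = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(beta)) or np.any(np.abs(beta) > 1e3):
        return None
    return beta


def _fit_linear(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def multilevel_mediation(
    data: pd.DataFrame,
    x: str = "x",
    m: str = "m",
    y: str = "y",
    subject: str = "subject_id",
    n_boot: int = 5000,
    seed: int = 0,
    y_stage: str = "logistic",
) -> MediationResult:
    """Test whether M mediates the effect of X on Y across subjects.

    Level 1 (per subject): path a from the linear fit m ~ x; paths b and c'
    from the y-stage fit y ~ m + x; path c from y ~ x.  The y-stage is
    logistic by default (Y binary) with a linear variant for which
    c = c' + a*b holds exactly per subject.

    Level 2: one-sample t tests on the per-subject coefficients; the
    indirect effect is the mean of per-subject a*b with a percentile CI from
    resampling subjects with replacement (seeded).

    Subjects with no variance in x or m, or whose y-stage fit fails (e.g.
    perfect separation), are dropped with a warning.
    """
    if y_stage not in ("logistic", "linear"):
        raise ConfigError("y_stage must be 'logistic' or 'linear'")
    fit_y = _fit_logistic if y_stage == "logistic" else _fit_linear
    a_l, b_l, c_l, cp_l = [], [], [], []
    dropped = 0
    for sid, sub in data.groupby(subject):
        xv = sub[x].to_numpy(float)
        mv = sub[m].to_numpy(float)
        yv = sub[y].to_numpy(float)
        if np.std(xv) == 0 or np.std(mv) == 0 or len(xv) < 4:
            warnings.warn(f"subject {sid}: no variance in x or m; dropped")
            dropped += 1
            continue
        a = np.polyfit(xv, mv, 1)[0]
        Xmx = np.column_stack([np.ones_like(xv), mv, xv])
        Xx = np.column_stack([np.ones_like(xv), xv])
        bm = fit_y(yv, Xmx)
        bc = fit_y(yv, Xx)
        if bm is None or bc is None:
            warnings.warn(f"subject {sid}: y-stage fit failed; dropped")
            dropped += 1
            continue
        a_l.append(a)
        b_l.append(bm[1])
        cp_l.append(bm[2])
        c_l.append(bc[1])
    n_sub = len(a_l)
    if n_sub < 3:
        raise InputError(f"mediation requires >= 3 usable subjects, got {n_sub}")
    a_arr, b_arr = np.array(a_l), np.array(b_l)
    ab = a_arr * b_arr
    rng = np.random.default_rng(seed)
    boot_idx = rng.integers(0, n_sub, size=(n_boot, n_sub))
    boot_means = ab[boot_idx].mean(axis=1)
    ci = (float(np.percentile(boot_means, 2.5)), float(np.percentile(boot_means, 97.5)))
    return MediationResult(
        path_a=_path_stats(a_arr),
        path_b=_path_stats(b_arr),
        path_c=_path_stats(np.array(c_l)),
        path_c_prime=_path_stats(np.array(cp_l)),
        indirect_ab=float(ab.mean()),
        indirect_ci=ci,
        n_subjects=n_sub,
        n_dropped=dropped,
        y_stage=y_stage,
    )


# ---------------------------------------------------------------------------
# Behavioral summaries


@dataclass(frozen=True)
class PairedTest:
    mean_diff: float
    t: float
    p: float
    n: int


def _paired_test(a: np.ndarray, b: np.ndarray) -> PairedTest:
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[np.isfinite(d)]
    n = len(d)
    if n < 2 or d.std(ddof=1) == 0:
        return PairedTest(mean_diff=float(d.mean()) if n else np.nan,
                          t=np.nan, p=np.nan, n=n)
    t, p = sps.ttest_1samp(d, 0.0)
    return PairedTest(mean_diff=float(d.mean()), t=float(t), p=float(p), n=n)


@dataclass(frozen=True)
class BehavioralSummary:
    """Per-subject gamble rates, RTs, value-difference bins and group tests."""

    per_subject: pd.DataFrame
    bin_rates: pd.DataFrame
    gamble_rate_test: PairedTest
    rt_test: PairedTest  # high minus low: negative = faster when activity high
    n_bins: int


def value_difference_bins(
    trials: pd.DataFrame, n_bins: int = 5
) -> pd.DataFrame:
    """Assign each trial to a per-subject equal-size bin of EV(gamble) - safe."""
    out = trials.copy()
    vd = 0.5 * out["gain"] - out["safe"]
    out["value_diff"] = vd
    out["vd_bin"] = -1
    for sid, sub in out.groupby("subject_id"):
        order = sub["value_diff"].to_numpy().argsort(kind="stable")
        chunks = np.array_split(np.arange(len(sub)), n_bins)
        bins = np.empty(len(sub), dtype=int)
        for b, chunk in enumerate(chunks):
            bins[order[chunk]] = b
        out.loc[sub.index, "vd_bin"] = bins
    return out


def behavioral_summary(trials: pd.DataFrame, n_bins: int = 5) -> BehavioralSummary:
    """Condition contrasts of gamble rate and RT, plus value-difference bins.

    Gamble rates use valid (non-missed) trials only.  The value-difference
    bins are equal-size quantile bins computed per subject across both
    conditions, so each bin probes the same offers in both activity states.
    """
    valid = trials[trials["choice"].notna()].copy()
    if len(valid) == 0:
        raise InputError("no valid trials")
    rows = []
    for sid, sub in valid.groupby("subject_id"):
        row = {"subject_id": sid}
        for cond in ("low", "high"):
            c = sub[sub["condition"] == cond]
            row[f"gamble_rate_{cond}"] = c["choice"].mean() if len(c) else np.nan
            row[f"rt_mean_{cond}"] = c["rt_s"].mean() if len(c) else np.nan
            row[f"n_{cond}"] = len(c)
        row["gamble_rate_overall"] = sub["choice"].mean()
        rows.append(row)
    per_subject = pd.DataFrame(rows)

    binned = value_difference_bins(valid, n_bins=n_bins)
    bin_rates = (
        binned.groupby(["subject_id", "vd_bin", "condition"])
        .agg(gamble_rate=("choice", "mean"),
             mean_value_diff=("value_diff", "mean"),
             n_trials=("choice", "size"))
        .reset_index()
    )
    return BehavioralSummary(
        per_subject=per_subject,
        bin_rates=bin_rates,
        gamble_rate_test=_paired_test(
            per_subject["gamble_rate_low"], per_subject["gamble_rate_high"]
        ),
        rt_test=_paired_test(
            per_subject["rt_mean_high"], per_subject["rt_mean_low"]
        ),
        n_bins=n_bins,
    )


def susceptibility_correlations(x, y) -> dict[str, float]:
    """Spearman (midrank ties) and Pearson correlations with p-values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("need two equal-length vectors of at least 3 points")
    rho, p_rho = sps.spearmanr(x, y)
    r, p_r = sps.pearsonr(x, y)
    return {
        "spearman_rho": float(rho),
        "spearman_p": float(p_rho),
        "pearson_r": float(r),
        "pearson_p": float(p_r),
    }


# ---------------------------------------------------------------------------
# Reaction-time regression


@dataclass(frozen=True)
class RTRegressionResult:
    coefficients: pd.DataFrame  # one row per subject
    group_tests: dict[str, PairedTest]
    dropped_subjects: tuple


RT_PREDICTORS = ("prestim", "choice", "abs_dsv")


def _subject_rt_ols(sub: pd.DataFrame, dsv: np.ndarray) -> np.ndarray:
    X = np.column_stack(
        [
            np.ones(len(sub)),
            sub["percentile"].to_numpy(float),
            sub["choice"].to_numpy(float),
            np.abs(dsv),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InputError("rank-deficient design (constant predictor column)")
    beta, *_ = np.linalg.lstsq(X, sub["rt_s"].to_numpy(float), rcond=None)
    return beta


def rt_regression(
    trials: pd.DataFrame,
    params_by_subject: dict | None = None,
) -> RTRegressionResult:
    """Per-subject OLS of RT on prestimulus activity, choice, and |dSV|.

    ``params_by_subject`` maps subject id (or (subject, condition)) to fitted
    DecisionParams used to compute the subjective-value difference
    |U_gamble - U_certain| as a choice-difficulty index; omitted, the
    objective expected-value difference is used instead.  Subjects with a
    rank-deficient design (e.g. all-gamble choosers) are dropped; with a
    single subject the rank deficiency is raised as an error.
    """
    from .models import utility

    valid = trials[trials["choice"].notna() & trials["rt_s"].notna()]
    rows, dropped = [], []
    subjects = list(valid.groupby("subject_id"))
    for sid, sub in subjects:
        if params_by_subject is not None:
            dsv = np.empty(len(sub))
            for i, (_, tr) in enumerate(sub.iterrows()):
                key = (
                    (sid, tr["condition"])
                    if (sid, tr.get("condition")) in params_by_subject
                    else sid
                )
                p = params_by_subject[key]
                u_g, u_c = utility(tr["gain"], tr["safe"], p.alpha)
                dsv[i] = u_g - u_c + p.kappa
        else:
            dsv = (0.5 * sub["gain"] - sub["safe"]).to_numpy(float)
        try:
            beta = _subject_rt_ols(sub, dsv)
        except InputError:
            if len(subjects) == 1:
                raise
            dropped.append(sid)
            continue
        rows.append(
            {"subject_id": sid, "intercept": beta[0], "prestim": beta[1],
             "choice": beta[2], "abs_dsv": beta[3]}
        )
    if not rows:
        raise InputError("no usable subjects for RT regression")
    coef = pd.DataFrame(rows)
    tests = {
        name: _paired_test(coef[name].to_numpy(), np.zeros(len(coef)))
        for name in RT_PREDICTORS
    }
    return RTRegressionResult(
        coefficients=coef, group_tests=tests, dropped_subjects=tuple(dropped)
    )
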