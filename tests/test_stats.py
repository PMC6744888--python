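"""Evoked-response, behavioral, correlation and mediation statistics."""

import numpy as np
import pandas as pd
import pytest

from endofluct import (
    BoldTimeSeries,
    ClusterTestConfig,
    behavioral_summary,
    cluster_extent_permutation_test,
    epoch_average,
    extract_epochs,
    multilevel_mediation,
    percent_signal_change,
    rt_regression,
    susceptibility_correlations,
)
from endofluct.errors import InputError
from endofluct.stats import value_difference_bins

TAXIS = np.arange(8) * 1.75


# --- percent signal change and epoch averaging ------------------------------


def test_psc_constant_epoch_is_zero():
    raw = np.full((3, 8), 200.0)
    psc = percent_signal_change(raw, TAXIS)
    assert np.allclose(psc.values, 0.0)


def test_psc_arithmetic_and_scaling_invariance():
    raw = np.full((1, 8), 200.0)
    raw[0, 2:] = 205.0
    psc = percent_signal_change(raw, TAXIS)
    assert np.allclose(psc.values[0, 2:], 2.5)  # 100 * 5 / 200
    scaled = percent_signal_change(3.7 * raw, TAXIS)
    assert np.allclose(psc.values, scaled.values)


def test_psc_uniform_gain_from_baseline():
    raw = np.full((1, 8), 100.0)
    raw[0, 2:] *= 1.01
    psc = percent_signal_change(raw, TAXIS)
    assert np.allclose(psc.values[0, 2:], 1.0)


def test_psc_flags_nonpositive_baseline():
    raw = np.ones((2, 8))
    raw[1, :2] = -1.0
    psc = percent_signal_change(raw, TAXIS)
    assert psc.valid.tolist() == [True, False]
    assert np.isnan(psc.values[1]).all()


def test_epoch_average_window_samples():
    """At TR 1.75 s the 5.25-10.5 s window covers exactly samples 3..6."""
    psc = percent_signal_change(np.arange(8.0)[None, :] + 100.0, TAXIS)
    vals = np.zeros((1, 8))
    vals[0] = TAXIS  # linear ramp PSC(t) = t
    from endofluct.stats import EpochMatrix

    em = EpochMatrix(values=vals, time_axis=TAXIS)
    assert epoch_average(em) == pytest.approx(np.mean([5.25, 7.0, 8.75, 10.5]))
    assert epoch_average(em) == pytest.approx(7.875)
    single = epoch_average(em, window_s=(7.0, 7.0))
    assert single == pytest.approx(7.0)


def test_extract_epochs_alignment_and_completeness():
    values = np.arange(100.0)
    bold = BoldTimeSeries(values, tr_seconds=1.75)
    raw, taxis, complete = extract_epochs(bold, [0.0, 1.75 * 95], n_timepoints=8)
    assert np.array_equal(raw[0], values[:8])
    assert complete.tolist() == [True, False]
    with pytest.raises(InputError):
        extract_epochs(bold, [1.75 * 100], n_timepoints=8)


# --- cluster-extent permutation test ---------------------------------------


def test_cluster_identical_conditions_no_clusters():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(10, 12))
    res = cluster_extent_permutation_test(x, x.copy(), seed=0)
    assert res.clusters == ()
    assert np.allclose(res.t_values, 0.0)


def test_cluster_detects_injected_effect():
    rng = np.random.default_rng(1)
    n, T = 30, 15
    low = rng.normal(size=(n, T))
    high = rng.normal(size=(n, T))
    low[:, 5:10] += 1.0  # strong contiguous effect
    cfg = ClusterTestConfig(n_permutations=1000)
    res = cluster_extent_permutation_test(low, high, cfg, seed=2)
    sig = res.significant(0.01)
    assert any(c.start <= 5 and c.stop >= 10 and c.sign > 0 for c in sig)


def test_cluster_pvalues_bounds_and_seed_reproducibility():
    rng = np.random.default_rng(3)
    low = rng.normal(size=(12, 10))
    high = rng.normal(size=(12, 10))
    low[:, 3:6] += 0.6
    cfg = ClusterTestConfig(n_permutations=200)
    r1 = cluster_extent_permutation_test(low, high, cfg, seed=7)
    r2 = cluster_extent_permutation_test(low, high, cfg, seed=7)
    assert r1.clusters == r2.clusters
    assert np.array_equal(r1.t_values, r2.t_values)
    for c in r1.clusters:
        assert 1.0 / 201 <= c.p_value <= 1.0


def test_cluster_requires_three_subjects():
    with pytest.raises(InputError):
        cluster_extent_permutation_test(np.zeros((2, 5)), np.ones((2, 5)))


def test_cluster_mass_statistic_variant():
    rng = np.random.default_rng(4)
    low = rng.normal(size=(20, 12))
    high = rng.normal(size=(20, 12))
    low[:, 4:8] += 1.5
    cfg = ClusterTestConfig(n_permutations=500, statistic="mass")
    res = cluster_extent_permutation_test(low, high, cfg, seed=1)
    assert any(c.p_value < 0.05 and c.sign > 0 for c in res.clusters)


# --- mediation ---------------------------------------------------------------


def _mediation_data(n_sub=12, n_trials=80, seed=0, full_mediation=True, a=1.5):
    """x -> m -> y generative chain; optionally y from x only."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sub):
        x = rng.normal(size=n_trials)
        m = a * x + rng.normal(0, 1.0, n_trials)
        if full_mediation:
            eta = 1.2 * m
        else:
            eta = 1.2 * x
        y = (rng.random(n_trials) < 1 / (1 + np.exp(-eta))).astype(float)
        rows.append(pd.DataFrame({"subject_id": s, "x": x, "m": m, "y": y}))
    return pd.concat(rows, ignore_index=True)


def test_mediation_full_chain():
    """x->m->y with no direct path: c' centers on 0, a, b and a*b nonzero."""
    res = multilevel_mediation(_mediation_data(seed=1), n_boot=1000, seed=0)
    assert res.path_a.p < 1e-6 and res.path_a.mean > 0
    assert res.path_b.p < 1e-3 and res.path_b.mean > 0
    assert res.indirect_ci[0] > 0  # CI excludes zero
    assert abs(res.path_c_prime.mean) < abs(res.path_c.mean)
    assert res.path_c_prime.p > 0.01  # no residual direct effect


def test_mediation_no_mediator_role():
    """y generated from x only: a*b centers on 0 and c is close to c'.

    Uses a weak x->m coupling so the level-1 logistic does not split the x
    effect across collinear predictors at finite n.
    """
    res = multilevel_mediation(
        _mediation_data(
            n_sub=15, n_trials=150, seed=2, full_mediation=False, a=0.5
        ),
        n_boot=1000,
        seed=0,
    )
    assert res.indirect_ci[0] < 0 < res.indirect_ci[1]
    # without a real m->y path, controlling for m changes c little
    assert res.path_c.mean == pytest.approx(res.path_c_prime.mean, rel=0.3)


def test_mediation_linear_stage_exact_decomposition():
    """With a linear y-stage, c = c' + a*b holds exactly per subject."""
    rng = np.random.default_rng(5)
    rows = []
    for s in range(5):
        x = rng.normal(size=50)
        m = 0.8 * x + rng.normal(0, 1, 50)
        y = 0.5 * m + 0.3 * x + rng.normal(0, 1, 50)
        rows.append(pd.DataFrame({"subject_id": s, "x": x, "m": m, "y": y}))
    res = multilevel_mediation(
        pd.concat(rows, ignore_index=True), n_boot=200, seed=0, y_stage="linear"
    )
    per_subject_c = res.path_c.per_subject
    recomposed = (
        res.path_c_prime.per_subject
        + res.path_a.per_subject * res.path_b.per_subject
    )
    assert np.allclose(per_subject_c, recomposed, atol=1e-10)


def test_mediation_drops_degenerate_subjects_and_needs_three():
    data = _mediation_data(n_sub=4, seed=3)
    data.loc[data["subject_id"] == 0, "x"] = 1.0  # no variance in x
    with pytest.warns(UserWarning):
        res = multilevel_mediation(data, n_boot=100, seed=0)
    assert res.n_subjects == 3 and res.n_dropped == 1
    with pytest.raises(InputError):
        multilevel_mediation(_mediation_data(n_sub=2, seed=4), n_boot=100, seed=0)


# --- behavioral summaries ----------------------------------------------------


def _trials_frame(choices_low, choices_high, rt_low=1.7, rt_high=1.6, sid=0):
    n = len(choices_low)
    rng = np.random.default_rng(sid)
    df_low = pd.DataFrame(
        {
            "subject_id": sid,
            "condition": "low",
            "gain": rng.choice([6.0, 9.0, 12.0], n),
            "safe": rng.uniform(1, 5, n),
            "choice": choices_low,
            "rt_s": rt_low,
        }
    )
    df_high = df_low.copy()
    df_high["condition"] = "high"
    df_high["choice"] = choices_high
    df_high["rt_s"] = rt_high
    return pd.concat([df_low, df_high], ignore_index=True)


def test_behavioral_all_gamble_subject():
    df = _trials_frame(np.ones(20), np.ones(20))
    summ = behavioral_summary(df)
    row = summ.per_subject.iloc[0]
    assert row["gamble_rate_low"] == 1.0 and row["gamble_rate_high"] == 1.0


def test_behavioral_binning_equal_sizes():
    """45 trials in 5 bins gives 9 trials per bin, ordered by value difference."""
    rng = np.random.default_rng(9)
    df = pd.DataFrame(
        {
            "subject_id": 0,
            "condition": rng.choice(["low", "high"], 45),
            "gain": rng.choice([6.0, 9.0, 12.0], 45),
            "safe": rng.uniform(1, 5, 45),
            "choice": rng.integers(0, 2, 45).astype(float),
            "rt_s": 1.7,
        }
    )
    binned = value_difference_bins(df, n_bins=5)
    sizes = binned.groupby("vd_bin").size()
    assert (sizes == 9).all()
    means = binned.groupby("vd_bin")["value_diff"].mean()
    assert means.is_monotonic_increasing


def test_behavioral_group_direction():
    dfs = []
    rng = np.random.default_rng(10)
    for s in range(8):
        low = (rng.random(40) < 0.62).astype(float)
        high = (rng.random(40) < 0.5).astype(float)
        dfs.append(_trials_frame(low, high, rt_low=1.72, rt_high=1.67, sid=s))
    summ = behavioral_summary(pd.concat(dfs, ignore_index=True))
    assert summ.gamble_rate_test.mean_diff > 0
    assert summ.rt_test.mean_diff < 0  # high minus low


# --- correlations and RT regression -----------------------------------------


def test_spearman_hand_rank_oracle():
    """rho = 1 - 6*sum(d^2)/(n(n^2-1)) on a 6-point table with d^2 = 6."""
    x = [1, 2, 3, 4, 5, 6]
    y = [2, 1, 4, 3, 6, 5]
    res = susceptibility_correlations(x, y)
    assert res["spearman_rho"] == pytest.approx(1 - 36 / 210)


def test_spearman_monotone_and_reversed():
    x = np.array([1.0, 2.0, 5.0, 9.0, 11.0])
    assert susceptibility_correlations(x, np.exp(x))["spearman_rho"] == pytest.approx(1.0)
    assert susceptibility_correlations(x, -x)["spearman_rho"] == pytest.approx(-1.0)
    assert susceptibility_correlations(x, -x)["pearson_r"] == pytest.approx(-1.0)


def test_rt_regression_exact_recovery():
    """Noise-free RT = 2 - 0.1 * activity recovers the coefficient exactly."""
    rng = np.random.default_rng(2)
    n = 60
    df = pd.DataFrame(
        {
            "subject_id": 0,
            "condition": "low",
            "percentile": rng.uniform(0, 1, n),
            "gain": rng.choice([6.0, 9.0, 12.0], n),
            "safe": rng.uniform(1, 5, n),
            "choice": rng.integers(0, 2, n).astype(float),
        }
    )
    df["rt_s"] = 2.0 - 0.1 * df["percentile"]
    res = rt_regression(df)
    assert res.coefficients["prestim"].iloc[0] == pytest.approx(-0.1, abs=1e-8)
    assert res.coefficients["choice"].iloc[0] == pytest.approx(0.0, abs=1e-8)


def test_rt_regression_constant_predictor_raises():
    rng = np.random.default_rng(3)
    n = 30
    df = pd.DataFrame(
        {
            "subject_id": 0,
            "condition": "low",
            "percentile": rng.uniform(0, 1, n),
            "gain": 6.0,
            "safe": 3.0,
            "choice": 1.0,  # constant column -> rank deficient
            "rt_s": rng.uniform(1, 2, n),
        }
    )
    with pytest.raises(InputError):
        rt_regression(df)
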