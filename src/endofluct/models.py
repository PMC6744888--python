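"""Prospect-theory choice models, maximum-likelihood fitting and comparison.

The core model values a 50/50 gamble between ``gain`` and £0 against a safe
amount through a power utility,

    U_gamble = 0.5 * gain**alpha,      U_certain = safe**alpha,

and chooses the gamble with softmax probability

    P(gamble) = 1 / (1 + exp(-mu * (U_gamble - U_certain + kappa))),

where ``alpha`` is risk aversion (alpha < 1 risk-averse), ``mu`` the inverse
temperature, and ``kappa`` an additive gambling bias that shifts the decision
function toward or away from the risky option independently of value.  The
base model fixes kappa = 0.

Trials are pandas DataFrames with at least columns ``gain``, ``safe`` and
``choice`` (1 = gamble, 0 = safe, NaN = missed; missed trials are excluded
from the likelihood) and, for per-condition fits, a ``condition`` column with
values ``low`` / ``high``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import qmc

from .errors import FittingError, InputError

#: Fitting bounds per parameter (also the validity range of DecisionParams).
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.01, 3.0),
    "mu": (1e-3, 50.0),
    "kappa": (-5.0, 5.0),
    "kappa_mult": (-2.0, 2.0),
    "alpha_lo": (0.01, 3.0),
    "alpha_hi": (0.01, 3.0),
}


@dataclass(frozen=True)
class DecisionParams:
    """Parameters (alpha, mu, kappa) of the softmax gambling model."""

    alpha: float
    mu: float
    kappa: float = 0.0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise InputError(f"alpha must be positive, got {self.alpha}")
        if not self.mu > 0:
            raise InputError(f"mu must be positive, got {self.mu}")


def utility(gain, safe, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Power utilities of the gamble and the certain option."""
    gain = np.asarray(gain, dtype=float)
    safe = np.asarray(safe, dtype=float)
    return 0.5 * gain**alpha, safe**alpha


def p_gamble(params: DecisionParams, gain, safe) -> np.ndarray:
    """Softmax probability of choosing the gamble; stable for extreme arguments."""
    u_g, u_c = utility(gain, safe, params.alpha)
    eta = params.mu * (u_g - u_c + params.kappa)
    return expit(eta)


# ---------------------------------------------------------------------------
# Model registry


@dataclass(frozen=True)
class ModelSpec:
    """A named choice model: free parameters, fixed values, linear predictor.

    ``eta`` maps a parameter dict and offer arrays to the softmax argument;
    ``eta_grad`` (optional) returns its Jacobian with respect to the free
    parameters, an (n_trials, n_free) array, enabling analytic-gradient
    fitting.
    """

    name: str
    free: tuple[str, ...]
    fixed: Mapping[str, float]
    eta: Callable[[Mapping[str, float], np.ndarray, np.ndarray], np.ndarray]
    eta_grad: Callable | None = None
    canonical: bool = True

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [PARAM_BOUNDS[p] for p in self.free]

    def params_dict(self, theta: Sequence[float]) -> dict[str, float]:
        d = dict(zip(self.free, theta))
        d.update(self.fixed)
        return d


def _eta_pt(p: Mapping[str, float], gain, safe):
    u_g, u_c = utility(gain, safe, p["alpha"])
    return p["mu"] * (u_g - u_c + p["kappa"])


def _eta_grad_pt(p, gain, safe, free):
    u_g, u_c = utility(gain, safe, p["alpha"])
    du_dalpha = 0.5 * gain**p["alpha"] * np.log(gain) - safe**p["alpha"] * np.log(safe)
    delta = u_g - u_c + p["kappa"]
    cols = {
        "alpha": p["mu"] * du_dalpha,
        "mu": delta,
        "kappa": np.full_like(delta, p["mu"]),
    }
    return np.column_stack([cols[f] for f in free])


def _eta_kappa_mult(p, gain, safe):
    # Non-canonical placeholder: gambling bias as a multiplicative gain on the
    # softmax slope, mu_eff = mu * exp(kappa_mult).
    u_g, u_c = utility(gain, safe, p["alpha"])
    return p["mu"] * np.exp(p["kappa_mult"]) * (u_g - u_c)


def _eta_dual_alpha(p, gain, safe, reference: float = 9.0):
    # Non-canonical placeholder: separate utility curvature for amounts below
    # vs at-or-above a reference magnitude (£9).
    gain = np.asarray(gain, dtype=float)
    safe = np.asarray(safe, dtype=float)

    def u(v):
        a = np.where(v < reference, p["alpha_lo"], p["alpha_hi"])
        return v**a

    return p["mu"] * (0.5 * u(gain) - u(safe))


MODELS: dict[str, ModelSpec] = {
    "pt": ModelSpec(
        name="pt",
        free=("alpha", "mu"),
        fixed={"kappa": 0.0},
        eta=_eta_pt,
        eta_grad=lambda p, g, s: _eta_grad_pt(p, g, s, ("alpha", "mu")),
    ),
    "pt_kappa": ModelSpec(
        name="pt_kappa",
        free=("alpha", "mu", "kappa"),
        fixed={},
        eta=_eta_pt,
        eta_grad=lambda p, g, s: _eta_grad_pt(p, g, s, ("alpha", "mu", "kappa")),
    ),
    "pt_kappa_mult": ModelSpec(
        name="pt_kappa_mult",
        free=("alpha", "mu", "kappa_mult"),
        fixed={},
        eta=_eta_kappa_mult,
        canonical=False,
    ),
    "pt_dual_alpha": ModelSpec(
        name="pt_dual_alpha",
        free=("alpha_lo", "alpha_hi", "mu"),
        fixed={},
        eta=_eta_dual_alpha,
        canonical=False,
    ),
}


def get_model(spec: str | ModelSpec) -> ModelSpec:
    if isinstance(spec, ModelSpec):
        return spec
    try:
        return MODELS[spec]
    except KeyError:
        raise InputError(f"unknown model {spec!r}; available: {sorted(MODELS)}")


# ---------------------------------------------------------------------------
# Likelihood and fitting


@dataclass(frozen=True)
class FitResult:
    """Outcome of a maximum-likelihood fit of one model to one trial set."""

    model: str
    params: dict[str, float]
    log_likelihood: float
    n_trials: int
    pseudo_r2: float
    bic: float
    n_starts_converged: int

    @property
    def decision_params(self) -> DecisionParams:
        """The canonical (alpha, mu, kappa) view, where the model has one."""
        return DecisionParams(
            alpha=self.params["alpha"],
            mu=self.params["mu"],
            kappa=self.params.get("kappa", 0.0),
        )


def _valid_trials(trials: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    keep = trials["choice"].notna()
    t = trials.loc[keep]
    return (
        t["gain"].to_numpy(float),
        t["safe"].to_numpy(float),
        t["choice"].to_numpy(float),
    )


def neg_log_likelihood(
    params: Mapping[str, float] | DecisionParams,
    trials: pd.DataFrame,
    spec: str | ModelSpec = "pt_kappa",
) -> float:
    """Bernoulli negative log-likelihood of the observed choices (nats).

    Missed trials (NaN choice) are excluded.  Computed through the softplus
    identity -log sigma(x) = log(1 + e^(-x)), which is overflow-safe.
    """
    spec = get_model(spec)
    if isinstance(params, DecisionParams):
        params = {"alpha": params.alpha, "mu": params.mu, "kappa": params.kappa}
    gain, safe, y = _valid_trials(trials)
    eta = spec.eta(params, gain, safe)
    return float(np.sum(np.logaddexp(0.0, (1.0 - 2.0 * y) * eta)))


def _nll_and_grad(theta, spec, gain, safe, y):
    p = spec.params_dict(theta)
    eta = spec.eta(p, gain, safe)
    nll = np.sum(np.logaddexp(0.0, (1.0 - 2.0 * y) * eta))
    grad = None
    if spec.eta_grad is not None:
        resid = expit(eta) - y
        grad = spec.eta_grad(p, gain, safe) * resid[:, None]
        grad = grad.sum(axis=0)
    return nll, grad


def pseudo_r2(fit: FitResult) -> float:
    """McFadden-style fit index against a coin-flip null: 1 - LL / (n ln 0.5)."""
    return pseudo_r2_from_ll(fit.log_likelihood, fit.n_trials)


def pseudo_r2_from_ll(log_likelihood: float, n_trials: int) -> float:
    if n_trials == 0:
        raise InputError("pseudo-R2 undefined for zero trials")
    return 1.0 - log_likelihood / (n_trials * np.log(0.5))


def bic(fit: FitResult) -> float:
    """Bayesian information criterion k ln n - 2 LL (lower is better)."""
    k = len(get_model(fit.model).free)
    return bic_from_ll(fit.log_likelihood, n_trials=fit.n_trials, n_params=k)


def bic_from_ll(log_likelihood: float, n_trials: int, n_params: int) -> float:
    return n_params * np.log(n_trials) - 2.0 * log_likelihood


def fit_mle(
    trials: pd.DataFrame,
    spec: str | ModelSpec = "pt_kappa",
    n_starts: int = 20,
    seed: int = 0,
) -> FitResult:
    """Bounded multi-start maximum-likelihood fit.

    Starting points are a Latin-hypercube sample of the parameter box plus its
    midpoint; each start runs L-BFGS-B (analytic gradient where the model
    provides one) and the best converged solution is returned.  Deterministic
    for a given seed.
    """
    spec = get_model(spec)
    gain, safe, y = _valid_trials(trials)
    if len(y) == 0:
        raise FittingError("no valid trials to fit")
    bounds = np.array(spec.bounds)
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    starts = qmc.scale(sampler.random(max(n_starts - 1, 0)), bounds[:, 0], bounds[:, 1])
    starts = np.vstack([bounds.mean(axis=1), starts])

    use_grad = spec.eta_grad is not None

    def objective(theta):
        nll, grad = _nll_and_grad(theta, spec, gain, safe, y)
        return (nll, grad) if use_grad else nll

    best = None
    n_ok = 0
    for theta0 in starts:
        res = optimize.minimize(
            objective,
            theta0,
            jac=use_grad,
            method="L-BFGS-B",
            bounds=spec.bounds,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if not np.isfinite(res.fun):
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise FittingError(
            f"all {len(starts)} starts failed for model {spec.name} "
            f"on {len(y)} trials"
        )
    ll = -float(best.fun)
    return FitResult(
        model=spec.name,
        params=spec.params_dict(best.x),
        log_likelihood=ll,
        n_trials=len(y),
        pseudo_r2=pseudo_r2_from_ll(ll, len(y)),
        bic=bic_from_ll(ll, len(y), len(spec.free)),
        n_starts_converged=n_ok,
    )


def fit_by_condition(
    trials: pd.DataFrame,
    spec: str | ModelSpec = "pt_kappa",
    n_starts: int = 20,
    seed: int = 0,
) -> dict[str, FitResult]:
    """Independent fits on the low- and high-condition trial subsets.

    All free parameters are estimated separately in each condition; paired
    differences of the fitted values feed the group-level tests.
    """
    out = {}
    for cond in ("low", "high"):
        sub = trials[trials["condition"] == cond]
        if len(sub) == 0:
            raise FittingError(f"no trials in condition {cond!r}")
        out[cond] = fit_mle(sub, spec=spec, n_starts=n_starts, seed=seed)
    return out


def fit_cohort_by_condition(
    trials: pd.DataFrame,
    spec: str | ModelSpec = "pt_kappa",
    n_starts: int = 10,
    seed: int = 0,
    min_pseudo_r2: float | None = None,
) -> pd.DataFrame:
    """Per-subject, per-condition fits for a cohort trial table.

    Returns one row per subject with columns ``<param>_low`` / ``<param>_high``
    plus log-likelihoods and pseudo-R2.  ``min_pseudo_r2``, when given,
    excludes subjects whose pooled fit quality falls below the threshold
    (a simple identifiability screen; excluded rows are dropped).
    """
    spec = get_model(spec)
    rows = []
    for sid, sub in trials.groupby("subject_id"):
        fits = fit_by_condition(sub, spec=spec, n_starts=n_starts, seed=seed)
        row: dict[str, float] = {"subject_id": sid}
        for cond, fit in fits.items():
            for k, v in fit.params.items():
                row[f"{k}_{cond}"] = v
            row[f"ll_{cond}"] = fit.log_likelihood
            row[f"pseudo_r2_{cond}"] = fit.pseudo_r2
        rows.append(row)
    df = pd.DataFrame(rows)
    if min_pseudo_r2 is not None and len(df):
        pooled = (df["pseudo_r2_low"] + df["pseudo_r2_high"]) / 2.0
        df = df[pooled >= min_pseudo_r2].reset_index(drop=True)
    return df
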