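"""Flexible parametric excess-hazard models on the log cumulative scale.

The model expresses the log cumulative excess hazard as a restricted
cubic spline in log time plus covariate effects:

    ln H(t | x) = s(ln t | gamma, k0) + x beta                    (proportional)
    ln H(t | x) = s(ln t | gamma, k0) + x beta
                  + sum_j s(ln t | delta_j, k_j) x_j              (time-dependent)

With one baseline degree of freedom the spline collapses to ``ln t`` and
the model is exactly Weibull.  Here the covariate is age at diagnosis:
its main effect is a restricted cubic spline in (winsorised, rescaled)
age, and the optional time-dependent effect interacts a spline in log
time with the linear age term, letting the age effect vary over
follow-up.

Estimation maximises the excess-hazard likelihood with delayed entry

    l = sum_i [ d_i ln(h*_i + lambda_i(t_i)) - H_i(t_i) + H_i(t0_i) ]

where ``h*_i`` is the expected (population) hazard at the event time,
``H_i = exp(eta_i)`` the cumulative excess hazard, and
``lambda_i(t) = eta_i'(ln t) H_i(t) / t`` the excess hazard.  Additive
constants from expected survival do not involve the parameters and are
dropped.  The score is analytic; the observed information is obtained by
central differences of the score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .lifetable import LifeTable, expected_hazard_at
from .splines import KnotVector, SplineBasisSpec, place_knots, rcs_eval

logger = logging.getLogger(__name__)

AGE_SCALE = 10.0  # age entered per decade, for optimizer conditioning

__all__ = ["ModelConfig", "FittedFPM", "DesignBundle", "build_design", "log_likelihood", "fit_fpm", "information_criteria"]


@dataclass(frozen=True)
class ModelConfig:
    """Degrees of freedom for baseline, age main effect and age tvc.

    ``df_age = 0`` omits the age effect entirely; ``df_tvc = 0`` gives a
    proportional-hazards model.  ``tvc_linear_only`` restricts the
    time-dependent interaction to the linear column of the time spline
    (used where sparse data cause convergence trouble).
    """

    df_baseline: int
    df_age: int = 0
    df_tvc: int = 0
    tvc_linear_only: bool = False
    tvc_full_age_basis: bool = False  # interact time spline with full age basis

    def __post_init__(self) -> None:
        if not 1 <= self.df_baseline <= 10:
            raise ValueError("df_baseline must be in 1..10")
        if not 0 <= self.df_age <= 6:
            raise ValueError("df_age must be in 0..6")
        if not 0 <= self.df_tvc <= 6:
            raise ValueError("df_tvc must be in 0..6")

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.df_baseline, self.df_age, self.df_tvc)


@dataclass
class DesignBundle:
    """Design matrices for the likelihood, evaluated at exit and entry times."""

    config: ModelConfig
    knots_time: KnotVector
    knots_age: KnotVector | None
    knots_tvc: KnotVector | None
    age_center: float
    X_exit: np.ndarray       # (n, p) basis at ln t_i
    dX_exit: np.ndarray      # (n, p) d/d ln t of X_exit
    X_entry: np.ndarray      # (n, p), zero rows where t0 = 0
    has_entry: np.ndarray    # (n,) bool
    t: np.ndarray
    d: np.ndarray
    column_names: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return self.X_exit.shape[1]

    @property
    def n_obs(self) -> int:
        return self.X_exit.shape[0]


def _age_z(age, center: float) -> np.ndarray:
    return (np.asarray(age, dtype=float) - center) / AGE_SCALE


def design_row(config: ModelConfig, knots_time, knots_age, knots_tvc, age_center,
               log_t, age_model):
    """Basis and d/d(ln t) rows at arbitrary (ln t, age); used for prediction too."""
    log_t = np.atleast_1d(np.asarray(log_t, dtype=float))
    n = log_t.shape[0]
    age = np.broadcast_to(np.atleast_1d(np.asarray(age_model, dtype=float)), (n,))
    cols = [np.ones((n, 1))]
    dcols = [np.zeros((n, 1))]
    names = ["intercept"]

    tb, dtb = rcs_eval(log_t, SplineBasisSpec(knots_time))
    cols.append(tb)
    dcols.append(dtb)
    names += [f"time{j}" for j in range(1, config.df_baseline + 1)]

    z = _age_z(age, age_center)
    if config.df_age >= 1:
        if config.df_age == 1:
            ab = z[:, None]
        else:
            ab, _ = rcs_eval(z, SplineBasisSpec(knots_age))
        cols.append(ab)
        dcols.append(np.zeros_like(ab))
        names += [f"age{j}" for j in range(1, config.df_age + 1)]

    if config.df_tvc >= 1:
        if config.tvc_linear_only:
            tvb, dtvb = log_t[:, None], np.ones((n, 1))
        else:
            tvb, dtvb = rcs_eval(log_t, SplineBasisSpec(knots_tvc))
        if config.tvc_full_age_basis and config.df_age > 1:
            ab_full, _ = rcs_eval(z, SplineBasisSpec(knots_age))
            tv = np.concatenate([tvb * ab_full[:, [m]] for m in range(ab_full.shape[1])], axis=1)
            dtv = np.concatenate([dtvb * ab_full[:, [m]] for m in range(ab_full.shape[1])], axis=1)
        else:
            tv = tvb * z[:, None]
            dtv = dtvb * z[:, None]
        cols.append(tv)
        dcols.append(dtv)
        names += [f"tvc{j}" for j in range(1, tv.shape[1] + 1)]

    return np.concatenate(cols, axis=1), np.concatenate(dcols, axis=1), names


def place_model_knots(rows: pd.DataFrame, config: ModelConfig):
    """Knot placement from the analysis rows, following the quantile rules.

    Time knots (baseline and tvc) sit at equally spaced quantiles of the
    log of the observed event times, with boundary knots at the min and
    max; age knots at equally spaced quantiles of the (winsorised,
    rescaled) age distribution.
    """
    event_times = rows.loc[rows["d"] == 1, "t"].to_numpy(dtype=float)
    if event_times.size < 2:
        raise ValueError("need at least two event times to place time knots")
    knots_time = place_knots(event_times, config.df_baseline, transform="log")
    age_center = float(rows["age_model"].mean())
    knots_age = None
    if config.df_age > 1 or (config.df_tvc >= 1 and config.tvc_full_age_basis and config.df_age > 1):
        z = _age_z(rows["age_model"].to_numpy(dtype=float), age_center)
        knots_age = place_knots(z, config.df_age, transform="identity", axis_label="age")
    knots_tvc = None
    if config.df_tvc >= 1:
        knots_tvc = place_knots(event_times, config.df_tvc, transform="log")
    return knots_time, knots_age, knots_tvc, age_center


def build_design(rows: pd.DataFrame, config: ModelConfig, knots_time=None, knots_age=None,
                 knots_tvc=None, age_center=None) -> DesignBundle:
    """Assemble likelihood design matrices for the analysis rows.

    Rows need columns ``t0, t, d, age_model``.  Knots are placed from the
    rows unless supplied.
    """
    if knots_time is None:
        knots_time, knots_age, knots_tvc, age_center = place_model_knots(rows, config)
    t = rows["t"].to_numpy(dtype=float)
    t0 = rows["t0"].to_numpy(dtype=float)
    d = rows["d"].to_numpy(dtype=float)
    age = rows["age_model"].to_numpy(dtype=float)
    if np.any(t <= 0):
        raise ValueError("exit times must be positive")

    X_exit, dX_exit, names = design_row(config, knots_time, knots_age, knots_tvc, age_center, np.log(t), age)
    has_entry = t0 > 0
    X_entry = np.zeros_like(X_exit)
    if has_entry.any():
        Xe, _, _ = design_row(config, knots_time, knots_age, knots_tvc, age_center,
                              np.log(t0[has_entry]), age[has_entry])
        X_entry[has_entry] = Xe
    return DesignBundle(config, knots_time, knots_age, knots_tvc, float(age_center),
                        X_exit, dX_exit, X_entry, has_entry, t, d, names)


_ETA_MAX = 200.0  # exp overflow guard; steps beyond this are rejected


def log_likelihood(theta: np.ndarray, bundle: DesignBundle, hstar_exit: np.ndarray):
    """Delayed-entry excess-hazard log likelihood and analytic score.

    Returns ``(ll, grad)``; non-permissible parameter values (overflow,
    or non-positive total hazard at an event) give ``ll = -inf`` so the
    optimiser rejects the step.
    """
    theta = np.asarray(theta, dtype=float)
    eta = bundle.X_exit @ theta
    if np.any(eta > _ETA_MAX):
        return -np.inf, np.zeros_like(theta)
    H = np.exp(eta)
    deta = bundle.dX_exit @ theta
    lam = deta * H / bundle.t
    total = hstar_exit + lam
    events = bundle.d > 0
    if np.any(total[events] <= 0):
        return -np.inf, np.zeros_like(theta)

    eta0 = bundle.X_entry @ theta
    if np.any(eta0[bundle.has_entry] > _ETA_MAX):
        return -np.inf, np.zeros_like(theta)
    H0 = np.where(bundle.has_entry, np.exp(np.minimum(eta0, _ETA_MAX)), 0.0)

    ll = float(np.sum(np.log(total[events])) - np.sum(H) + np.sum(H0[bundle.has_entry]))

    # score: d lambda/d theta = H (dX + deta * X) / t
    w_event = np.where(events, 1.0 / np.where(events, total, 1.0), 0.0) * H / bundle.t
    grad = (
        (w_event * bundle.d) @ bundle.dX_exit
        + ((w_event * bundle.d * deta) - H) @ bundle.X_exit
        + (H0 * bundle.has_entry) @ bundle.X_entry
    )
    if not np.isfinite(ll):
        return -np.inf, np.zeros_like(theta)
    return ll, grad


@dataclass
class FittedFPM:
    """A fitted flexible parametric excess-hazard model."""

    config: ModelConfig
    knots_time: KnotVector
    knots_age: KnotVector | None
    knots_tvc: KnotVector | None
    age_center: float
    age_low: float
    age_high: float
    theta: np.ndarray
    cov: np.ndarray | None
    loglik: float
    n_params: int
    n_obs: int
    aic: float
    bic: float
    converged: bool
    column_names: list[str] = field(default_factory=list)
    message: str = ""

    @property
    def gamma(self) -> np.ndarray:
        """Baseline spline coefficients (including intercept)."""
        return self.theta[: 1 + self.config.df_baseline]

    @property
    def beta(self) -> np.ndarray:
        a = 1 + self.config.df_baseline
        return self.theta[a : a + self.config.df_age]

    @property
    def delta(self) -> np.ndarray:
        return self.theta[1 + self.config.df_baseline + self.config.df_age :]

    def linear_predictor(self, times, age_model):
        """eta(ln t) and its ln-t derivative, and the design rows used."""
        log_t = np.log(np.asarray(times, dtype=float))
        age = np.clip(age_model, self.age_low, self.age_high)
        X, dX, _ = design_row(self.config, self.knots_time, self.knots_age, self.knots_tvc,
                              self.age_center, log_t, age)
        return X @ self.theta, dX @ self.theta, X


def _score_hessian(theta, bundle, hstar, step: float = 1e-5):
    """Observed information by central differences of the analytic score."""
    p = theta.size
    H = np.empty((p, p))
    scale = step * np.maximum(1.0, np.abs(theta))
    for j in range(p):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += scale[j]
        tm[j] -= scale[j]
        _, gp = log_likelihood(tp, bundle, hstar)
        _, gm = log_likelihood(tm, bundle, hstar)
        H[j] = (gp - gm) / (2.0 * scale[j])
    return -0.5 * (H + H.T)


def _initial_theta(bundle: DesignBundle, hstar: np.ndarray) -> np.ndarray:
    """Deterministic starting values: crude excess-rate exponential."""
    person_time = np.sum(bundle.t - np.where(bundle.has_entry, np.exp(bundle.X_entry[:, 1]), 0.0))
    # column 1 of X_entry is ln t0 for entry rows; recover t0 via exp
    n_events = float(np.sum(bundle.d))
    exp_deaths = float(np.sum(hstar * bundle.t))
    excess = max(n_events - exp_deaths, 0.1 * max(n_events, 1.0))
    rate = max(excess / max(person_time, 1e-8), 1e-8)
    theta0 = np.zeros(bundle.n_params)
    theta0[0] = np.log(rate)
    theta0[1] = 1.0  # linear ln t coefficient: exponential baseline
    return theta0


def _standardise_bundle(bundle: DesignBundle):
    """Centre and scale the non-intercept columns for optimizer conditioning.

    Returns ``(std_bundle, means, scales)``; the fitted coefficients in
    the standardised basis map back as ``theta_j = phi_j / s_j`` (j >= 1)
    and ``theta_0 = phi_0 - sum_j phi_j m_j / s_j``.
    """
    m = bundle.X_exit.mean(axis=0)
    s = bundle.X_exit.std(axis=0)
    m[0] = 0.0
    s = np.where(s > 1e-12, s, 1.0)
    s[0] = 1.0
    X = (bundle.X_exit - m) / s
    dX = bundle.dX_exit / s
    Xe = np.where(bundle.has_entry[:, None], (bundle.X_entry - m) / s, 0.0)
    std = DesignBundle(
        bundle.config, bundle.knots_time, bundle.knots_age, bundle.knots_tvc,
        bundle.age_center, X, dX, Xe, bundle.has_entry, bundle.t, bundle.d,
        bundle.column_names,
    )
    return std, m, s


def _phi_to_theta(phi: np.ndarray, m: np.ndarray, s: np.ndarray) -> np.ndarray:
    theta = phi / s
    theta[0] = phi[0] - np.sum(phi[1:] * m[1:] / s[1:])
    return theta


def _theta_to_phi(theta: np.ndarray, m: np.ndarray, s: np.ndarray) -> np.ndarray:
    phi = theta * s
    phi[0] = theta[0] + np.sum(theta[1:] * m[1:])
    return phi


def _maximise(bundle, hstar, theta0):
    """BFGS followed by a damped Newton polish with the FD observed information."""

    def nll(th):
        ll, g = log_likelihood(th, bundle, hstar)
        if not np.isfinite(ll):
            return np.inf, np.zeros_like(th)
        return -ll, -g

    res = optimize.minimize(nll, theta0, jac=True, method="BFGS",
                            options={"gtol": 1e-8, "maxiter": 1000})
    theta = res.x
    ll, grad = log_likelihood(theta, bundle, hstar)
    for _ in range(50):
        if np.max(np.abs(grad)) / (1.0 + abs(ll)) < 1e-9:
            break
        info = _score_hessian(theta, bundle, hstar)
        ridge = 0.0
        for _try in range(8):
            try:
                step = np.linalg.solve(info + ridge * np.eye(info.shape[0]), grad)
                break
            except np.linalg.LinAlgError:
                ridge = max(ridge * 10.0, 1e-6)
        else:
            break
        improved = False
        for frac in (1.0, 0.5, 0.25, 0.1, 0.01):
            cand = theta + frac * step
            ll_new, g_new = log_likelihood(cand, bundle, hstar)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                theta, ll, grad = cand, ll_new, g_new
                improved = True
                break
        if not improved:
            break
    return theta, ll


def fit_fpm(rows: pd.DataFrame, lifetable: LifeTable, config: ModelConfig,
            age_low: float | None = None, age_high: float | None = None) -> FittedFPM:
    """Fit the model by maximum likelihood with deterministic initial values.

    ``rows`` must carry ``t0, t, d, age_model, age_dx, dx_date, sex``.
    The expected hazard at each exit time uses the *true* age at
    diagnosis.  Rows are sorted canonically before the likelihood is
    assembled so refits are invariant to input row order.

    A warm start is used: the (1, df_age, 0) sub-model (near-Weibull) is
    fitted first, and its coefficients are carried over (extra columns
    start at zero).
    """
    if int(rows["d"].sum()) < 30:
        raise ValueError("need at least 30 events to fit")
    rows = rows.sort_values(["t", "t0", "d", "age_model"], kind="mergesort").reset_index(drop=True)
    if age_low is None:
        age_low = float(rows["age_model"].min())
    if age_high is None:
        age_high = float(rows["age_model"].max())

    hstar = expected_hazard_at(
        lifetable, rows["sex"].to_numpy(), rows["age_dx"].to_numpy(dtype=float),
        rows["dx_date"].to_numpy(dtype=float), rows["t"].to_numpy(dtype=float),
    )

    knots_time, knots_age, knots_tvc, age_center = place_model_knots(rows, config)
    bundle = build_design(rows, config, knots_time, knots_age, knots_tvc, age_center)
    sb, means, scales = _standardise_bundle(bundle)

    # warm start from the near-Weibull sub-model (shared columns carry over)
    sub_cfg = ModelConfig(1, config.df_age, 0, tvc_linear_only=config.tvc_linear_only)
    sub_knots_time = KnotVector(knots_time.boundary_low, knots_time.boundary_high, (), "log-time")
    sub_bundle = build_design(rows, sub_cfg, sub_knots_time, knots_age, None, age_center)
    sub_sb, sub_m, sub_s = _standardise_bundle(sub_bundle)
    phi_sub0 = _theta_to_phi(_initial_theta(sub_bundle, hstar), sub_m, sub_s)
    phi_sub, _ = _maximise(sub_sb, hstar, phi_sub0)
    theta_sub = _phi_to_theta(phi_sub, sub_m, sub_s)

    theta0 = np.zeros(bundle.n_params)
    theta0[0] = theta_sub[0]
    theta0[1] = theta_sub[1]
    if config.df_age >= 1:
        a = 1 + config.df_baseline
        theta0[a : a + config.df_age] = theta_sub[2 : 2 + config.df_age]

    phi, ll = _maximise(sb, hstar, _theta_to_phi(theta0, means, scales))
    ll, grad = log_likelihood(phi, sb, hstar)

    info = _score_hessian(phi, sb, hstar)
    cov = None
    pos_def = False
    try:
        np.linalg.cholesky(info)
        cov_phi = np.linalg.inv(info)
        L = np.diag(1.0 / scales)
        L[0, 1:] = -means[1:] / scales[1:]
        L[0, 0] = 1.0
        cov = L @ cov_phi @ L.T
        pos_def = True
    except np.linalg.LinAlgError:
        logger.warning("observed information not positive definite for config %s", config.as_tuple())

    scaled_gnorm = float(np.max(np.abs(grad))) / (1.0 + abs(ll))
    converged = bool(np.isfinite(ll) and scaled_gnorm < 1e-5 and pos_def)
    n_obs = bundle.n_obs
    n_params = bundle.n_params
    aic = -2.0 * ll + 2.0 * n_params
    bic = -2.0 * ll + n_params * np.log(n_obs)
    if not converged:
        logger.warning("non-convergence for config %s: |g|/(1+|ll|)=%.2e, pd=%s",
                       config.as_tuple(), scaled_gnorm, pos_def)
    return FittedFPM(
        config=config, knots_time=knots_time, knots_age=knots_age, knots_tvc=knots_tvc,
        age_center=age_center, age_low=age_low, age_high=age_high,
        theta=_phi_to_theta(phi, means, scales), cov=cov, loglik=float(ll), n_params=n_params, n_obs=n_obs,
        aic=float(aic), bic=float(bic), converged=converged,
        column_names=bundle.column_names,
    )


def information_criteria(fit: FittedFPM) -> tuple[float, float]:
    """(AIC, BIC) = (-2 ll + 2 p, -2 ll + p ln n)."""
    return fit.aic, fit.bic
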