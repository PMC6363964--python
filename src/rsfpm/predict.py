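"""Model-based predictions: relative-survival and excess-hazard curves.

Relative survival at covariate pattern x is ``R(t) = exp(-exp(eta))``
with ``eta = ln H(t|x)`` the fitted log cumulative excess hazard; the
excess hazard is ``lambda(t) = eta'(ln t) exp(eta) / t``.  Confidence
intervals are delta-method intervals on the eta scale, back-transformed,
so they respect the (0, 1] range.

Marginal (age-group and age-standardised) estimates average the
individual predicted curves of cohort members: the group curve is the
mean of its members' curves, and the standardised curve is the weighted
average of group curves with weights equal to the cohort's own
age-group shares (internal standardisation) or user-supplied external
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fpm import FittedFPM, design_row

Z95 = 1.959964

AGE_GROUPS_DEFAULT = ((18, 45), (45, 55), (55, 65), (65, 75), (75, np.inf))
AGE_GROUPS_PROSTATE = ((18, 55), (55, 65), (65, 75), (75, 85), (85, np.inf))
AGE_SPECIFIC_AGES = (55.0, 65.0, 75.0, 85.0)

__all__ = [
    "PredictionResult", "relative_survival_curve", "excess_hazard_curve",
    "marginal_estimates", "AGE_GROUPS_DEFAULT", "AGE_GROUPS_PROSTATE", "AGE_SPECIFIC_AGES",
]


@dataclass
class PredictionResult:
    times: np.ndarray
    estimate: np.ndarray
    se_eta: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times, "estimate": self.estimate,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "kind": self.kind, "meta": str(self.meta),
        })


def _design_at(fit: FittedFPM, age: float, times: np.ndarray):
    age_m = float(np.clip(age, fit.age_low, fit.age_high))
    X, dX, _ = design_row(fit.config, fit.knots_time, fit.knots_age, fit.knots_tvc,
                          fit.age_center, np.log(times), age_m)
    return X, dX


def relative_survival_curve(fit: FittedFPM, age: float, times) -> PredictionResult:
    """Predicted relative survival R(t) at a single age, with 95% CI.

    The age is clamped to the fit's winsorisation cut points before the
    basis is evaluated.  ``t = 0`` returns R = 1 with a degenerate CI.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    pos = times > 0
    est = np.ones_like(times)
    se = np.zeros_like(times)
    lo = np.ones_like(times)
    hi = np.ones_like(times)
    if pos.any():
        X, _ = _design_at(fit, age, times[pos])
        eta = X @ fit.theta
        if fit.cov is not None:
            se_eta = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov, X))
        else:
            se_eta = np.full(eta.shape, np.nan)
        est[pos] = np.exp(-np.exp(eta))
        se[pos] = se_eta
        lo[pos] = np.exp(-np.exp(eta + Z95 * se_eta))
        hi[pos] = np.exp(-np.exp(eta - Z95 * se_eta))
    return PredictionResult(times, est, se, lo, hi, "age_specific", {"age": float(age)})


def excess_hazard_curve(fit: FittedFPM, age: float, times) -> PredictionResult:
    """Predicted excess hazard lambda(t) (per person-year) at a single age."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times <= 0):
        raise ValueError("excess hazard requires times > 0")
    X, dX = _design_at(fit, age, times)
    eta = X @ fit.theta
    deta = dX @ fit.theta
    lam = deta * np.exp(eta) / times
    # delta-method se on the log-hazard scale where the hazard is positive
    se = np.full_like(lam, np.nan)
    lo = np.full_like(lam, np.nan)
    hi = np.full_like(lam, np.nan)
    if fit.cov is not None:
        ok = lam > 0
        if ok.any():
            # d ln lambda / d theta = X + dX / deta
            G = X[ok] + dX[ok] / deta[ok, None]
            se_log = np.sqrt(np.einsum("ij,jk,ik->i", G, fit.cov, G))
            se[ok] = se_log
            lo[ok] = lam[ok] * np.exp(-Z95 * se_log)
            hi[ok] = lam[ok] * np.exp(Z95 * se_log)
    return PredictionResult(times, lam, se, lo, hi, "excess_hazard", {"age": float(age)})


def _member_curves(fit: FittedFPM, ages_model: np.ndarray, times: np.ndarray):
    """Per-member R_i(t) and gradient dR_i/dtheta, vectorised over members."""
    ages = np.clip(ages_model, fit.age_low, fit.age_high)
    n, m = ages.shape[0], times.shape[0]
    R = np.empty((n, m))
    G = np.zeros((m, fit.theta.size))  # accumulated sum_i dR_i/dtheta
    for j, t in enumerate(times):
        X, _, _ = design_row(fit.config, fit.knots_time, fit.knots_age, fit.knots_tvc,
                             fit.age_center, np.full(n, np.log(t)), ages)
        eta = X @ fit.theta
        H = np.exp(eta)
        R[:, j] = np.exp(-H)
        G[j] = (-R[:, j] * H) @ X
    return R, G


def _avg_result(times, rbar, var, kind, meta) -> PredictionResult:
    """CI for an averaged survival via the log(-log) transform."""
    se_r = np.sqrt(np.maximum(var, 0.0))
    inner = np.clip(rbar, 1e-12, 1.0 - 1e-12)
    se_eta = se_r / (inner * np.abs(np.log(inner)))
    eta_bar = np.log(-np.log(inner))
    lo = np.exp(-np.exp(eta_bar + Z95 * se_eta))
    hi = np.exp(-np.exp(eta_bar - Z95 * se_eta))
    return PredictionResult(times, rbar, se_eta, lo, hi, kind, meta)


def marginal_estimates(fit: FittedFPM, cohort: pd.DataFrame, times, scheme: str,
                       weights=None, age_groups=None, ages=AGE_SPECIFIC_AGES,
                       average: str = "groups") -> list[PredictionResult]:
    """Age-specific, age-group or age-standardised relative survival.

    scheme 'age_specific'   : curves at the four conventional ages.
    scheme 'age_groups'     : per-group mean of members' predicted curves,
                              groups assigned on the true age at diagnosis.
    scheme 'standardised'   : weighted average of the group curves with
                              internal (cohort-share) or external weights;
                              ``average='individuals'`` instead averages
                              over all members directly (identical when
                              weights are internal).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times <= 0):
        raise ValueError("marginal estimates require times > 0")
    if age_groups is None:
        age_groups = AGE_GROUPS_DEFAULT

    if scheme == "age_specific":
        return [relative_survival_curve(fit, a, times) for a in ages]

    ages_true = cohort["age_dx"].to_numpy(dtype=float)
    ages_model = cohort["age_model"].to_numpy(dtype=float)
    group_idx = np.full(ages_true.shape, -1)
    for g, (lo_a, hi_a) in enumerate(age_groups):
        group_idx[(ages_true >= lo_a) & (ages_true < hi_a)] = g
    group_idx[ages_true < age_groups[0][0]] = 0  # under-range ages join the first group

    results = []
    group_R: list[np.ndarray | None] = []
    group_G: list[np.ndarray | None] = []
    shares = []
    n_total = len(cohort)
    for g, (lo_a, hi_a) in enumerate(age_groups):
        mask = group_idx == g
        shares.append(mask.sum() / n_total)
        if not mask.any():
            group_R.append(None)
            group_G.append(None)
            continue
        R, Gsum = _member_curves(fit, ages_model[mask], times)
        group_R.append(R.mean(axis=0))
        group_G.append(Gsum / mask.sum())

    if scheme == "age_groups":
        for g, (lo_a, hi_a) in enumerate(age_groups):
            if group_R[g] is None:
                continue
            var = (np.einsum("ij,jk,ik->i", group_G[g], fit.cov, group_G[g])
                   if fit.cov is not None else np.zeros(times.shape))
            results.append(_avg_result(times, group_R[g], var, "age_group",
                                       {"group": (lo_a, hi_a), "share": shares[g]}))
        return results

    if scheme == "standardised":
        if weights is None:
            w = np.asarray(shares, dtype=float)
        else:
            w = np.asarray(weights, dtype=float)
            if abs(w.sum() - 1.0) > 1e-8:
                raise ValueError(f"external weights must sum to 1 (got {w.sum()!r})")
            if len(w) != len(age_groups):
                raise ValueError("one weight per age group required")
        if average == "individuals" and weights is None:
            R, Gsum = _member_curves(fit, ages_model, times)
            rbar = R.mean(axis=0)
            Gbar = Gsum / n_total
        else:
            rbar = np.zeros(times.shape)
            Gbar = np.zeros((times.shape[0], fit.theta.size))
            for g in range(len(age_groups)):
                if group_R[g] is None:
                    if w[g] > 0:
                        raise ValueError(f"non-zero weight for empty age group {age_groups[g]}")
                    continue
                rbar += w[g] * group_R[g]
                Gbar += w[g] * group_G[g]
        var = (np.einsum("ij,jk,ik->i", Gbar, fit.cov, Gbar)
               if fit.cov is not None else np.zeros(times.shape))
        return [_avg_result(times, rbar, var, "standardised",
                            {"weights": list(np.round(w, 6)), "groups": list(age_groups)})]

    raise ValueError(f"unknown scheme {scheme!r}")
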