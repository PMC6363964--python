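"""Non-parametric survival estimators with delayed entry.

Three estimators share the risk-set convention ``Y(u) = #{i : t0_i < u <= t_i}``
(left-truncated, right-continuous exits):

* Kaplan-Meier product-limit estimate of all-cause survival (used mainly
  as the zero-expected-hazard oracle for the other two).
* Ederer II relative survival on the hazard scale:
  ``Lambda_E2(t) = sum_{s<=t} dN(s)/Y(s) - int_0^t [sum_i Y_i(u) h*_i(u)] / Y(u) du``
  with the expected-hazard integral evaluated exactly: the integrand is
  piecewise constant between consecutive entry/exit times and each
  patient's annual life-table band changes, and every such sub-segment
  is integrated in closed form.
* Pohar Perme net survival: the same construction with every patient
  weighted by the inverse of their own expected survival,
  ``w_i(u) = 1/S*_i(u)``.  Weighted sums are refreshed at every distinct
  entry and exit time (weights are held at their segment-start values
  across a segment, while each patient's expected-hazard increment over
  the segment is exact); event-time terms use exact weights at the event
  time.  Weights are capped (default 1e6) with a logged count, since
  ``1/S*`` can explode for the very old with long follow-up.

All estimators return a right-continuous step function over the distinct
event times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable

logger = logging.getLogger(__name__)

__all__ = ["StepEstimate", "kaplan_meier", "ederer2", "pohar_perme"]


@dataclass
class StepEstimate:
    """A step survival estimate over the distinct event times."""

    times: np.ndarray
    value: np.ndarray
    at_risk: np.ndarray
    variance: np.ndarray | None = None

    def value_at(self, t) -> np.ndarray:
        """Step-function lookup: value at the last event time <= t (1 before)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.times.size == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        return np.where(idx >= 0, self.value[np.clip(idx, 0, None)], 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "estimate": self.value, "at_risk": self.at_risk})


def _extract(rows: pd.DataFrame):
    t0 = rows["t0"].to_numpy(dtype=float) if "t0" in rows else np.zeros(len(rows))
    t = rows["t"].to_numpy(dtype=float)
    d = rows["d"].to_numpy(dtype=float)
    if np.any(t <= t0):
        raise ValueError("exit times must exceed entry times")
    return t0, t, d


def _risk_at(t0_sorted, t_sorted, s):
    """Y(s) = #{t0 < s <= t} for each s."""
    return (np.searchsorted(t0_sorted, s, side="left")
            - np.searchsorted(t_sorted, s, side="left"))


def kaplan_meier(rows: pd.DataFrame) -> StepEstimate:
    """Product-limit estimate of all-cause survival with delayed entry."""
    t0, t, d = _extract(rows)
    death_times = np.unique(t[d > 0])
    if death_times.size == 0:
        logger.warning("no events: Kaplan-Meier estimate is flat at 1")
        return StepEstimate(np.array([]), np.array([]), np.array([], dtype=int))
    dN = _death_counts(t, d, death_times)
    Y = _risk_at(np.sort(t0), np.sort(t), death_times).astype(float)
    surv = np.cumprod(1.0 - dN / Y)
    return StepEstimate(death_times, surv, Y.astype(int))


def _death_counts(t, d, death_times) -> np.ndarray:
    idx = np.searchsorted(death_times, t[d > 0])
    return np.bincount(idx, minlength=death_times.size).astype(float)


def _expected_paths(rows: pd.DataFrame, lifetable: LifeTable):
    t_max = float(rows["t"].max()) + 1e-9
    return lifetable.hazard_path(
        rows["sex"].to_numpy(), rows["age_dx"].to_numpy(dtype=float),
        rows["dx_date"].to_numpy(dtype=float), t_max,
    )


def ederer2(rows: pd.DataFrame, lifetable: LifeTable) -> StepEstimate:
    """Ederer II relative survival (hazard-scale dialect), exact integrals."""
    t0, t, d = _extract(rows)
    death_times = np.unique(t[d > 0])
    if death_times.size == 0:
        logger.warning("no events: Ederer II estimate is flat at 1")
        return StepEstimate(np.array([]), np.array([]), np.array([], dtype=int))
    starts, lens, rates = _expected_paths(rows, lifetable)

    # global segment grid: entries, exits and each patient's band changes
    ends = starts + lens
    bp_mask = (starts > t0[:, None]) & (starts < t[:, None]) & (lens > 0)
    P = np.unique(np.concatenate([[0.0], t0, t, starts[bp_mask]]))
    nseg = P.size - 1

    # piecewise-constant Y(u) and A(u) = sum of at-risk patients' current rates
    dY = np.zeros(nseg + 1)
    np.add.at(dY, np.searchsorted(P, t0), 1.0)
    np.add.at(dY, np.searchsorted(P, t), -1.0)
    Y_seg = np.cumsum(dY)[:nseg]

    lo = np.maximum(starts, t0[:, None])
    hi = np.minimum(ends, t[:, None])
    seg_ok = (hi > lo) & (rates > 0)
    dA = np.zeros(nseg + 1)
    np.add.at(dA, np.searchsorted(P, lo[seg_ok]), rates[seg_ok])
    np.add.at(dA, np.searchsorted(P, hi[seg_ok]), -rates[seg_ok])
    A_seg = np.cumsum(dA)[:nseg]
    A_seg = np.where(np.abs(A_seg) < 1e-15, 0.0, A_seg)  # kill rounding residue

    seg_len = np.diff(P)
    with np.errstate(invalid="ignore", divide="ignore"):
        integrand = np.where(Y_seg > 0.5, A_seg * seg_len / np.maximum(Y_seg, 1.0), 0.0)
    cum_int = np.concatenate([[0.0], np.cumsum(integrand)])

    dN = _death_counts(t, d, death_times)
    Y = _risk_at(np.sort(t0), np.sort(t), death_times).astype(float)
    idx = np.searchsorted(P, death_times)
    lam = np.cumsum(dN / Y) - cum_int[idx]
    return StepEstimate(death_times, np.exp(-lam), Y.astype(int))


def pohar_perme(rows: pd.DataFrame, lifetable: LifeTable, weight_cap: float = 1e6) -> StepEstimate:
    """Pohar Perme net survival with inverse-expected-survival weights."""
    t0, t, d = _extract(rows)
    n = t.size
    death_times = np.unique(t[d > 0])
    if death_times.size == 0:
        logger.warning("no events: Pohar Perme estimate is flat at 1")
        return StepEstimate(np.array([]), np.array([]), np.array([], dtype=int))
    starts, lens, rates = _expected_paths(rows, lifetable)
    ends = starts + lens

    Q = np.unique(np.concatenate([[0.0], t0[t0 > 0], t]))
    m = Q.size
    is_death_point = np.isin(Q, death_times)

    # per-patient cumulative expected hazard, advanced incrementally over Q
    K = starts.shape[1]
    H = np.zeros(n)
    # current band pointer per patient
    ptr = np.zeros(n, dtype=np.intp)

    # exact H*_i at each patient's own exit (for the dN weights)
    dtearly = np.clip(t[:, None] - starts, 0.0, lens)
    H_at_exit = np.einsum("ik,ik->i", rates, dtearly)
    w_at_exit = np.minimum(np.exp(H_at_exit), weight_cap)

    event_terms = np.zeros(m)
    int_terms = np.zeros(m)

    row_idx = np.arange(n)
    dead_mask_by_time = {}
    order = np.argsort(t, kind="mergesort")
    t_sorted = t[order]
    for s in death_times:
        a, b = np.searchsorted(t_sorted, s, side="left"), np.searchsorted(t_sorted, s, side="right")
        sel = order[a:b]
        dead_mask_by_time[s] = sel[d[sel] > 0]

    log_cap = np.log(weight_cap)
    ever_capped = np.zeros(n, dtype=bool)
    prev_q = 0.0
    for j in range(1, m):
        q = Q[j]
        capped = H > log_cap
        ever_capped |= capped
        w_prev = np.exp(np.minimum(H, log_cap))
        # advance every patient's H from prev_q to q through any band changes
        dH = np.zeros(n)
        u = np.full(n, prev_q)
        while True:
            nxt = ends[row_idx, ptr]
            step_end = np.minimum(nxt, q)
            dH += rates[row_idx, ptr] * np.maximum(step_end - np.maximum(u, starts[row_idx, ptr]), 0.0)
            cross = (nxt < q) & (ptr < K - 1)
            if not cross.any():
                break
            ptr[cross] += 1
            u = np.maximum(u, step_end)
        H = H + dH

        at_risk = (t0 <= prev_q) & (t >= q)
        den_prev = np.sum(w_prev[at_risk])
        if den_prev > 0:
            int_terms[j] = np.sum(w_prev[at_risk] * dH[at_risk]) / den_prev

        if is_death_point[j]:
            w_now = np.exp(np.minimum(H, log_cap))
            den_now = np.sum(w_now[at_risk])
            dying = dead_mask_by_time[q]
            if den_now > 0:
                event_terms[j] = np.sum(w_at_exit[dying]) / den_now
        prev_q = q

    if ever_capped.any():
        logger.warning("Pohar Perme: weight cap %.1e engaged for %d patients",
                       weight_cap, int(ever_capped.sum()))

    lam_cum = np.cumsum(event_terms) - np.cumsum(int_terms)
    idx = np.searchsorted(Q, death_times)
    Y = _risk_at(np.sort(t0), np.sort(t), death_times).astype(int)
    return StepEstimate(death_times, np.exp(-lam_cum[idx]), Y)
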