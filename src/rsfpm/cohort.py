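"""Patient-level cohort handling: reading, period analysis, age constraint.

A cohort is a pandas DataFrame of registry-style records with columns
``id, sex, age_dx, dx_date, exit_date, status, cancer_type`` (dates as
decimal calendar years).  Period analysis restricts estimation to the
person-time falling inside a recent calendar window, which turns into
delayed entry (left truncation) on the time-since-diagnosis scale.

The age constraint clamps the *modelled* age at the 2nd and 98th
percentiles of the cohort age distribution, so that patients in the
sparse extremes share the relative survival of the cut-off ages; the
original age is kept for life-table lookups and age-group assignment.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["id", "sex", "age_dx", "dx_date", "exit_date", "status", "cancer_type"]
STATUS_LABELS = {"dead", "censored"}

__all__ = ["read_cohort", "apply_period_window", "winsorise_age"]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a delimited-text cohort file."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError("no records in cohort file")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort file missing columns: {sorted(missing)}")
    _validate_cohort(df, line_offset=2)
    return df[COHORT_COLUMNS].copy()


def _validate_cohort(df: pd.DataFrame, line_offset: int = 0) -> None:
    bad_status = ~df["status"].isin(STATUS_LABELS)
    if bad_status.any():
        i = int(np.argmax(bad_status.to_numpy()))
        raise ValueError(
            f"unknown status {df['status'].iloc[i]!r} at line {df.index[i] + line_offset}"
        )
    from .lifetable import SEX_CODES

    bad_sex = ~df["sex"].isin(SEX_CODES)
    if bad_sex.any():
        i = int(np.argmax(bad_sex.to_numpy()))
        raise ValueError(f"unknown sex {df['sex'].iloc[i]!r} at line {df.index[i] + line_offset}")
    bad_dates = df["exit_date"].to_numpy() < df["dx_date"].to_numpy()
    if bad_dates.any():
        i = int(np.argmax(bad_dates))
        raise ValueError(
            f"exit_date before dx_date at line {df.index[i] + line_offset} (id={df['id'].iloc[i]})"
        )
    if (df["age_dx"].to_numpy() < 0).any():
        i = int(np.argmax(df["age_dx"].to_numpy() < 0))
        raise ValueError(f"negative age at line {df.index[i] + line_offset}")


def winsorise_age(cohort: pd.DataFrame, lower_pct: float = 2.0, upper_pct: float = 98.0):
    """Clamp the modelled age at the cohort's 2nd/98th age percentiles.

    Returns ``(cohort_with_age_model, low_cut, high_cut)``.  Percentiles
    use linear interpolation between order statistics (the repository-wide
    quantile convention).  The cohort should contain a single cancer type;
    cut points are computed on the cohort as passed, before any period
    window is applied.
    """
    if len(cohort) < 50:
        raise ValueError("winsorisation needs at least 50 patients for stable percentiles")
    ages = cohort["age_dx"].to_numpy(dtype=float)
    low, high = np.percentile(ages, [lower_pct, upper_pct], method="linear")
    out = cohort.copy()
    out["age_model"] = np.clip(ages, low, high)
    n_clamped = int(np.sum((ages < low) | (ages > high)))
    logger.info(
        "age constraint: cut points %.2f / %.2f, %d of %d patients clamped",
        low, high, n_clamped, len(cohort),
    )
    return out, float(low), float(high)


def apply_period_window(cohort: pd.DataFrame, window: tuple[float, float]) -> pd.DataFrame:
    """Restrict to person-time inside a calendar window [start, end).

    Patients whose follow-up ended before the window are dropped; those
    diagnosed before the window enter late at ``t0 = start - dx_date``
    (delayed entry); follow-up beyond the window's right edge is censored
    there.  Deaths exactly at the right edge count as censored (half-open
    window).  Returns analysis rows with columns ``t0``, ``t`` (years
    since diagnosis) and event indicator ``d``.
    """
    start, end = window
    if not start < end:
        raise ValueError("window start must be before end")
    df = cohort[(cohort["exit_date"] >= start) & (cohort["dx_date"] < end)].copy()
    if df.empty:
        raise ValueError("no person-time in window")
    t0 = np.maximum(0.0, start - df["dx_date"].to_numpy())
    exit_clipped = np.minimum(df["exit_date"].to_numpy(), end)
    t = exit_clipped - df["dx_date"].to_numpy()
    d = ((df["status"] == "dead") & (df["exit_date"] < end)).to_numpy().astype(int)
    keep = t > t0  # zero person-time rows (e.g. exit exactly at window start before entry)
    df["t0"] = t0
    df["t"] = t
    df["d"] = d
    df = df.loc[keep]
    if df.empty:
        raise ValueError("no person-time in window")
    return df
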