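"""Population (expected) mortality from a life table.

A life table is a complete grid of annual expected mortality rates
(deaths per person-year) stratified by sex, integer attained age and
integer calendar year.  Relative-survival methods treat these rates as
known: they supply the expected hazard ``h*`` and, by integration, the
expected survival ``S*`` of a cancer-free population comparable to each
patient.

The lookup convention is the registry standard: within each one-year
band of attained age and calendar year the rate is constant, so a
patient's expected-hazard path is a step function whose steps occur at
every birthday and every calendar new year after diagnosis.  Ages above
the table maximum reuse the maximum-age row; calendar years outside the
table range are clamped to the nearest available year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_CODES = {"male": 0, "female": 1}

__all__ = ["LifeTable", "read_lifetable", "expected_hazard_at", "expected_survival"]


@dataclass(frozen=True)
class LifeTable:
    """Expected mortality surface over sex x integer age x calendar year.

    ``rates[s, a, y]`` is the expected mortality rate for sex index ``s``
    (0 = male, 1 = female), age ``age_min + a`` and year ``year_min + y``.
    """

    rates: np.ndarray
    age_min: int
    age_max: int
    year_min: int
    year_max: int

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, dtype=float)
        expected_shape = (
            2,
            self.age_max - self.age_min + 1,
            self.year_max - self.year_min + 1,
        )
        if r.shape != expected_shape:
            raise ValueError(f"rates shape {r.shape} != {expected_shape}")
        if not np.all(np.isfinite(r)) or np.any(r < 0):
            raise ValueError("life-table rates must be finite and non-negative")
        object.__setattr__(self, "rates", r)

    @property
    def year_range(self) -> tuple[int, int]:
        return (self.year_min, self.year_max)

    def _sex_index(self, sex) -> np.ndarray:
        sex_arr = np.atleast_1d(np.asarray(sex))
        if sex_arr.dtype.kind in "iu":
            idx = sex_arr.astype(np.intp)
            if np.any((idx < 0) | (idx > 1)):
                raise ValueError("integer sex codes must be 0 (male) or 1 (female)")
            return idx
        try:
            return np.asarray([SEX_CODES[str(s)] for s in sex_arr], dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"unknown sex label {exc.args[0]!r}; expected 'male' or 'female'") from None

    def rate_at(self, sex, age, year) -> np.ndarray:
        """Annual rate at integer attained age and calendar year (capped/clamped)."""
        s = self._sex_index(sex)
        a = np.clip(np.floor(np.atleast_1d(age)).astype(np.intp), self.age_min, self.age_max) - self.age_min
        y = np.clip(np.floor(np.atleast_1d(year)).astype(np.intp), self.year_min, self.year_max) - self.year_min
        return self.rates[s, a, y]

    def hazard_path(self, sex, age_dx, dx_date, t_max: float):
        """Piecewise-constant expected-hazard paths for a set of patients.

        Returns ``(starts, lengths, rates)``, each of shape ``(n, K)``, such
        that the cumulative expected hazard of patient ``i`` at follow-up
        time ``u`` (years since diagnosis) is exactly

            H*_i(u) = sum_k rates[i, k] * clip(u - starts[i, k], 0, lengths[i, k]).

        Segment boundaries fall at every birthday and calendar new year
        between 0 and ``t_max``; the rate of each segment is looked up at
        its midpoint (robust to boundary rounding).
        """
        age_dx = np.atleast_1d(np.asarray(age_dx, dtype=float))
        dx_date = np.atleast_1d(np.asarray(dx_date, dtype=float))
        s_idx = self._sex_index(sex)
        if s_idx.size == 1:
            s_idx = np.broadcast_to(s_idx, age_dx.shape)
        n = age_dx.shape[0]
        n_years = int(np.ceil(t_max)) + 1

        # offsets (in follow-up time) of the first birthday / new year
        off_age = 1.0 - (age_dx - np.floor(age_dx))
        off_age = np.where(off_age >= 1.0, 1.0, off_age)
        off_year = 1.0 - (dx_date - np.floor(dx_date))
        off_year = np.where(off_year >= 1.0, 1.0, off_year)

        grid = np.arange(n_years, dtype=float)
        bps = np.concatenate(
            [
                np.zeros((n, 1)),
                off_age[:, None] + grid[None, :],
                off_year[:, None] + grid[None, :],
                np.full((n, 1), float(t_max)),
            ],
            axis=1,
        )
        np.clip(bps, 0.0, float(t_max), out=bps)
        bps.sort(axis=1)
        starts = bps[:, :-1]
        lengths = np.diff(bps, axis=1)
        mids = starts + 0.5 * lengths
        ages = np.floor(age_dx[:, None] + mids).astype(np.intp)
        years = np.floor(dx_date[:, None] + mids).astype(np.intp)
        a = np.clip(ages, self.age_min, self.age_max) - self.age_min
        y = np.clip(years, self.year_min, self.year_max) - self.year_min
        rates = self.rates[s_idx[:, None], a, y]
        rates = np.where(lengths > 0, rates, 0.0)
        return starts, lengths, rates

    def cumulative_hazard(self, sex, age_dx, dx_date, t):
        """Exact cumulative expected hazard H*(t), broadcast over patients/times."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t < 0):
            raise ValueError("follow-up time must be non-negative")
        age_dx = np.atleast_1d(np.asarray(age_dx, dtype=float))
        dx_date = np.atleast_1d(np.asarray(dx_date, dtype=float))
        s_idx = self._sex_index(sex)
        t, age_dx, dx_date, s_idx = np.broadcast_arrays(t, age_dx, dx_date, s_idx)
        starts, lengths, rates = self.hazard_path(
            s_idx, age_dx, dx_date, float(t.max(initial=0.0)) + 1e-12
        )
        dt = np.clip(t[:, None] - starts, 0.0, lengths)
        return np.einsum("ik,ik->i", rates, dt)


def read_lifetable(path) -> LifeTable:
    """Read and validate a ``sex,age,year,rate`` delimited-text life table."""
    df = pd.read_csv(path)
    required = {"sex", "age", "year", "rate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"life table missing columns: {sorted(missing)}")
    for col in ("age", "year"):
        vals = df[col].to_numpy()
        if not np.allclose(vals, np.round(vals)):
            bad = df.loc[~np.isclose(vals, np.round(vals))].iloc[0]
            raise ValueError(f"non-integer {col} in life table at (sex={bad['sex']}, age={bad['age']}, year={bad['year']})")
    df = df.assign(age=df["age"].astype(int), year=df["year"].astype(int))
    unknown = set(df["sex"].unique()) - set(SEX_CODES)
    if unknown:
        raise ValueError(f"unknown sex labels in life table: {sorted(unknown)}")
    neg = df[(df["rate"] < 0) | ~np.isfinite(df["rate"])]
    if len(neg):
        bad = neg.iloc[0]
        raise ValueError(f"invalid rate at (sex={bad['sex']}, age={bad['age']}, year={bad['year']}): {bad['rate']}")

    age_min, age_max = int(df["age"].min()), int(df["age"].max())
    year_min, year_max = int(df["year"].min()), int(df["year"].max())
    n_age = age_max - age_min + 1
    n_year = year_max - year_min + 1
    rates = np.full((2, n_age, n_year), np.nan)
    rates[
        df["sex"].map(SEX_CODES).to_numpy(),
        df["age"].to_numpy() - age_min,
        df["year"].to_numpy() - year_min,
    ] = df["rate"].to_numpy()
    holes = np.argwhere(np.isnan(rates))
    if len(holes):
        s, a, y = holes[0]
        sex_label = {v: k for k, v in SEX_CODES.items()}[int(s)]
        raise ValueError(
            f"incomplete life table: missing cell (sex={sex_label}, age={a + age_min}, "
            f"year={y + year_min}) and {len(holes) - 1} more"
        )
    return LifeTable(rates, age_min, age_max, year_min, year_max)


def expected_hazard_at(lt: LifeTable, sex, age_at_dx, dx_date, t):
    """Expected mortality rate h* at follow-up time t (years since diagnosis).

    Attained age is ``floor(age_at_dx + t)`` capped at the table maximum;
    attained calendar year is ``floor(dx_date + t)`` clamped to the table
    range.  Accepts scalars or aligned arrays; returns an array.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0):
        raise ValueError("follow-up time must be non-negative")
    age = np.atleast_1d(np.asarray(age_at_dx, dtype=float)) + t
    year = np.atleast_1d(np.asarray(dx_date, dtype=float)) + t
    return lt.rate_at(sex, age, year)


def expected_survival(lt: LifeTable, sex, age_at_dx, dx_date, t):
    """Expected survival S*(t) = exp(-integral of h*), exact over annual bands."""
    return np.exp(-lt.cumulative_hazard(sex, age_at_dx, dx_date, t))
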