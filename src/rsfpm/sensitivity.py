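"""Knot-sensitivity protocol: df grid, model selection, difference tables.

The protocol fits one flexible parametric model per combination of
degrees of freedom for the baseline excess hazard (3-7), the main age
effect (3-5) and the time-dependent age effect (2-5) — sixty models —
selects the minimum-AIC and minimum-BIC models, and tabulates the
percentage-point differences between the reference model (5, 3, 3) and
the selected models (plus the Pohar Perme estimate for the standardised
column) at one and five years, for standardised, age-group and
age-specific relative survival.

A transcription of the published difference tables (both sexes, ten
cancer types, 1- and 5-year horizons) ships with the package so the
summary statistics can be recomputed without registry data.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .fpm import FittedFPM, ModelConfig, fit_fpm
from .nonparam import StepEstimate
from .predict import AGE_SPECIFIC_AGES, marginal_estimates

logger = logging.getLogger(__name__)

TABLE2_SHA256 = "6c7629d15de53d834b96a51e63737f374ba25dc48c0637ab5a04740eacc83244"

STD_COLUMNS = ["std_aic", "std_bic", "std_pp"]
GROUP_COLUMNS = [f"group{g}_{c}" for g in range(1, 6) for c in ("aic", "bic")]
AGE_COLUMNS = [f"age{a}_{c}" for a in (55, 65, 75, 85) for c in ("aic", "bic")]
ALL_CELL_COLUMNS = STD_COLUMNS + GROUP_COLUMNS + AGE_COLUMNS

__all__ = [
    "GridSpec", "make_grid", "run_grid", "select_models", "difference_table",
    "summarise_differences", "load_published_differences",
]


@dataclass(frozen=True)
class GridSpec:
    """The df grid of the sensitivity protocol (default: the 60-model grid)."""

    df_baseline_set: tuple[int, ...] = (3, 4, 5, 6, 7)
    df_age_set: tuple[int, ...] = (3, 4, 5)
    df_tvc_set: tuple[int, ...] = (2, 3, 4, 5)
    reference: tuple[int, int, int] = (5, 3, 3)
    tvc_linear_only: bool = False

    def __post_init__(self) -> None:
        if not (self.df_baseline_set and self.df_age_set and self.df_tvc_set):
            raise ValueError("df sets must be non-empty")
        ref = self.reference
        if not (ref[0] in self.df_baseline_set and ref[1] in self.df_age_set
                and ref[2] in self.df_tvc_set):
            raise ValueError(f"reference {ref} not in grid")

    @property
    def size(self) -> int:
        return len(self.df_baseline_set) * len(self.df_age_set) * len(self.df_tvc_set)


def make_grid(spec: GridSpec) -> list[ModelConfig]:
    """Cartesian product of the df sets, baseline-major deterministic order."""
    return [
        ModelConfig(b, a, v, tvc_linear_only=spec.tvc_linear_only)
        for b, a, v in itertools.product(spec.df_baseline_set, spec.df_age_set, spec.df_tvc_set)
    ]


def run_grid(rows: pd.DataFrame, lifetable, spec: GridSpec,
             age_low: float | None = None, age_high: float | None = None) -> list[FittedFPM]:
    """Fit every model of the grid; non-converged fits are kept, flagged."""
    fits = []
    for cfg in make_grid(spec):
        fit = fit_fpm(rows, lifetable, cfg, age_low=age_low, age_high=age_high)
        fits.append(fit)
        logger.info("grid fit %s: ll=%.3f aic=%.1f bic=%.1f converged=%s",
                    cfg.as_tuple(), fit.loglik, fit.aic, fit.bic, fit.converged)
    ref = next(f for f in fits if f.config.as_tuple() == spec.reference)
    if not ref.converged:
        raise RuntimeError(f"reference model {spec.reference} did not converge")
    return fits


def select_models(fits: list[FittedFPM]) -> tuple[ModelConfig, ModelConfig]:
    """Minimum-AIC and minimum-BIC configs among converged fits.

    Ties go to the model with fewer parameters, then to grid order.
    """
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fits to select from")

    def pick(key):
        best = converged[0]
        for f in converged[1:]:
            k, kb = key(f), key(best)
            if k < kb or (k == kb and f.n_params < best.n_params):
                best = f
        return best.config

    return pick(lambda f: f.aic), pick(lambda f: f.bic)


def grid_summary(fits: list[FittedFPM]) -> pd.DataFrame:
    return pd.DataFrame({
        "df_baseline": [f.config.df_baseline for f in fits],
        "df_age": [f.config.df_age for f in fits],
        "df_tvc": [f.config.df_tvc for f in fits],
        "loglik": [f.loglik for f in fits],
        "n_params": [f.n_params for f in fits],
        "aic": [f.aic for f in fits],
        "bic": [f.bic for f in fits],
        "converged": [f.converged for f in fits],
    })


def _estimates_for(fit: FittedFPM, cohort: pd.DataFrame, horizons, age_groups):
    """Standardised, per-group and age-specific survival at the horizons."""
    times = np.asarray(horizons, dtype=float)
    from .predict import AGE_GROUPS_DEFAULT

    groups_def = tuple(age_groups) if age_groups is not None else AGE_GROUPS_DEFAULT
    std = marginal_estimates(fit, cohort, times, "standardised", age_groups=age_groups)[0]
    groups = marginal_estimates(fit, cohort, times, "age_groups", age_groups=age_groups)
    spec_ages = marginal_estimates(fit, cohort, times, "age_specific")
    out = {"std": std.estimate}
    for res in groups:
        g = groups_def.index(tuple(res.meta["group"])) + 1
        out[f"group{g}"] = res.estimate
    for a, res in zip(AGE_SPECIFIC_AGES, spec_ages):
        out[f"age{int(a)}"] = res.estimate
    return out


def difference_table(fits: list[FittedFPM], selections: tuple[ModelConfig, ModelConfig],
                     pp_estimate: StepEstimate, cohort: pd.DataFrame,
                     horizons=(1.0, 5.0), age_groups=None, sex: str = "all",
                     cancer_type: str = "synthetic",
                     reference: tuple[int, int, int] = (5, 3, 3)) -> pd.DataFrame:
    """Reference-minus-comparator differences in percentage points.

    One row per horizon; columns as in the published tables: standardised
    differences against the minimum-AIC model, the minimum-BIC model and
    the Pohar Perme estimate, then per-age-group and age-specific
    differences against the AIC/BIC selections.  Cells are
    (reference - comparator) * 100.
    """
    by_cfg = {f.config.as_tuple(): f for f in fits}
    max_t = float(cohort["t"].max())
    if max(horizons) > max_t:
        raise ValueError(f"horizon {max(horizons)} beyond observed follow-up {max_t:.2f}")
    missing = [t for t in (reference, selections[0].as_tuple(), selections[1].as_tuple())
               if t not in by_cfg]
    if missing:
        raise ValueError(f"configs missing from fits: {missing}")
    ref_fit = by_cfg[reference]
    if not ref_fit.converged:
        raise ValueError(f"reference model {reference} did not converge")
    aic_fit = by_cfg[selections[0].as_tuple()]
    bic_fit = by_cfg[selections[1].as_tuple()]
    if not (aic_fit.converged and bic_fit.converged):
        raise ValueError("selected fits must be converged")

    est_ref = _estimates_for(ref_fit, cohort, horizons, age_groups)
    est_aic = _estimates_for(aic_fit, cohort, horizons, age_groups)
    est_bic = _estimates_for(bic_fit, cohort, horizons, age_groups)
    pp_vals = pp_estimate.value_at(np.asarray(horizons, dtype=float))

    records = []
    for h_idx, h in enumerate(horizons):
        rec = {"sex": sex, "cancer_type": cancer_type, "horizon_years": h,
               "std_aic": 100.0 * (est_ref["std"][h_idx] - est_aic["std"][h_idx]),
               "std_bic": 100.0 * (est_ref["std"][h_idx] - est_bic["std"][h_idx]),
               "std_pp": 100.0 * (est_ref["std"][h_idx] - pp_vals[h_idx])}
        for g in range(1, 6):
            key = f"group{g}"
            if key in est_ref:
                rec[f"{key}_aic"] = 100.0 * (est_ref[key][h_idx] - est_aic[key][h_idx])
                rec[f"{key}_bic"] = 100.0 * (est_ref[key][h_idx] - est_bic[key][h_idx])
        for a in (55, 65, 75, 85):
            key = f"age{a}"
            rec[f"{key}_aic"] = 100.0 * (est_ref[key][h_idx] - est_aic[key][h_idx])
            rec[f"{key}_bic"] = 100.0 * (est_ref[key][h_idx] - est_bic[key][h_idx])
        records.append(rec)
    table = pd.DataFrame(records)
    bad = [c for c in ALL_CELL_COLUMNS if c in table.columns and not np.isfinite(table[c]).all()]
    if bad:
        raise ValueError(f"non-finite difference cells in columns {bad}")
    return table


def summarise_differences(table: pd.DataFrame, columns, statistic: str = "mean",
                          sex: str | None = None) -> float:
    """Mean or median of absolute cell values over the selected columns.

    ``columns`` may be a list of column names or one of the shorthands
    'standardised_aic', 'standardised_bic', 'standardised_pp',
    'age_group_aic', 'age_group_bic', 'age_specific_aic',
    'age_specific_bic'.
    """
    shorthands = {
        "standardised_aic": ["std_aic"],
        "standardised_bic": ["std_bic"],
        "standardised_pp": ["std_pp"],
        "age_group_aic": [c for c in GROUP_COLUMNS if c.endswith("aic")],
        "age_group_bic": [c for c in GROUP_COLUMNS if c.endswith("bic")],
        "age_specific_aic": [c for c in AGE_COLUMNS if c.endswith("aic")],
        "age_specific_bic": [c for c in AGE_COLUMNS if c.endswith("bic")],
    }
    if isinstance(columns, str):
        columns = shorthands[columns]
    df = table
    if sex is not None:
        df = df[df["sex"] == sex]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"columns not in table: {missing}")
    cells = df[list(columns)].to_numpy(dtype=float)
    if cells.size == 0:
        raise ValueError("empty selection")
    if statistic == "mean":
        return float(np.mean(np.abs(cells)))
    if statistic == "median":
        return float(np.median(np.abs(cells)))
    raise ValueError(f"unknown statistic {statistic!r}")


def load_published_differences(verify_checksum: bool = True) -> pd.DataFrame:
    """The packaged transcription of the published difference tables."""
    ref = resources.files("rsfpm.data").joinpath("table2_differences.csv")
    raw = ref.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != TABLE2_SHA256:
            raise RuntimeError("published difference table fixture is corrupted")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))
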