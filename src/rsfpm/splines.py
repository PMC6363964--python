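"""Restricted cubic splines and quantile-based knot placement.

The spline dialect is the one used throughout the flexible-parametric
survival-modelling tradition (Royston–Parmar): a basis whose first column
is the covariate itself and whose remaining columns are truncated-cubic
terms constrained so that the fitted function is linear beyond the two
boundary knots and has continuous first and second derivatives at every
interior knot.  A basis with ``df`` degrees of freedom has ``df`` columns
and is induced by ``df + 1`` knots (two boundary knots plus ``df - 1``
interior knots); ``df = 1`` is the plain linear term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KnotVector", "SplineBasisSpec", "place_knots", "rcs_eval"]


@dataclass(frozen=True)
class KnotVector:
    """Boundary and interior knots on a (possibly transformed) axis."""

    boundary_low: float
    boundary_high: float
    interior: tuple[float, ...] = ()
    axis_label: str = "log-time"

    def __post_init__(self) -> None:
        interior = tuple(float(k) for k in self.interior)
        object.__setattr__(self, "interior", interior)
        if not self.boundary_low < self.boundary_high:
            raise ValueError(
                f"degenerate knot vector: boundary_low={self.boundary_low!r} "
                f"must be < boundary_high={self.boundary_high!r}"
            )
        if any(k2 <= k1 for k1, k2 in zip(interior, interior[1:])):
            raise ValueError("degenerate knot vector: interior knots must be strictly increasing")
        if interior and not (
            self.boundary_low < interior[0] and interior[-1] < self.boundary_high
        ):
            raise ValueError("degenerate knot vector: interior knots must lie strictly inside the boundaries")

    @property
    def df(self) -> int:
        """Degrees of freedom: number of knots minus one."""
        return len(self.interior) + 1

    @property
    def all_knots(self) -> np.ndarray:
        return np.asarray([self.boundary_low, *self.interior, self.boundary_high])


@dataclass(frozen=True)
class SplineBasisSpec:
    """A knot vector together with the basis dimension it induces."""

    knots: KnotVector
    df: int = field(default=0)

    def __post_init__(self) -> None:
        df = self.df if self.df else self.knots.df
        object.__setattr__(self, "df", df)
        if df != self.knots.df:
            raise ValueError(f"df={df} inconsistent with knots (df={self.knots.df})")


def place_knots(values, df: int, transform: str = "log", axis_label: str | None = None) -> KnotVector:
    """Place boundary and interior knots from an empirical distribution.

    Boundary knots sit at the minimum and maximum of the (transformed)
    values; the ``df - 1`` interior knots sit at the equally spaced
    quantiles ``1/df, ..., (df-1)/df``, using linear interpolation between
    order statistics.

    Parameters
    ----------
    values : array-like
        Observed values (event times or ages). Must be positive when
        ``transform='log'``.
    df : int
        Degrees of freedom of the basis the knots will induce (>= 1).
    transform : {'log', 'identity'}
        Axis transform applied before taking quantiles.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot place knots on an empty sample")
    if df < 1:
        raise ValueError("df must be >= 1")
    if transform == "log":
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive values")
        x = np.log(x)
        label = axis_label or "log-time"
    elif transform == "identity":
        label = axis_label or "age"
    else:
        raise ValueError(f"unknown transform {transform!r}")

    n_distinct = np.unique(x).size
    if df >= n_distinct and df > 1:
        raise ValueError(
            f"degenerate knot vector: df={df} requires more distinct values than the {n_distinct} available"
        )

    lo, hi = float(np.min(x)), float(np.max(x))
    if df == 1:
        if lo == hi:
            raise ValueError("degenerate knot vector: all values identical")
        return KnotVector(lo, hi, (), label)

    probs = np.arange(1, df) / df
    interior = np.quantile(x, probs, method="linear")
    if np.unique(interior).size != interior.size:
        raise ValueError("degenerate knot vector: duplicate interior knots at requested quantiles")
    return KnotVector(lo, hi, tuple(float(k) for k in interior), label)


def rcs_eval(u, spec: SplineBasisSpec | KnotVector) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the restricted cubic basis and its first derivative.

    Returns ``(basis, deriv)``, each of shape ``(len(u), df)``.  Column 1
    is ``u`` itself; column ``j >= 2`` is

        v_j(u) = (u - k_j)^3_+ - lam_j (u - k_min)^3_+ - (1 - lam_j)(u - k_max)^3_+

    with ``lam_j = (k_max - k_j) / (k_max - k_min)`` and ``k_j`` the j-th
    interior knot.  Derivatives are exact.
    """
    if isinstance(spec, KnotVector):
        spec = SplineBasisSpec(spec)
    knots = spec.knots
    u = np.atleast_1d(np.asarray(u, dtype=float))
    n = u.shape[0]
    basis = np.empty((n, spec.df))
    deriv = np.empty((n, spec.df))
    basis[:, 0] = u
    deriv[:, 0] = 1.0

    k_min, k_max = knots.boundary_low, knots.boundary_high
    span = k_max - k_min
    cube_lo = np.maximum(u - k_min, 0.0) ** 3
    cube_hi = np.maximum(u - k_max, 0.0) ** 3
    dcube_lo = 3.0 * np.maximum(u - k_min, 0.0) ** 2
    dcube_hi = 3.0 * np.maximum(u - k_max, 0.0) ** 2
    for j, kj in enumerate(knots.interior, start=1):
        lam = (k_max - kj) / span
        cube_j = np.maximum(u - kj, 0.0) ** 3
        dcube_j = 3.0 * np.maximum(u - kj, 0.0) ** 2
        basis[:, j] = cube_j - lam * cube_lo - (1.0 - lam) * cube_hi
        deriv[:, j] = dcube_j - lam * dcube_lo - (1.0 - lam) * dcube_hi
    return basis, deriv
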