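"""Saturation modeling of peak-discovery build curves.

A polynomial (orders 1..5) is fit by least squares to the build-curve
points (replicates added, peaks called). The plateau — the replicate
count at which discovery saturates — is the smallest positive root of
the fitted polynomial's first derivative; the model value there
estimates the total discoverable peak set, and observed/predicted gives
the fraction of the binding profile already discovered.

Because R² of nested polynomial fits is monotone in order, "best R²"
alone always selects the highest order; the default criterion instead
selects the lowest order whose R² is within ``delta_r2`` (1e-3) of the
order-5 fit, favoring the smoothest curve that explains the data.

``H3K4ME3_REFERENCE_QUINTIC`` and ``BCATENIN_REFERENCE_CUBIC`` are
published discovery-curve fits (ascending coefficient order) for deeply
replicated H3K4me3 (10 replicates) and β-catenin (25 replicates)
CUT&RUN aggregation experiments, kept as reference inputs for the
derivative/plateau machinery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.polynomial import polynomial as P
from scipy.optimize import brentq

__all__ = [
    "PolynomialModel",
    "PlateauEstimate",
    "SaturationError",
    "H3K4ME3_REFERENCE_QUINTIC",
    "BCATENIN_REFERENCE_CUBIC",
    "fit_polynomials",
    "poly_derivative",
    "smallest_positive_root",
    "plateau_estimate",
    "fraction_discovered",
]

logger = logging.getLogger("iceberg")

# ascending degree: constant term first
H3K4ME3_REFERENCE_QUINTIC = (
    14700.3867, 370.7989, 176.2564, -74.7615, 10.3849, -0.4687
)
BCATENIN_REFERENCE_CUBIC = (-812.39289, 1036.53907, -20.94564, 0.08184)


class SaturationError(ValueError):
    pass


@dataclass(frozen=True)
class PolynomialModel:
    """A fitted polynomial: coefficients in ascending degree order."""

    coefficients: tuple[float, ...]
    order: int
    r_squared: float = math.nan
    fit_domain: tuple[float, float] = (math.nan, math.nan)

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.order + 1:
            raise SaturationError(
                f"order {self.order} needs {self.order + 1} coefficients, "
                f"got {len(self.coefficients)}"
            )

    def __call__(self, x) -> np.ndarray | float:
        return P.polyval(x, self.coefficients)

    @property
    def is_zero(self) -> bool:
        return all(c == 0 for c in self.coefficients)


@dataclass(frozen=True)
class PlateauEstimate:
    """Saturation point: x_star replicates, y_star predicted total peaks.

    Both are None when the derivative has no root in (0, horizon] —
    discovery has not saturated within the extrapolation horizon.
    """

    x_star: float | None
    y_star: float | None
    horizon: float


def fit_polynomials(
    points: Sequence[tuple[float, float]],
    max_order: int = 5,
    selection: str = "delta_r2",
    delta_r2: float = 1e-3,
) -> tuple[PolynomialModel, dict[int, PolynomialModel]]:
    """Least-squares polynomial fits of orders 1..max_order.

    Returns the selected model and all candidates keyed by order.
    Selection: ``"delta_r2"`` (lowest order within ``delta_r2`` of the
    highest order's R²), ``"adj_r2"`` (max adjusted R²), or
    ``"order:N"`` (fixed order N). Orders with more parameters than
    points are skipped with a warning.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3:
        raise SaturationError("need at least 3 points to fit")
    n_distinct = len({x for x, _ in pts})
    if n_distinct < 2:
        raise SaturationError("need at least 2 distinct x values to fit")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    domain = (float(x.min()), float(x.max()))

    candidates: dict[int, PolynomialModel] = {}
    for order in range(1, max_order + 1):
        if order + 1 > n_distinct:
            logger.warning(
                "skipping order %d: only %d distinct x values", order, n_distinct
            )
            continue
        coeffs = P.polyfit(x, y, order)
        resid = y - P.polyval(x, coeffs)
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        candidates[order] = PolynomialModel(
            coefficients=tuple(float(c) for c in coeffs),
            order=order,
            r_squared=r2,
            fit_domain=domain,
        )
    if not candidates:
        raise SaturationError("no polynomial order could be fit")

    orders = sorted(candidates)
    if selection.startswith("order:"):
        wanted = int(selection.split(":", 1)[1])
        if wanted not in candidates:
            raise SaturationError(f"order {wanted} was not fit (available: {orders})")
        selected = candidates[wanted]
    elif selection == "adj_r2":
        def adj(m: PolynomialModel) -> float:
            n = len(pts)
            k = m.order
            if n - k - 1 <= 0:
                return -math.inf
            return 1 - (1 - m.r_squared) * (n - 1) / (n - k - 1)
        selected = max(candidates.values(), key=adj)
    elif selection == "delta_r2":
        best_r2 = candidates[orders[-1]].r_squared
        selected = next(
            candidates[o] for o in orders if candidates[o].r_squared >= best_r2 - delta_r2
        )
    else:
        raise SaturationError(f"unknown selection criterion {selection!r}")
    return selected, candidates


def poly_derivative(model: PolynomialModel) -> PolynomialModel:
    """Exact term-wise first derivative (order reduced by one)."""
    if model.order == 0:
        return PolynomialModel(coefficients=(0.0,), order=0, fit_domain=model.fit_domain)
    coeffs = tuple(float(c) for c in P.polyder(model.coefficients))
    return PolynomialModel(
        coefficients=coeffs, order=model.order - 1, fit_domain=model.fit_domain
    )


def smallest_positive_root(
    poly: PolynomialModel | Sequence[float],
    horizon: float,
    scan_points: int = 100_001,
) -> float | None:
    """Smallest x in (0, horizon] with poly(x) = 0, or None.

    Dense sign-scan over a uniform grid followed by bisection
    (refined to well below 1e-9 in x). A polynomial that never changes
    sign on the grid yields None.
    """
    coeffs = tuple(poly.coefficients) if isinstance(poly, PolynomialModel) else tuple(poly)
    if all(c == 0 for c in coeffs):
        raise SaturationError("zero polynomial has no well-defined roots")
    if horizon <= 0:
        raise SaturationError(f"horizon must be > 0, got {horizon}")

    grid = np.linspace(0.0, float(horizon), scan_points)
    values = P.polyval(grid, coeffs)

    exact = np.flatnonzero((values == 0.0) & (grid > 0))
    first_exact = grid[exact[0]] if len(exact) else None

    sign = np.sign(values)
    flips = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    first_flip = None
    for i in flips:
        lo, hi = grid[i], grid[i + 1]
        root = float(brentq(lambda t: P.polyval(t, coeffs), lo, hi, xtol=1e-12))
        if root > 0:
            first_flip = root
            break
    roots = [r for r in (first_exact, first_flip) if r is not None]
    return min(roots) if roots else None


def plateau_estimate(
    model: PolynomialModel, horizon: float | None = None
) -> PlateauEstimate:
    """Saturation point of a fitted discovery curve.

    The default extrapolation horizon is three times the largest
    observed x; a derivative with no root inside the horizon reports an
    absent plateau rather than an extrapolated guess.
    """
    if horizon is None:
        if math.isnan(model.fit_domain[1]):
            raise SaturationError("model has no fit domain; pass horizon explicitly")
        horizon = 3.0 * model.fit_domain[1]
    deriv = poly_derivative(model)
    if deriv.is_zero:
        return PlateauEstimate(x_star=None, y_star=None, horizon=horizon)
    x_star = smallest_positive_root(deriv, horizon)
    if x_star is None:
        return PlateauEstimate(x_star=None, y_star=None, horizon=horizon)
    return PlateauEstimate(x_star=x_star, y_star=float(model(x_star)), horizon=horizon)


def fraction_discovered(observed_count: int, predicted_total: float) -> float:
    """Percentage of the predicted total peak set already observed."""
    if predicted_total <= 0:
        raise SaturationError(f"predicted total must be > 0, got {predicted_total}")
    return 100.0 * observed_count / predicted_total
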