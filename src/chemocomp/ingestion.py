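"""Grazing-rate estimation from bottle experiments.

Implements the classical control/grazed bottle framework: the prey growth
coefficient ``k`` from control bottles, the grazing coefficient ``g`` from
grazed bottles, Frost's time-averaged prey density, the logarithmic-mean
grazer density, and the derived clearance and ingestion rates.  A saturating
(Michaelis-Menten) functional response ``I(C) = I_max * C / (K + C)`` is then
fitted across prey densities to obtain the maximum ingestion rate I_max.

The estimators assume exponential prey growth minus a constant clearance
(Frost's standard form) and exponential grazer change over the incubation
(the logarithmic-mean correction); both assumptions are exact for the
synthetic bottles produced by :mod:`chemocomp.synthcommunity`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from ._core import LIMIT_TOL, log_mean

__all__ = [
    "BottleExperiment",
    "FunctionalResponseFit",
    "prey_growth_coefficient",
    "grazing_coefficient",
    "mean_prey_density",
    "mean_grazer_density",
    "clearance_and_ingestion",
    "fit_functional_response",
    "read_bottle_table",
]


@dataclass(frozen=True)
class BottleExperiment:
    """Paired control/grazed bottle counts for one incubation.

    Counts are cells (prey) or individuals (grazers) per ml; duration in days.
    """

    prey_control_start: float
    prey_control_end: float
    prey_grazed_start: float
    prey_grazed_end: float
    grazer_start: float
    grazer_end: float
    duration: float

    def __post_init__(self) -> None:
        for name in (
            "prey_control_start",
            "prey_control_end",
            "prey_grazed_start",
            "prey_grazed_end",
            "grazer_start",
            "grazer_end",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")


@dataclass(frozen=True)
class FunctionalResponseFit:
    """Fitted saturating functional response I(C) = I_max*C/(K+C)."""

    imax: float  # prey cells per grazer per day
    half_saturation_k: float  # cells per ml
    residual_sse: float
    converged: bool

    def predict(self, density):
        c = np.asarray(density, dtype=float)
        return self.imax * c / (self.half_saturation_k + c)


def prey_growth_coefficient(exp: BottleExperiment) -> float:
    """Prey growth constant k (per day) from the grazer-free control bottle."""
    return math.log(exp.prey_control_end / exp.prey_control_start) / exp.duration


def grazing_coefficient(exp: BottleExperiment) -> float:
    """Grazing constant g (per day): control growth minus grazed net rate."""
    k = prey_growth_coefficient(exp)
    return k - math.log(exp.prey_grazed_end / exp.prey_grazed_start) / exp.duration


def mean_prey_density(exp: BottleExperiment) -> float:
    """Frost's time-averaged prey density in the grazed bottle (cells/ml).

    C̄ = C1 * (e^{(k-g)T} - 1) / ((k-g) T); the (k-g) -> 0 limit is the
    starting density itself.
    """
    k = prey_growth_coefficient(exp)
    g = grazing_coefficient(exp)
    net = (k - g) * exp.duration
    if abs(net) < LIMIT_TOL:
        return exp.prey_grazed_start
    return exp.prey_grazed_start * (math.expm1(net)) / net


def mean_grazer_density(start: float, end: float) -> float:
    """Time-averaged grazer density (logarithmic mean of start and end)."""
    return log_mean(start, end)


def clearance_and_ingestion(exp: BottleExperiment) -> tuple[float, float]:
    """Per-capita clearance (ml/grazer/d) and ingestion (cells/grazer/d).

    clearance = g / N̄ with N̄ the logarithmic-mean grazer density;
    ingestion = clearance * C̄ with C̄ Frost's mean prey density.  A negative
    grazing coefficient (grazed bottle outgrowing the control) is reported
    as-is with a warning, never clamped.
    """
    g = grazing_coefficient(exp)
    if g < 0:
        warnings.warn(
            f"negative grazing coefficient g={g:.4g}/d: grazed bottle outgrew "
            "the control; estimates returned unclamped",
            stacklevel=2,
        )
    clearance = g / mean_grazer_density(exp.grazer_start, exp.grazer_end)
    return clearance, clearance * mean_prey_density(exp)


def fit_functional_response(
    points: Sequence[tuple[float, float]],
    *,
    exclude_negative: bool = True,
) -> FunctionalResponseFit:
    """Least-squares fit of I(C) = I_max*C/(K+C) to (prey density, ingestion).

    Requires at least three points with distinct densities.  Negative
    ingestion estimates (from negative grazing coefficients) are excluded by
    default.  The fit is initialised from a Hanes-Woolf linearisation and K
    is bounded to (0, 10*max density].
    """
    pts = [(float(c), float(i)) for c, i in points]
    if exclude_negative:
        pts = [(c, i) for c, i in pts if i >= 0]
    if len(pts) < 3:
        raise ValueError(f"need >= 3 usable points, got {len(pts)}")
    c = np.array([p[0] for p in pts])
    i = np.array([p[1] for p in pts])
    if len(np.unique(c)) < 3:
        raise ValueError("need >= 3 distinct prey densities")
    if np.all(i == 0):
        return FunctionalResponseFit(0.0, c.max(), 0.0, True)

    k_hi = 10.0 * c.max()
    # Hanes-Woolf: C/I = K/Imax + C/Imax, linear in C.
    pos = i > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(c[pos], c[pos] / i[pos], 1)
        imax0 = 1.0 / slope if slope > 0 else i.max()
        k0 = intercept * imax0 if intercept > 0 and slope > 0 else c.mean()
    else:
        imax0, k0 = i.max(), c.mean()
    imax0 = min(max(imax0, 1e-12), 10 * max(i.max(), 1e-12))
    k0 = min(max(k0, 1e-9), k_hi)

    def model(cc, imax, k):
        return imax * cc / (k + cc)

    try:
        popt, _ = curve_fit(
            model, c, i, p0=[imax0, k0], bounds=([0.0, 1e-12], [np.inf, k_hi]),
            maxfev=10000,
        )
        resid = i - model(c, *popt)
        return FunctionalResponseFit(float(popt[0]), float(popt[1]), float(resid @ resid), True)
    except RuntimeError:
        resid = i - model(c, imax0, k0)
        return FunctionalResponseFit(float(imax0), float(k0), float(resid @ resid), False)


_BOTTLE_COLUMNS = [
    "prey_control_start",
    "prey_control_end",
    "prey_grazed_start",
    "prey_grazed_end",
    "grazer_start",
    "grazer_end",
    "duration",
]


def read_bottle_table(path) -> list[BottleExperiment]:
    """Read bottle experiments from CSV, one row per bottle."""
    df = pd.read_csv(path)
    missing = set(_BOTTLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"bottle table missing columns: {sorted(missing)}")
    return [
        BottleExperiment(**{col: float(getattr(row, col)) for col in _BOTTLE_COLUMNS})
        for row in df.itertuples(index=False)
    ]
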