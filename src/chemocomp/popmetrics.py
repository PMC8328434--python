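"""Population-dynamics statistics from censored biomass time series.

Net growth rates r = (ln B2 - ln B1)/(t2 - t1), time-averaged densities,
population filtration rates F = I_max * C̄, log-linear phase rates, and the
Coleps:Euplotes log biomass ratio.  Observations below the counting detection
limit are substituted with half the limit and flagged censored, never
silently imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._core import log_mean
from .allometry import TaxonProfile, abundance_to_carbon

__all__ = [
    "BiomassSeries",
    "DetectionPolicy",
    "apply_detection_policy",
    "net_growth_rate",
    "time_averaged_density",
    "population_filtration_rate",
    "phase_rate",
    "log_biomass_ratio",
]


@dataclass(frozen=True)
class DetectionPolicy:
    """Censoring rule for counts below the detection limit.

    Zero counts are replaced by ``substitute`` (conventionally half the
    detection limit, e.g. 0.25 cells/ml for a 0.5 cells/ml limit from one
    cell in a 2-ml subsample) and flagged.
    """

    detection_limit: float  # cells per ml
    substitute: float  # cells per ml

    def __post_init__(self) -> None:
        if not 0 < self.substitute <= self.detection_limit:
            raise ValueError(
                f"require 0 < substitute <= detection_limit, got "
                f"substitute={self.substitute}, limit={self.detection_limit}"
            )

    @classmethod
    def half_limit(cls, detection_limit: float) -> "DetectionPolicy":
        return cls(detection_limit, 0.5 * detection_limit)


@dataclass(frozen=True)
class BiomassSeries:
    """Replicated time series of abundance/biomass for one taxon.

    ``censored`` marks points that were below detection and substituted.
    ``biomass_carbon`` (pg C/ml) is derived from abundance via the taxon
    profile when one is attached.
    """

    taxon: str
    treatment: str
    replicate: str
    times: np.ndarray  # days, strictly ascending
    abundance: np.ndarray  # cells per ml
    biomass_carbon: np.ndarray | None = None  # pg C per ml
    censored: np.ndarray | None = None
    profile: TaxonProfile | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        abundance = np.asarray(self.abundance, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "abundance", abundance)
        if times.ndim != 1 or abundance.shape != times.shape:
            raise ValueError("times and abundance must be 1-D and congruent")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly ascending")
        if np.any(abundance < 0):
            raise ValueError("abundance must be >= 0")
        if self.censored is None:
            object.__setattr__(self, "censored", np.zeros(times.shape, dtype=bool))
        else:
            object.__setattr__(self, "censored", np.asarray(self.censored, dtype=bool))
        if self.biomass_carbon is None and self.profile is not None:
            bm = np.array([abundance_to_carbon(a, self.profile) for a in abundance])
            object.__setattr__(self, "biomass_carbon", bm)
        elif self.biomass_carbon is not None:
            bm = np.asarray(self.biomass_carbon, dtype=float)
            if np.any(bm < 0):
                raise ValueError("biomass_carbon must be >= 0")
            object.__setattr__(self, "biomass_carbon", bm)

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-observation table."""
        data = {
            "day": self.times,
            "treatment": self.treatment,
            "replicate": self.replicate,
            "taxon": self.taxon,
            "abundance_per_ml": self.abundance,
            "censored": self.censored,
        }
        if self.biomass_carbon is not None:
            data["biomass_pgc_per_ml"] = self.biomass_carbon
        return pd.DataFrame(data)


def apply_detection_policy(series: BiomassSeries, policy: DetectionPolicy) -> BiomassSeries:
    """Substitute below-detection (zero-count) observations and flag them.

    Positive observations pass through unchanged; biomass is recomputed from
    the substituted abundance when a taxon profile is attached.
    """
    below = series.abundance < policy.detection_limit
    abundance = np.where(below, policy.substitute, series.abundance)
    censored = series.censored | below
    biomass = series.biomass_carbon
    if series.profile is not None:
        biomass = np.array([abundance_to_carbon(a, series.profile) for a in abundance])
    elif biomass is not None:
        # scale substituted biomass in proportion where abundance was zero
        with np.errstate(divide="ignore", invalid="ignore"):
            biomass = np.where(below, np.nan, biomass)
    return replace(series, abundance=abundance, biomass_carbon=biomass, censored=censored)


def net_growth_rate(b1: float, b2: float, t1: float, t2: float) -> float:
    """Net growth rate r = (ln B2 - ln B1)/(t2 - t1), per day."""
    if b1 <= 0 or b2 <= 0:
        raise ValueError(f"biomass must be > 0, got ({b1}, {b2})")
    if t2 <= t1:
        raise ValueError(f"require t2 > t1, got ({t1}, {t2})")
    return (math.log(b2) - math.log(b1)) / (t2 - t1)


def time_averaged_density(c1: float, c2: float) -> float:
    """Time-averaged density between two samples of an exponential trajectory.

    C̄ = (C2 - C1)/(ln C2 - ln C1); shared with the grazer correction in
    :func:`chemocomp.ingestion.mean_grazer_density`.
    """
    return log_mean(c1, c2)


def population_filtration_rate(imax_carbon: float, cbar: float) -> tuple[float, float]:
    """Population filtration rate F = I_max * C̄ and its log10.

    ``imax_carbon`` in pg C per individual per day, ``cbar`` individuals per
    ml; returns (F, log10 F) with log10 F = -inf when F = 0.
    """
    if imax_carbon < 0 or cbar < 0:
        raise ValueError("imax_carbon and cbar must be >= 0")
    f = imax_carbon * cbar
    return f, (math.log10(f) if f > 0 else -math.inf)


def growth_rate_window(series: BiomassSeries, window: tuple[float, float]) -> float:
    """Two-point net growth rate over a window, using first/last points inside."""
    lo, hi = window
    mask = (series.times >= lo) & (series.times <= hi)
    if mask.sum() < 2:
        raise ValueError(f"need >= 2 points in window {window}")
    t = series.times[mask]
    b = series.biomass_carbon[mask] if series.biomass_carbon is not None else series.abundance[mask]
    return net_growth_rate(b[0], b[-1], t[0], t[-1])


def phase_rate(series: BiomassSeries, window: tuple[float, float]) -> float:
    """OLS slope of ln(biomass) vs time over the window (per day).

    Uses uncensored points only; requires at least three.
    """
    lo, hi = window
    biomass = series.biomass_carbon if series.biomass_carbon is not None else series.abundance
    mask = (series.times >= lo) & (series.times <= hi) & ~series.censored & (biomass > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 uncensored positive points in window {window}, got {int(mask.sum())}"
        )
    slope, _ = np.polyfit(series.times[mask], np.log(biomass[mask]), 1)
    return float(slope)


def log_biomass_ratio(coleps_bm: float, euplotes_bm: float) -> float:
    """log10(Coleps biomass / Euplotes biomass); antisymmetric under swap."""
    if coleps_bm <= 0 or euplotes_bm <= 0:
        raise ValueError("biomasses must be > 0 (apply the detection policy first)")
    return math.log10(coleps_bm / euplotes_bm)


def log_ratio_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Tidy Coleps:Euplotes log-ratio table from an observed series table.

    Expects the tidy schema (day, treatment, replicate, taxon,
    biomass_pgc_per_ml).  Coleps clones (taxa starting with 'Col') are summed
    per sample before the ratio.  Output columns: treatment, replicate, day,
    log_ratio — ready for any external mixed-model ANOVA tool.
    """
    required = {"day", "treatment", "replicate", "taxon", "biomass_pgc_per_ml"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"series table missing columns: {sorted(missing)}")
    rows = []
    for (treatment, replicate, day), grp in frame.groupby(["treatment", "replicate", "day"]):
        eup = grp.loc[grp["taxon"] == "Eup", "biomass_pgc_per_ml"].sum()
        col = grp.loc[grp["taxon"].str.startswith("Col"), "biomass_pgc_per_ml"].sum()
        if eup > 0 and col > 0:
            rows.append(
                {
                    "treatment": treatment,
                    "replicate": replicate,
                    "day": day,
                    "log_ratio": log_biomass_ratio(col, eup),
                }
            )
    return pd.DataFrame(rows, columns=["treatment", "replicate", "day", "log_ratio"])
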