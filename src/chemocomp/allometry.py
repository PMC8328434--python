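"""Biovolume-to-carbon conversion via allometric laws.

Plankton carbon content scales allometrically with cell volume,
``C[pg] = m * a * V[um^3]^b``.  This module houses those laws for the study
organisms (two microalgae, two ciliates, the accompanying bacteria), converts
abundances and per-cell ingestion rates into carbon units, and derives diet
composition from carbon-based maximum ingestion rates.

Units are fixed package-wide: volumes in um^3, carbon in pg, concentrations
per ml, rates per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd

from ._core import round_sig

__all__ = [
    "AllometricLaw",
    "TaxonProfile",
    "carbon_per_cell",
    "carbon_density",
    "abundance_to_carbon",
    "imax_to_carbon",
    "diet_share",
    "study_profiles",
    "read_trait_table",
    "write_trait_table",
]


@dataclass(frozen=True)
class AllometricLaw:
    """Power law ``C[pg] = m * a * V^b`` mapping cell volume to carbon.

    ``multiplier_m`` accommodates laws stated via an intermediate currency,
    e.g. the bacterial dry-weight law with carbon assumed half of dry weight
    (m = 0.5).
    """

    coefficient_a: float  # pg per um^3^b
    exponent_b: float  # dimensionless
    multiplier_m: float = 1.0  # dimensionless

    def __post_init__(self) -> None:
        if self.coefficient_a <= 0:
            raise ValueError(f"coefficient_a must be > 0, got {self.coefficient_a}")
        if self.exponent_b <= 0:
            raise ValueError(f"exponent_b must be > 0, got {self.exponent_b}")
        if self.multiplier_m <= 0:
            raise ValueError(f"multiplier_m must be > 0, got {self.multiplier_m}")


def carbon_per_cell(volume: float, law: AllometricLaw) -> float:
    """Carbon content (pg) of a single cell of the given volume (um^3)."""
    if volume <= 0:
        raise ValueError(f"cell volume must be > 0, got {volume}")
    return law.multiplier_m * law.coefficient_a * volume**law.exponent_b


def carbon_density(volume: float, law: AllometricLaw) -> float:
    """Volume-specific carbon content (pg C per um^3) at the given volume.

    For linear laws (b = 1) this is volume independent and equals m*a.
    Full precision is returned; round only when formatting.
    """
    return carbon_per_cell(volume, law) / volume


@dataclass(frozen=True)
class TaxonProfile:
    """Morphometry and carbon law of one organism.

    ``carbon_density`` is derived from the law at the mean cell volume and
    cached at full precision so downstream conversions do not compound
    rounding error.
    """

    name: str
    mean_cell_volume: float  # um^3
    law: AllometricLaw
    detection_limit_abundance: float | None = None  # cells per ml
    carbon_density: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mean_cell_volume <= 0:
            raise ValueError(f"mean_cell_volume must be > 0, got {self.mean_cell_volume}")
        object.__setattr__(
            self, "carbon_density", carbon_density(self.mean_cell_volume, self.law)
        )

    @property
    def carbon_per_cell(self) -> float:
        """Carbon content (pg) of an average cell."""
        return self.carbon_density * self.mean_cell_volume


def abundance_to_carbon(abundance: float, profile: TaxonProfile) -> float:
    """Convert an abundance (cells/ml) to carbon biomass (pg C/ml)."""
    if abundance < 0:
        raise ValueError(f"abundance must be >= 0, got {abundance}")
    return abundance * profile.mean_cell_volume * profile.carbon_density


def imax_to_carbon(imax_cells: float, prey: TaxonProfile) -> float:
    """Convert a maximum ingestion rate from prey cells/d to pg C/d.

    ``imax_cells`` is prey cells per ciliate per day; the result is carbon
    ingested per ciliate per day given the prey's mean cell carbon.
    """
    if imax_cells < 0:
        raise ValueError(f"imax_cells must be >= 0, got {imax_cells}")
    return imax_cells * prey.mean_cell_volume * prey.carbon_density


def diet_share(imax_by_prey: Mapping[str, float]) -> dict[str, float]:
    """Fraction of total carbon intake contributed by each prey.

    Input maps prey name -> carbon-based maximum ingestion rate
    (pg C per ciliate per day).  Shares sum to one.
    """
    if not imax_by_prey:
        raise ValueError("diet_share needs at least one prey")
    total = sum(imax_by_prey.values())
    if total <= 0:
        raise ValueError("diet_share undefined: all ingestion rates are zero")
    for prey, rate in imax_by_prey.items():
        if rate < 0:
            raise ValueError(f"negative ingestion rate for {prey!r}: {rate}")
    return {prey: rate / total for prey, rate in imax_by_prey.items()}


# ---------------------------------------------------------------------------
# Study organisms
# ---------------------------------------------------------------------------

# Menden-Deuer & Lessard power laws for the microalgae, the Putt & Stoecker
# linear ciliate law, and the Loferer-Kroessbacher bacterial dry-weight law
# with C = 0.5 * DW.
_LAW_CRY = AllometricLaw(0.216, 0.939)
_LAW_NAV = AllometricLaw(0.288, 0.811)
_LAW_CILIATE = AllometricLaw(0.14, 1.0)
_LAW_BACTERIA = AllometricLaw(0.435, 0.86, multiplier_m=0.5)

#: Maximum ingestion rates (prey cells per ciliate per day) per consumer and
#: prey, as measured in saturating single-prey bottle incubations.
STUDY_IMAX_CELLS: dict[str, dict[str, float]] = {
    "Col1": {"Cry": 17.6, "Nav": 38.8},
    "Col2": {"Cry": 18.6, "Nav": 12.1},
    "Col3": {"Cry": 17.0, "Nav": 35.1},
    "Eup": {"Cry": 116.0},
}


def study_profiles() -> dict[str, TaxonProfile]:
    """Trait profiles of the study organisms.

    Ciliate detection limits reflect a 2-ml counting subsample (1 cell ->
    0.5 cells/ml); algal limits reflect the respective counting volumes.
    """
    return {
        "Cry": TaxonProfile("Cry", 664.0, _LAW_CRY, detection_limit_abundance=3.3),
        "Nav": TaxonProfile("Nav", 100.0, _LAW_NAV, detection_limit_abundance=10.0),
        "Coleps": TaxonProfile("Coleps", 9850.0, _LAW_CILIATE, detection_limit_abundance=0.5),
        "Eup": TaxonProfile("Eup", 26890.0, _LAW_CILIATE, detection_limit_abundance=0.5),
        "Bacteria": TaxonProfile("Bacteria", 0.05, _LAW_BACTERIA),
    }


def format_factor(profile: TaxonProfile, sig: int = 2) -> float:
    """Conversion factor pg C/um^3 rounded to ``sig`` significant figures."""
    return round_sig(profile.carbon_density, sig)


# ---------------------------------------------------------------------------
# Trait-table I/O
# ---------------------------------------------------------------------------

_TRAIT_COLUMNS = ["taxon", "volume_um3", "law_a", "law_b", "law_m", "detection_limit_per_ml"]


def read_trait_table(path) -> dict[str, TaxonProfile]:
    """Read taxon profiles from a trait CSV.

    Required columns: taxon, volume_um3, law_a, law_b; optional: law_m
    (default 1), detection_limit_per_ml.
    """
    df = pd.read_csv(path)
    missing = {"taxon", "volume_um3", "law_a", "law_b"} - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    profiles: dict[str, TaxonProfile] = {}
    for row in df.itertuples(index=False):
        law = AllometricLaw(
            float(row.law_a),
            float(row.law_b),
            float(getattr(row, "law_m", 1.0)) if not pd.isna(getattr(row, "law_m", 1.0)) else 1.0,
        )
        limit = getattr(row, "detection_limit_per_ml", None)
        limit = None if limit is None or pd.isna(limit) else float(limit)
        profiles[str(row.taxon)] = TaxonProfile(
            str(row.taxon), float(row.volume_um3), law, detection_limit_abundance=limit
        )
    return profiles


def write_trait_table(profiles: Mapping[str, TaxonProfile], path) -> None:
    """Write taxon profiles to the trait CSV schema of :func:`read_trait_table`."""
    rows = [
        {
            "taxon": p.name,
            "volume_um3": p.mean_cell_volume,
            "law_a": p.law.coefficient_a,
            "law_b": p.law.exponent_b,
            "law_m": p.law.multiplier_m,
            "detection_limit_per_ml": p.detection_limit_abundance,
        }
        for p in profiles.values()
    ]
    pd.DataFrame(rows, columns=_TRAIT_COLUMNS).to_csv(path, index=False)


def default_trait_table_path():
    """Path to the bundled trait-table fixture for the study organisms."""
    return resources.files("chemocomp.data").joinpath("study_traits.csv")
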