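"""Shared I/O plumbing: tidy series tables, configs, manifests, pipeline.

The interchange format is UTF-8 CSV with '.' decimal and the tidy schema
(day, treatment, replicate, taxon, abundance_per_ml and/or
biomass_pgc_per_ml, censored); FASTA for sequences, YAML for configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allometry import TaxonProfile, abundance_to_carbon, read_trait_table
from .popmetrics import BiomassSeries, DetectionPolicy, apply_detection_policy

__all__ = ["RunConfig", "read_series", "write_series", "series_from_frame", "run_pipeline"]

SERIES_KEY = ["day", "treatment", "replicate", "taxon"]
_REQUIRED = {"day", "treatment", "replicate", "taxon"}


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    series_path: Path
    traits_path: Path
    out_dir: Path
    growth_window: tuple[float, float] = (0.0, 5.0)
    seed: int = 0
    exudation_f: float = 0.3
    column_map: dict[str, str] = field(default_factory=dict)
    force: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["series_path"] = Path(raw["series_path"])
        raw["traits_path"] = Path(raw["traits_path"])
        raw["out_dir"] = Path(raw["out_dir"])
        if "growth_window" in raw:
            raw["growth_window"] = tuple(raw["growth_window"])
        return cls(**raw)


def read_series(
    path,
    profiles: dict[str, TaxonProfile] | None = None,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a tidy series CSV.

    Requires columns day, treatment, replicate, taxon, and at least one of
    abundance_per_ml / biomass_pgc_per_ml (``column_map`` renames foreign
    headers first).  When taxon profiles are given, unknown taxa are
    rejected and missing biomass is derived from abundance.  Errors name the
    offending row.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = _REQUIRED - set(df.columns)
    if missing:
        raise ValueError(f"series table missing columns: {sorted(missing)}")
    if "abundance_per_ml" not in df.columns and "biomass_pgc_per_ml" not in df.columns:
        raise ValueError("series table needs abundance_per_ml or biomass_pgc_per_ml")
    if "censored" not in df.columns:
        df["censored"] = False
    df["censored"] = df["censored"].astype(bool)

    if "abundance_per_ml" in df.columns:
        bad = df.index[df["abundance_per_ml"] < 0]
        if len(bad):
            raise ValueError(f"negative abundance at row {bad[0]}")
    for (treatment, replicate, taxon), grp in df.groupby(["treatment", "replicate", "taxon"]):
        days = grp["day"].to_numpy()
        if np.any(np.diff(days) <= 0):
            raise ValueError(
                f"non-monotone days for series ({treatment}, {replicate}, {taxon})"
            )
    if profiles is not None:
        unknown = set(df["taxon"]) - set(profiles)
        unknown -= {t for t in set(df["taxon"]) if t.startswith("Col") and "Coleps" in profiles}
        if unknown:
            raise ValueError(f"unknown taxa not in trait table: {sorted(unknown)}")
        if "biomass_pgc_per_ml" not in df.columns:
            df["biomass_pgc_per_ml"] = [
                abundance_to_carbon(
                    a, profiles["Coleps" if t.startswith("Col") else t]
                )
                for a, t in zip(df["abundance_per_ml"], df["taxon"])
            ]
    return df.sort_values(SERIES_KEY).reset_index(drop=True)


def write_series(df: pd.DataFrame, path) -> None:
    """Write a tidy series table (read/write round-trips losslessly)."""
    df.to_csv(path, index=False)


def series_from_frame(
    df: pd.DataFrame, taxon: str, treatment: str, replicate: str,
    profile: TaxonProfile | None = None,
) -> BiomassSeries:
    """Extract one (taxon, treatment, replicate) series from a tidy table."""
    sel = df[
        (df["taxon"] == taxon)
        & (df["treatment"] == treatment)
        & (df["replicate"] == replicate)
    ].sort_values("day")
    if sel.empty:
        raise ValueError(f"no rows for ({taxon}, {treatment}, {replicate})")
    return BiomassSeries(
        taxon=taxon,
        treatment=treatment,
        replicate=replicate,
        times=sel["day"].to_numpy(float),
        abundance=sel["abundance_per_ml"].to_numpy(float),
        biomass_carbon=(
            sel["biomass_pgc_per_ml"].to_numpy(float)
            if "biomass_pgc_per_ml" in sel.columns
            else None
        ),
        censored=sel["censored"].to_numpy(bool) if "censored" in sel.columns else None,
        profile=profile,
    )


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "series": str(config.series_path),
            "traits": str(config.traits_path),
            "window": list(config.growth_window),
            "seed": config.seed,
            "exudation_f": config.exudation_f,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Convert -> censor -> rates -> log-ratios -> budget, with a manifest.

    Writes rates.csv (per-series net growth rate and filtration rates over
    the growth window), log_ratios.csv, budget.csv (P/B and demand curves
    from final-day stocks) and manifest.json into the output directory.
    Idempotent for fixed inputs; refuses to overwrite unless ``force``.
    """
    from . import budget as bud
    from .allometry import STUDY_IMAX_CELLS, imax_to_carbon
    from .popmetrics import (
        growth_rate_window,
        log_ratio_table,
        population_filtration_rate,
        time_averaged_density,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    targets = {
        name: out / f"{name}.csv" for name in ("rates", "log_ratios", "budget")
    }
    targets["manifest"] = out / "manifest.json"
    if not config.force:
        clash = [p for p in targets.values() if p.exists()]
        if clash:
            raise FileExistsError(f"outputs exist (use force): {clash[0]}")

    def stage(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    profiles = stage("read-traits", read_trait_table, config.traits_path)
    df = stage("read-series", read_series, config.series_path, profiles, config.column_map)

    # censor: substitute below-detection observations per taxon policy
    def censor(frame):
        parts = []
        for taxon, grp in frame.groupby("taxon"):
            key = "Coleps" if taxon.startswith("Col") and taxon not in profiles else taxon
            limit = profiles[key].detection_limit_abundance
            if limit:
                policy = DetectionPolicy.half_limit(limit)
                for (tr, rep), sub in grp.groupby(["treatment", "replicate"]):
                    series = series_from_frame(frame, taxon, tr, rep, profiles[key])
                    parts.append(apply_detection_policy(series, policy).to_frame())
            else:
                parts.append(grp)
        return pd.concat(parts, ignore_index=True).sort_values(SERIES_KEY)

    df = stage("censor", censor, df)

    def rates(frame):
        rows = []
        for (tr, rep, taxon), _ in frame.groupby(["treatment", "replicate", "taxon"]):
            key = "Coleps" if taxon.startswith("Col") and taxon not in profiles else taxon
            series = series_from_frame(frame, taxon, tr, rep, profiles[key])
            lo, hi = config.growth_window
            try:
                r = growth_rate_window(series, config.growth_window)
            except ValueError:
                continue
            row = {"treatment": tr, "replicate": rep, "taxon": taxon, "r_per_day": r}
            imax_cells = STUDY_IMAX_CELLS.get(taxon)
            if imax_cells:
                mask = (series.times >= lo) & (series.times <= hi)
                c1, c2 = series.abundance[mask][0], series.abundance[mask][-1]
                cbar = time_averaged_density(c1, c2)
                for prey, cells in imax_cells.items():
                    ic = imax_to_carbon(cells, profiles[prey])
                    f_rate, log10f = population_filtration_rate(ic, cbar)
                    row[f"F_{prey}_pgC_ml_d"] = f_rate
                    row[f"log10_F_{prey}"] = log10f
                row["lag_phase_flag"] = r < 0
            rows.append(row)
        return pd.DataFrame(rows)

    rates_df = stage("rates", rates, df)
    ratio_df = stage("log-ratios", log_ratio_table, df)

    def budget_curve(frame):
        final_day = frame["day"].max()
        last = frame[frame["day"] == final_day]
        mean_bm = last.groupby("taxon")["biomass_pgc_per_ml"].mean()
        coleps_names = [t for t in mean_bm.index if t.startswith("Col")]
        state = bud.CommunityState(
            algal_biomass_BN=float(mean_bm.get("Nav", 0.0)),
            bacterial_biomass_B=float(mean_bm.get("Bacteria", 2.0e4)),
            euplotes_biomass_BE=float(mean_bm.get("Eup", 0.0)),
        )
        rows = []
        for f in np.arange(0.01, config.exudation_f + 1e-9, 0.01):
            params = bud.BudgetParams(exudation_fraction_f=float(f))
            ea = bud.exudation(bud.required_npp(state, params), float(f))
            pb = bud.bacterial_production(ea, state, params)
            rows.append(
                {
                    "exudation_f": round(float(f), 3),
                    "bacterial_production": pb,
                    "pb_ratio_per_day": bud.pb_ratio(pb, state),
                    "euplotes_max_ingestion": bud.consumer_demand(
                        state, params, "max_ingestion"
                    ),
                    "euplotes_dilution_loss": bud.consumer_demand(
                        state, params, "dilution_loss"
                    ),
                    "coleps_present": ",".join(coleps_names),
                }
            )
        return pd.DataFrame(rows)

    budget_df = stage("budget", budget_curve, df)

    rates_df.to_csv(targets["rates"], index=False)
    ratio_df.to_csv(targets["log_ratios"], index=False)
    budget_df.to_csv(targets["budget"], index=False)
    manifest = {
        "chemocomp_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "inputs": {
            "series": str(config.series_path),
            "traits": str(config.traits_path),
        },
        "outputs": {k: str(v) for k, v in targets.items() if k != "manifest"},
    }
    targets["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return targets
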