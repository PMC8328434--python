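"""Seeded synthetic chemostat-community generator.

Simulates the study system — dissolved nitrogen feeding two microalgae
(Cryptomonas-like and Navicula-like), two ciliate consumers (a Euplotes-like
bacterivore/algivore with an initial lag phase and a Coleps-like algivore),
and exudate-fed bacteria — in a chemostat diluted at 0.1/d, then observes it
the way the laboratory did: sampling every second day over 33 days, with
multiplicative lognormal counting noise and taxon-specific detection limits.

Mechanisms: Monod nitrogen-limited algal growth with a fixed exudation split
(fraction f of gross production released as dissolved organic carbon),
multi-prey type-II grazing whose saturated single-prey intake equals the
configured maximum ingestion rate, DOC-fed bacterial growth, and dilution
loss on every suspended pool.  All carbon fluxes carry nitrogen at the source
pool's fixed N:C quota; quota mismatches at trophic transfers are excreted to
the dissolved pool, so total nitrogen obeys inflow-minus-outflow exactly.

Integration is fixed-step fourth-order Runge-Kutta (default 0.01 d) for
bit-reproducibility across platforms; observation noise is the only
stochastic element and flows from the single configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .allometry import TaxonProfile, study_profiles
from .ingestion import BottleExperiment
from .popmetrics import DetectionPolicy

__all__ = [
    "AlgaTraits",
    "ConsumerTraits",
    "BacteriaTraits",
    "SimConfig",
    "Trajectory",
    "default_config",
    "simulate",
    "observe",
    "nitrogen_balance_error",
    "generate_bottle_experiment",
    "generate_functional_response_bottles",
]

# N:C quotas in umol N per litre per (pg C per ml): 1 pg C/ml = (1e-3/12) umol C/l,
# divided by the molar C:N ratio of the pool.
_UMOLC_PER_PGC_ML = 1e-3 / 12.0


def quota_from_cn(cn_molar: float) -> float:
    """Fixed N:C quota (umol N/l per pg C/ml) from a molar C:N ratio."""
    return _UMOLC_PER_PGC_ML / cn_molar


@dataclass(frozen=True)
class AlgaTraits:
    """Monod growth traits of one alga."""

    name: str
    mu_max: float  # per day
    k_n: float  # umol N per litre
    n_quota: float = quota_from_cn(6.625)  # umol N/l per pg C/ml (Redfield default)


@dataclass(frozen=True)
class ConsumerTraits:
    """Grazing traits of one ciliate consumer.

    ``imax_specific`` maps prey name to the biomass-specific maximum
    ingestion rate (pg C prey per pg C consumer per day), derived from the
    cell-based I_max and the cell carbon of prey and consumer.
    """

    name: str
    imax_specific: dict[str, float]
    half_saturation: float  # pg C prey per ml, on total prey carbon
    growth_efficiency: float = 0.25
    lag_days: float = 0.0
    n_quota: float = quota_from_cn(5.0)
    nav_quality_decline: float = 0.0  # efficiency multiplier on N-starved Navicula


@dataclass(frozen=True)
class BacteriaTraits:
    """DOC-fed bacterial traits."""

    name: str = "Bacteria"
    uptake_max: float = 5.0  # pg C DOC per pg C bacteria per day
    k_doc: float = 5.0e4  # pg C per ml
    growth_efficiency: float = 0.5
    n_quota: float = quota_from_cn(5.0)


@dataclass(frozen=True)
class SimConfig:
    """Chemostat run configuration (defaults emulate the study conditions)."""

    algae: tuple[AlgaTraits, ...]
    consumers: tuple[ConsumerTraits, ...]
    bacteria: BacteriaTraits = field(default_factory=BacteriaTraits)
    dilution: float = 0.1  # per day
    n_inflow: float = 120.0  # umol N per litre
    duration: float = 33.0  # days
    sample_every: float = 2.0  # days
    dt: float = 0.01  # days, fixed RK4 step
    exudation_f: float = 0.1  # fraction of gross primary production
    n_quality_threshold: float = 2.0  # umol N/l below which Navicula quality drops
    initial_algal_biovolume: float = 14.4e6  # um^3 per ml, split equally
    initial_ciliate_biovolume: float = 1.3e6  # um^3 per ml, split equally
    initial_bacteria_carbon: float = 2.0e4  # pg C per ml
    initial_doc: float = 0.0  # pg C per ml
    observation_noise_cv: float = 0.10
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dilution < 0 or self.dt <= 0 or self.duration <= 0:
            raise ValueError("rates must be >= 0 and dt, duration > 0")
        if not 0 <= self.exudation_f < 1:
            raise ValueError(f"require 0 <= exudation_f < 1, got {self.exudation_f}")
        if not 0 <= self.observation_noise_cv:
            raise ValueError("observation_noise_cv must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Dense simulation output: times (days) and per-pool state arrays.

    ``pools`` maps pool name (taxa, 'Bacteria', 'N', 'DOC') to its time
    series; carbon pools in pg C/ml, nitrogen in umol/l.  ``n_bookkeeping``
    co-integrates cumulative nitrogen inflow minus outflow for the mass-
    balance audit.
    """

    times: np.ndarray
    pools: dict[str, np.ndarray]
    n_bookkeeping: np.ndarray
    config: SimConfig


def _specific_imax(
    imax_cells: dict[str, float],
    consumer_profile: TaxonProfile,
    prey_profiles: dict[str, TaxonProfile],
) -> dict[str, float]:
    """Convert cell-based I_max to biomass-specific rates (per day)."""
    cons_c = consumer_profile.carbon_per_cell
    return {
        prey: cells * prey_profiles[prey].carbon_per_cell / cons_c
        for prey, cells in imax_cells.items()
    }


def default_config(
    coleps_clone: str = "Col2",
    *,
    seed: int = 0,
    observation_noise_cv: float = 0.10,
    euplotes_bacterivory: float = 0.5,
    n_replicates: int = 4,
) -> SimConfig:
    """Study-condition configuration for one Euplotes-vs-Coleps treatment.

    ``coleps_clone`` selects the clone's measured I_max pair ('Col1', 'Col2'
    or 'Col3').  ``euplotes_bacterivory`` is the biomass-specific maximum
    bacterial ingestion of Euplotes (pg C per pg C per day); bacteria are an
    auxiliary food the cell-based assays did not quantify.
    """
    from .allometry import STUDY_IMAX_CELLS

    profiles = study_profiles()
    coleps = profiles["Coleps"]
    eup = profiles["Eup"]
    eup_imax = _specific_imax(STUDY_IMAX_CELLS["Eup"], eup, profiles)
    eup_imax["Bacteria"] = euplotes_bacterivory
    clone_imax = _specific_imax(STUDY_IMAX_CELLS[coleps_clone], coleps, profiles)

    # Half-saturations: grazing saturates well below the initial prey stock.
    algae = (
        AlgaTraits("Cry", mu_max=0.9, k_n=2.0),
        AlgaTraits("Nav", mu_max=1.2, k_n=0.8),
    )
    consumers = (
        ConsumerTraits(
            "Eup",
            imax_specific=eup_imax,
            half_saturation=2.0e5,
            lag_days=9.0,
        ),
        ConsumerTraits(
            coleps_clone,
            imax_specific=clone_imax,
            half_saturation=2.0e5,
            nav_quality_decline=0.0,
        ),
    )
    return SimConfig(
        algae=algae,
        consumers=consumers,
        seed=seed,
        observation_noise_cv=observation_noise_cv,
        n_replicates=n_replicates,
    )


def _derivatives(state: np.ndarray, t: float, cfg: SimConfig, layout: dict) -> np.ndarray:
    """Right-hand side of the community ODE (see module docstring)."""
    idx = layout["index"]
    n = max(state[idx["N"]], 0.0)
    doc = max(state[idx["DOC"]], 0.0)
    d = np.zeros_like(state)
    delta = cfg.dilution
    f = cfg.exudation_f

    # Algae: Monod growth on N, exudation split, dilution.
    for alga in cfg.algae:
        a = max(state[idx[alga.name]], 0.0)
        gross = alga.mu_max * n / (alga.k_n + n) * a
        d[idx[alga.name]] += (1.0 - f) * gross - delta * a
        d[idx["DOC"]] += f * gross
        d[idx["N"]] -= alga.n_quota * (1.0 - f) * gross

    # Bacteria: DOC uptake, dilution.
    bac = cfg.bacteria
    b = max(state[idx[bac.name]], 0.0)
    uptake = bac.uptake_max * doc / (bac.k_doc + doc) * b
    bac_growth = bac.growth_efficiency * uptake
    d[idx[bac.name]] += bac_growth - delta * b
    d[idx["DOC"]] -= uptake
    d[idx["N"]] -= bac.n_quota * bac_growth

    # Consumers: multi-prey type II grazing after any lag phase, dilution.
    quotas = layout["quotas"]
    for cons in cfg.consumers:
        bc = max(state[idx[cons.name]], 0.0)
        d[idx[cons.name]] -= delta * bc
        if t < cons.lag_days or bc == 0.0:
            continue
        prey_carbon = {p: max(state[idx[p]], 0.0) for p in cons.imax_specific}
        total_prey = sum(prey_carbon.values())
        growth = 0.0
        n_ingested = 0.0
        for prey, imax in cons.imax_specific.items():
            intake = imax * bc * prey_carbon[prey] / (cons.half_saturation + total_prey)
            eff = cons.growth_efficiency
            if prey == "Nav" and n < cfg.n_quality_threshold:
                eff *= cons.nav_quality_decline
            assimilated = eff * intake
            growth += assimilated
            n_ingested += quotas[prey] * intake
            d[idx[prey]] -= intake
            d[idx["DOC"]] += (1.0 - eff) * intake
        d[idx[cons.name]] += growth
        # quota mismatch excreted to (or, never here, taken from) dissolved N
        d[idx["N"]] += n_ingested - cons.n_quota * growth

    # Dilution on dissolved pools; nitrogen inflow.
    d[idx["N"]] += delta * (cfg.n_inflow - n)
    d[idx["DOC"]] -= delta * doc

    # Bookkeeping: cumulative N inflow - outflow across all N-bearing pools.
    total_n_out = n + sum(
        quotas[name] * max(state[idx[name]], 0.0) for name in layout["carbon_pools"]
    )
    d[idx["_cumN"]] = delta * (cfg.n_inflow - total_n_out)
    return d


def _layout(cfg: SimConfig) -> dict:
    profiles = study_profiles()
    names = [a.name for a in cfg.algae] + [cfg.bacteria.name] + [c.name for c in cfg.consumers]
    index = {name: i for i, name in enumerate(names)}
    index["N"] = len(names)
    index["DOC"] = len(names) + 1
    index["_cumN"] = len(names) + 2
    quotas = {a.name: a.n_quota for a in cfg.algae}
    quotas[cfg.bacteria.name] = cfg.bacteria.n_quota
    quotas.update({c.name: c.n_quota for c in cfg.consumers})
    return {"index": index, "carbon_pools": names, "quotas": quotas, "profiles": profiles}


def _initial_state(cfg: SimConfig, layout: dict) -> np.ndarray:
    idx = layout["index"]
    profiles = layout["profiles"]
    state = np.zeros(len(idx))
    n_algae = len(cfg.algae)
    for alga in cfg.algae:
        dens = profiles[alga.name].carbon_density if alga.name in profiles else 0.14
        state[idx[alga.name]] = cfg.initial_algal_biovolume / n_algae * dens
    n_cons = len(cfg.consumers)
    for cons in cfg.consumers:
        key = "Coleps" if cons.name.startswith("Col") else cons.name
        dens = profiles[key].carbon_density if key in profiles else 0.14
        state[idx[cons.name]] = cfg.initial_ciliate_biovolume / n_cons * dens
    state[idx[cfg.bacteria.name]] = cfg.initial_bacteria_carbon
    state[idx["N"]] = cfg.n_inflow
    state[idx["DOC"]] = cfg.initial_doc
    return state


def simulate(cfg: SimConfig) -> Trajectory:
    """Integrate the community ODE with fixed-step RK4.

    Deterministic for a given config (noise enters only in :func:`observe`).
    Raises on non-finite states with the offending time in the message.
    """
    layout = _layout(cfg)
    state = _initial_state(cfg, layout)
    n_steps = int(round(cfg.duration / cfg.dt))
    times = np.linspace(0.0, n_steps * cfg.dt, n_steps + 1)
    out = np.empty((n_steps + 1, state.size))
    out[0] = state
    dt = cfg.dt
    for i in range(n_steps):
        t = times[i]
        k1 = _derivatives(state, t, cfg, layout)
        k2 = _derivatives(state + 0.5 * dt * k1, t + 0.5 * dt, cfg, layout)
        k3 = _derivatives(state + 0.5 * dt * k2, t + 0.5 * dt, cfg, layout)
        k4 = _derivatives(state + dt * k3, t + dt, cfg, layout)
        state = state + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"non-finite state at t={t + dt:.3f} d")
        # RK4 can undershoot zero by O(dt^5); clip negligibly small negatives
        nc = len(layout["carbon_pools"]) + 2  # carbon pools, N, DOC
        state[:nc] = np.maximum(state[:nc], 0.0)
        out[i + 1] = state
    pools = {
        name: out[:, layout["index"][name]]
        for name in layout["carbon_pools"] + ["N", "DOC"]
    }
    return Trajectory(times, pools, out[:, layout["index"]["_cumN"]], cfg)


def nitrogen_balance_error(traj: Trajectory) -> float:
    """Maximum relative nitrogen mass-balance violation over the run.

    Compares total nitrogen (dissolved plus quota-bound in every carbon
    pool) against its initial value plus the co-integrated cumulative
    inflow-minus-outflow.
    """
    cfg = traj.config
    quotas = {a.name: a.n_quota for a in cfg.algae}
    quotas[cfg.bacteria.name] = cfg.bacteria.n_quota
    quotas.update({c.name: c.n_quota for c in cfg.consumers})
    total = traj.pools["N"].copy()
    for name, q in quotas.items():
        total += q * traj.pools[name]
    expected = total[0] + traj.n_bookkeeping
    return float(np.max(np.abs(total - expected) / np.maximum(np.abs(expected), 1e-30)))


def observe(traj: Trajectory, cfg: SimConfig | None = None) -> pd.DataFrame:
    """Sample the trajectory the way the laboratory did.

    Samples every ``sample_every`` days, multiplies each replicate's count by
    lognormal noise with the configured CV (mean one), converts carbon to
    abundance via the taxon profiles, and censors below-detection
    observations with half the detection limit.  Returns the tidy schema
    (day, treatment, replicate, taxon, abundance_per_ml, biomass_pgc_per_ml,
    censored).
    """
    cfg = cfg or traj.config
    rng = np.random.default_rng(cfg.seed)
    profiles = study_profiles()
    cv = cfg.observation_noise_cv
    sigma = math.sqrt(math.log1p(cv**2)) if cv > 0 else 0.0
    sample_times = np.arange(0.0, cfg.duration + 1e-9, cfg.sample_every)
    sample_idx = [int(round(t / cfg.dt)) for t in sample_times]
    treatment = "-".join(
        c.name for c in cfg.consumers if c.name.startswith("Col")
    ) or "community"

    taxa = [a.name for a in cfg.algae] + [c.name for c in cfg.consumers]
    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        for taxon in taxa:
            key = "Coleps" if taxon.startswith("Col") else taxon
            profile = profiles[key]
            limit = profile.detection_limit_abundance or 0.0
            policy = DetectionPolicy.half_limit(limit) if limit > 0 else None
            carbon = traj.pools[taxon][sample_idx]
            if sigma > 0:
                noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=carbon.size)
            else:
                noise = np.ones_like(carbon)
            observed_c = carbon * noise
            abundance = observed_c / profile.carbon_per_cell
            for t, a in zip(sample_times, abundance):
                censored = policy is not None and a < policy.detection_limit
                if censored:
                    a = policy.substitute
                rows.append(
                    {
                        "day": t,
                        "treatment": treatment,
                        "replicate": f"R{rep}",
                        "taxon": taxon,
                        "abundance_per_ml": a,
                        "biomass_pgc_per_ml": a * profile.carbon_per_cell,
                        "censored": censored,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bottle-experiment factories
# ---------------------------------------------------------------------------


def generate_bottle_experiment(
    imax: float,
    k: float,
    grazer_density: float,
    prey0: float,
    duration: float,
    seed: int | None = None,
    *,
    grazer_growth: float = 0.0,
    noise_cv: float = 0.0,
) -> BottleExperiment:
    """Forward-simulate a grazing bottle under the estimators' own assumptions.

    The clearance implied by ``imax`` at the starting prey density
    (F = imax/prey0, ml per grazer per day) is held constant, prey follow
    exponential growth-minus-grazing, and grazers change exponentially at
    ``grazer_growth``.  With ``noise_cv`` = 0 the bottle is analytic, so the
    grazing coefficient and clearance are recoverable to machine precision;
    at saturating ``prey0`` the estimated ingestion approaches ``imax``.
    Counts are multiplied by lognormal noise of the given CV when requested.
    """
    if min(imax, grazer_density, prey0, duration) < 0 or prey0 == 0:
        raise ValueError("imax, grazer_density, duration must be >= 0 and prey0 > 0")
    clearance = imax / prey0
    grazer_end = grazer_density * math.exp(grazer_growth * duration)
    if abs(grazer_growth) > 1e-12:
        mean_grazers = (grazer_end - grazer_density) / (grazer_growth * duration)
    else:
        mean_grazers = grazer_density
    g = clearance * mean_grazers
    control_end = prey0 * math.exp(k * duration)
    grazed_end = prey0 * math.exp((k - g) * duration)
    counts = [prey0, control_end, prey0, grazed_end, grazer_density, grazer_end]
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        counts = [
            c * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma) for c in counts
        ]
    return BottleExperiment(
        prey_control_start=counts[0],
        prey_control_end=counts[1],
        prey_grazed_start=counts[2],
        prey_grazed_end=counts[3],
        grazer_start=counts[4],
        grazer_end=counts[5],
        duration=duration,
    )


def generate_functional_response_bottles(
    imax: float,
    half_saturation: float,
    prey_densities,
    *,
    k: float = 0.0,
    duration: float = 1.0,
    target_depletion: float = 0.5,
    noise_cv: float = 0.0,
    seed: int | None = None,
    dt: float = 0.01,
) -> list[BottleExperiment]:
    """Bottles spanning prey densities, with true type-II grazing dynamics.

    Prey in the grazed bottle follow dC/dt = k*C - imax*C/(K+C)*N with
    grazers held constant; the experiment design sets each bottle's grazer
    density so the expected grazing signal g*T is ~``target_depletion``
    (weakly grazed bottles carry no information about I_max).  Counting
    noise (lognormal, ``noise_cv``) applies to all six counts.
    """
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    bottles = []
    for c0 in prey_densities:
        clearance0 = imax / (half_saturation + c0)
        grazers = target_depletion / (clearance0 * duration)
        c = float(c0)
        n_steps = int(round(duration / dt))
        for _ in range(n_steps):

            def rhs(x):
                return k * x - imax * x / (half_saturation + x) * grazers

            k1 = rhs(c)
            k2 = rhs(c + 0.5 * dt * k1)
            k3 = rhs(c + 0.5 * dt * k2)
            k4 = rhs(c + dt * k3)
            c += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        counts = [c0, c0 * math.exp(k * duration), c0, c, grazers, grazers]
        if sigma > 0:
            counts = [
                x * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma) for x in counts
            ]
        bottles.append(
            BottleExperiment(
                prey_control_start=counts[0],
                prey_control_end=counts[1],
                prey_grazed_start=counts[2],
                prey_grazed_end=counts[3],
                grazer_start=counts[4],
                grazer_end=counts[5],
                duration=duration,
            )
        )
    return bottles
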