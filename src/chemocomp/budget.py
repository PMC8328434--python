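"""Microbial-loop carbon budget at chemostat equilibrium.

Algae release a fraction ``f`` of gross primary production as exudates,
E_A = f/(1-f) * NPP.  Bacteria convert the available carbon into production
with growth efficiency e_B; ciliates consuming bacteria excrete a fraction
(1 - e_C) back into the dissolved pool, which bacteria consume again.  At
equilibrium the recurrent production-consumption-excretion cycle sums to

    P_B = e_B * (E_A - D) / (1 - e_B * (1 - e_C)),    D = delta * B,

equivalently the limit of the geometric series implemented by
:func:`bacterial_production_iterative`.  The module also provides bacterial
P/B ratios, the consumer-side demand terms (maximum ingestion and dilution
loss of Euplotes), and the critical exudation fraction at which bacterial
production meets a given demand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BudgetParams",
    "CommunityState",
    "required_npp",
    "exudation",
    "bacterial_production",
    "bacterial_production_iterative",
    "pb_ratio",
    "consumer_demand",
    "critical_exudation",
]


@dataclass(frozen=True)
class BudgetParams:
    """Efficiencies and rates entering the carbon budget.

    Defaults: bacterial growth efficiency e_B = 0.5, ciliate assimilation
    efficiency e_C = 0.5, dilution 0.1/d, consumer (Euplotes) growth
    efficiency 25% with maximum growth rate 0.4/d.
    """

    exudation_fraction_f: float = 0.3  # fraction of GPP, upper limit used in the study
    bacterial_growth_efficiency_eB: float = 0.5
    ciliate_assimilation_efficiency_eC: float = 0.5
    dilution_delta: float = 0.1  # per day
    consumer_growth_efficiency: float = 0.25
    consumer_max_growth: float = 0.4  # per day

    def __post_init__(self) -> None:
        if not 0 <= self.exudation_fraction_f < 1:
            raise ValueError(f"require 0 <= f < 1, got {self.exudation_fraction_f}")
        if not 0 < self.bacterial_growth_efficiency_eB <= 1:
            raise ValueError(f"require 0 < e_B <= 1, got {self.bacterial_growth_efficiency_eB}")
        if not 0 <= self.ciliate_assimilation_efficiency_eC <= 1:
            raise ValueError(f"require 0 <= e_C <= 1, got {self.ciliate_assimilation_efficiency_eC}")
        if self.recycling_factor >= 1:
            raise ValueError(
                f"divergent recycling loop: e_B*(1-e_C) = {self.recycling_factor} >= 1"
            )
        if self.dilution_delta < 0:
            raise ValueError(f"dilution must be >= 0, got {self.dilution_delta}")
        if not 0 < self.consumer_growth_efficiency <= 1:
            raise ValueError("consumer_growth_efficiency must be in (0, 1]")
        if self.consumer_max_growth < 0:
            raise ValueError("consumer_max_growth must be >= 0")

    @property
    def recycling_factor(self) -> float:
        """Carbon returned per unit bacterial production: e_B * (1 - e_C)."""
        return self.bacterial_growth_efficiency_eB * (
            1.0 - self.ciliate_assimilation_efficiency_eC
        )


@dataclass(frozen=True)
class CommunityState:
    """Standing stocks (pg C/ml) entering the budget."""

    algal_biomass_BN: float  # dominant alga (Navicula)
    bacterial_biomass_B: float
    euplotes_biomass_BE: float

    def __post_init__(self) -> None:
        for name in ("algal_biomass_BN", "bacterial_biomass_B", "euplotes_biomass_BE"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def required_npp(state: CommunityState, params: BudgetParams) -> float:
    """NPP (pg C/ml/d) the dominant alga needs to balance dilution: delta*B_N."""
    return params.dilution_delta * state.algal_biomass_BN


def exudation(npp: float, f: float) -> float:
    """Exudate flux E_A = f/(1-f) * NPP for exudation fraction f of GPP."""
    if not 0 <= f < 1:
        raise ValueError(f"require 0 <= f < 1, got {f}")
    if npp < 0:
        raise ValueError(f"NPP must be >= 0, got {npp}")
    return f / (1.0 - f) * npp


def bacterial_production(ea: float, state: CommunityState, params: BudgetParams) -> float:
    """Equilibrium bacterial production (closed form).

    P_B = e_B*(E_A - D)/(1 - e_B*(1 - e_C)) with dilution loss D = delta*B.
    Negative when exudation does not cover the dilution loss of the standing
    bacterial stock; returned unclamped so the relation stays invertible.
    """
    d = params.dilution_delta * state.bacterial_biomass_B
    return params.bacterial_growth_efficiency_eB * (ea - d) / (1.0 - params.recycling_factor)


def bacterial_production_iterative(
    ea: float, state: CommunityState, params: BudgetParams, n_iter: int
) -> float:
    """Bacterial production as a truncated recycling series.

    Iterates P(n+1) = e_B*(E_A - D) + e_B*(1-e_C)*P(n) from
    P(0) = e_B*(E_A - D); equals the partial geometric sum with ratio
    e_B*(1-e_C) and converges to the closed form.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    d = params.dilution_delta * state.bacterial_biomass_B
    base = params.bacterial_growth_efficiency_eB * (ea - d)
    pb = base
    for _ in range(n_iter):
        pb = base + params.recycling_factor * pb
    return pb


def pb_ratio(pb: float, state: CommunityState) -> float:
    """Bacterial production-to-biomass ratio P/B (per day)."""
    if state.bacterial_biomass_B <= 0:
        raise ValueError("P/B undefined for zero bacterial biomass")
    return pb / state.bacterial_biomass_B


def consumer_demand(state: CommunityState, params: BudgetParams, kind: str) -> float:
    """Consumer-side carbon flux (pg C/ml/d) for the Euplotes stock.

    kinds:
      - ``max_ingestion``: ingestion sustaining maximal growth,
        (mu_max / GE) * B_E (1.6 * B_E at defaults);
      - ``dilution_loss``: washout of the standing stock, delta * B_E;
      - ``dilution_compensating_ingestion``: ingestion that just offsets
        washout, delta * B_E / GE.
    """
    be = state.euplotes_biomass_BE
    if kind == "max_ingestion":
        return params.consumer_max_growth / params.consumer_growth_efficiency * be
    if kind == "dilution_loss":
        return params.dilution_delta * be
    if kind == "dilution_compensating_ingestion":
        return params.dilution_delta / params.consumer_growth_efficiency * be
    raise ValueError(f"unknown demand kind {kind!r}")


def critical_exudation(
    target_flux: float, state: CommunityState, params: BudgetParams
) -> float | None:
    """Exudation fraction f* at which bacterial production equals a demand.

    Closed-form inversion: E_A* = D + target*(1 - e_B(1-e_C))/e_B, then
    f* = E_A*/(NPP + E_A*) using the dilution-compensating NPP of the
    dominant alga.  Returns None when no admissible f in [0, 1) exists
    (negative required exudation).
    """
    if target_flux < 0:
        raise ValueError("target flux must be >= 0")
    npp = required_npp(state, params)
    if npp <= 0:
        raise ValueError("critical exudation undefined without positive required NPP")
    d = params.dilution_delta * state.bacterial_biomass_B
    ea_star = d + target_flux * (1.0 - params.recycling_factor) / params.bacterial_growth_efficiency_eB
    if ea_star < 0:
        return None
    f_star = ea_star / (npp + ea_star)
    return f_star if f_star < 1 else None


def growth_rate_from_pb(pb_over_b: float) -> float:
    """Diagnostic specific growth rate ln(1 + P/B) for a daily P/B ratio."""
    if pb_over_b <= -1:
        raise ValueError("P/B must exceed -1")
    return math.log1p(pb_over_b)
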