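"""Minimal dynamic carbon pools: leaves and living sapwood.

A deliberately reduced two-pool carbon scheme drives the dynamic-vegetation
experiments: realised GPP becomes NPP through a fixed autotrophic-respiration
fraction, NPP is allocated to the leaf and sapwood pools, and each pool
turns over at a first-order rate. The fractional recruitment (lambda) and
turnover (mu) rates feed the damage cohorts, and LAI follows leaf carbon
through the specific leaf area. Fine roots, reserves, fruits, heartwood and
phenology are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

__all__ = ["CarbonPools", "step_carbon", "lai_from_leaf_carbon", "TurnoverRates"]


@dataclass(frozen=True)
class CarbonPools:
    """Leaf and sapwood carbon state plus allocation/turnover parameters."""

    Cleaf: float = 0.12  # kg C m-2
    Csap: float = 2.0  # kg C m-2
    SLA: float = 25.0  # specific leaf area [m2 (kg C)-1]
    alloc_leaf: float = 0.35
    alloc_sap: float = 0.35
    d_leaf: float = 1.0 / 120.0  # leaf turnover [day-1]
    d_sap: float = 1.0 / (5.0 * 365.0)  # sapwood turnover [day-1]
    resp_frac: float = 0.5  # autotrophic respiration fraction of GPP

    def __post_init__(self):
        if self.Cleaf < 0 or self.Csap < 0:
            raise ValueError("carbon pools must be non-negative")
        if self.alloc_leaf + self.alloc_sap > 1.0 + 1e-12:
            raise ValueError("allocation fractions must sum to <= 1")
        if min(self.alloc_leaf, self.alloc_sap, self.d_leaf, self.d_sap) < 0:
            raise ValueError("allocation and turnover rates must be non-negative")


class TurnoverRates(NamedTuple):
    """Fractional recruitment/turnover rates [fraction of pool per day]."""

    lam_leaf: float
    mu_leaf: float
    lam_sap: float
    mu_sap: float


def step_carbon(pools: CarbonPools, gpp_kgc_day: float, dt_days: float = 1.0):
    """Advance the pools by ``dt_days`` given daily GPP [kg C m-2 day-1].

    Explicit Euler on dC/dt = alloc * NPP - d * C with NPP = (1 - resp_frac)
    GPP. Returns ``(new_pools, TurnoverRates)`` where the rates are the
    fractional growth and loss of each pool over the step, the currency the
    damage cohorts consume.
    """
    if gpp_kgc_day < 0:
        raise ValueError("GPP must be non-negative")
    npp = (1.0 - pools.resp_frac) * gpp_kgc_day
    grow_leaf = pools.alloc_leaf * npp * dt_days
    grow_sap = pools.alloc_sap * npp * dt_days
    loss_leaf = pools.d_leaf * pools.Cleaf * dt_days
    loss_sap = pools.d_sap * pools.Csap * dt_days
    new = replace(
        pools,
        Cleaf=max(pools.Cleaf + grow_leaf - loss_leaf, 0.0),
        Csap=max(pools.Csap + grow_sap - loss_sap, 0.0),
    )
    rates = TurnoverRates(
        lam_leaf=grow_leaf / pools.Cleaf / dt_days if pools.Cleaf > 0 else 0.0,
        mu_leaf=pools.d_leaf,
        lam_sap=grow_sap / pools.Csap / dt_days if pools.Csap > 0 else 0.0,
        mu_sap=pools.d_sap,
    )
    return new, rates


def lai_from_leaf_carbon(pools: CarbonPools) -> float:
    """LAI = SLA * Cleaf [m2 m-2]."""
    return pools.SLA * pools.Cleaf
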