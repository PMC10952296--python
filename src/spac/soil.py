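"""Layered bucket soil-water balance.

The column is a stack of layers, each with a volumetric water content, a
thickness and a fine-root fraction. It supplies the plant with a root-weighted
soil water potential psi_s (the retention curve applied to the root-weighted
water content), the unsaturated hydraulic conductivity, and the soil-to-root
conductance

    kr = cf * ks(psi_s) * 2 * pi * Rl / ln(rc / rr)

with Rl the root length index [m root m-2 ground], rc the radius of the soil
cylinder each root can access, rr the root radius, and cf = 1e6 / (rho * g)
converting head per metre into flux per MPa so that kr comes out in
m s-1 MPa-1.

Retention and unsaturated conductivity default to van Genuchten-Mualem, with
Clapp-Hornberger (Brooks-Corey style power laws) as an alternative dialect.
Potentials are negative MPa throughout.

The water-balance step is a simple explicit bucket: infiltration fills layers
top-down to saturation, root uptake is removed per layer, and gravity
percolation at the layer's unsaturated conductivity cascades downwards with
free drainage (unit gradient) at the base. Richards dynamics, soil
evaporation and freeze-thaw are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import M_HEAD_PER_MPA

__all__ = [
    "VanGenuchten",
    "ClappHornberger",
    "SoilLayer",
    "SoilColumn",
    "retention_psi",
    "unsat_conductivity",
    "theta_from_psi",
    "root_weighted_psi",
    "soil_root_conductance",
    "step_soil_water",
    "total_water",
]


@dataclass(frozen=True)
class VanGenuchten:
    """van Genuchten retention with Mualem conductivity.

    ``alpha`` is in 1/m of hydraulic head; ``ks_sat`` in m s-1.
    """

    theta_r: float = 0.05
    theta_s: float = 0.45
    alpha: float = 2.0
    n: float = 1.6
    ks_sat: float = 5.0e-6
    l_pore: float = 0.5

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n

    def psi(self, theta):
        se = self._se(theta)
        se = np.clip(se, 1e-12, 1.0)
        head = np.where(
            se >= 1.0, 0.0, ((se ** (-1.0 / self.m) - 1.0) ** (1.0 / self.n)) / self.alpha
        )
        return -head / M_HEAD_PER_MPA

    def k(self, theta):
        se = np.clip(self._se(theta), 1e-12, 1.0)
        term = (1.0 - (1.0 - se ** (1.0 / self.m)) ** self.m) ** 2
        return self.ks_sat * se**self.l_pore * term

    def _se(self, theta):
        return (np.asarray(theta, dtype=float) - self.theta_r) / (self.theta_s - self.theta_r)


@dataclass(frozen=True)
class ClappHornberger:
    """Clapp-Hornberger power-law retention/conductivity.

    ``psi_sat`` is the (negative) air-entry head in m; ``b`` the shape exponent.
    """

    theta_r: float = 0.0
    theta_s: float = 0.45
    psi_sat: float = -0.3
    b: float = 5.0
    ks_sat: float = 5.0e-6

    def psi(self, theta):
        se = np.clip(
            (np.asarray(theta, dtype=float) - self.theta_r) / (self.theta_s - self.theta_r),
            1e-12,
            1.0,
        )
        head = -self.psi_sat * se ** (-self.b)
        return -head / M_HEAD_PER_MPA

    def k(self, theta):
        se = np.clip(
            (np.asarray(theta, dtype=float) - self.theta_r) / (self.theta_s - self.theta_r),
            1e-12,
            1.0,
        )
        return self.ks_sat * se ** (2.0 * self.b + 3.0)


RETENTION_MODELS = {"van_genuchten": VanGenuchten, "clapp_hornberger": ClappHornberger}


@dataclass(frozen=True)
class SoilLayer:
    theta: float  # volumetric water content [m3 m-3]
    depth: float  # thickness [m]
    w: float  # fine-root fraction [0-1]


@dataclass(frozen=True)
class SoilColumn:
    layers: tuple[SoilLayer, ...]
    retention: VanGenuchten | ClappHornberger = field(default_factory=VanGenuchten)
    Rl: float = 5000.0  # root length index [m m-2]
    rc: float = 0.05  # soil cylinder radius [m]
    rr: float = 5.0e-4  # root radius [m]

    def __post_init__(self):
        if self.rc <= self.rr or self.rr <= 0:
            raise ValueError("require rc > rr > 0")
        if self.Rl <= 0:
            raise ValueError("require Rl > 0")
        wsum = sum(l.w for l in self.layers)
        if abs(wsum - 1.0) > 1e-8:
            raise ValueError(f"root fractions must sum to 1, got {wsum}")

    @property
    def theta(self) -> np.ndarray:
        return np.array([l.theta for l in self.layers])

    @property
    def depths(self) -> np.ndarray:
        return np.array([l.depth for l in self.layers])

    @property
    def root_w(self) -> np.ndarray:
        return np.array([l.w for l in self.layers])

    def with_theta(self, theta: Sequence[float]) -> "SoilColumn":
        layers = tuple(replace(l, theta=float(t)) for l, t in zip(self.layers, theta))
        return replace(self, layers=layers)


def retention_psi(theta, retention) -> float:
    """Soil water potential [MPa, <= 0] from water content via the retention curve.

    Contents outside [theta_r, theta_s] are clamped to the physical range.
    """
    lo = retention.theta_r + 1e-12
    theta_c = np.clip(theta, lo, retention.theta_s)
    out = retention.psi(theta_c)
    return float(out) if np.ndim(theta) == 0 else out


def theta_from_psi(psi: float, retention) -> float:
    """Invert the retention curve (scalar, bisection on theta)."""
    if psi >= 0:
        return retention.theta_s
    lo, hi = retention.theta_r + 1e-12, retention.theta_s
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if float(retention.psi(mid)) < psi:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def unsat_conductivity(theta, retention) -> float:
    """Unsaturated hydraulic conductivity ks(theta) [m s-1]."""
    lo = retention.theta_r + 1e-12
    theta_c = np.clip(theta, lo, retention.theta_s)
    out = retention.k(theta_c)
    return float(out) if np.ndim(theta) == 0 else out


def root_weighted_psi(column: SoilColumn) -> float:
    """psi_s = P(sum_i w_i * theta_i): retention applied to root-weighted content."""
    theta_bar = float(np.dot(column.root_w, column.theta))
    return retention_psi(theta_bar, column.retention)


def root_weighted_psi_per_layer(column: SoilColumn) -> float:
    """Alternative reading: root-weighted average of per-layer potentials."""
    psis = retention_psi(column.theta, column.retention)
    return float(np.dot(column.root_w, psis))


def soil_root_conductance(column: SoilColumn, psi_s: float | None = None) -> float:
    """Soil-to-root conductance kr [m s-1 MPa-1] (Hoelttae-style root cylinder).

    kr = cf * ks(psi_s) * 2*pi*Rl / ln(rc/rr) with cf = 1e6/(rho*g) so that a
    potential difference in MPa drives a flux in m s-1. Evaluated at the
    root-weighted water content unless psi_s is supplied.
    """
    if psi_s is None:
        theta_eval = float(np.dot(column.root_w, column.theta))
    else:
        theta_eval = theta_from_psi(psi_s, column.retention)
    ks = unsat_conductivity(theta_eval, column.retention)
    geom = 2.0 * math.pi * column.Rl / math.log(column.rc / column.rr)
    return M_HEAD_PER_MPA * ks * geom


def total_water(column: SoilColumn) -> float:
    """Column water storage [m]."""
    return float(np.dot(column.theta, column.depths))


def step_soil_water(
    column: SoilColumn,
    uptake: Sequence[float] | float,
    precip_mm_h: float,
    dt: float,
):
    """Advance the bucket water balance by ``dt`` seconds.

    ``uptake`` is either a per-layer flux [m s-1] or a total flux distributed
    by root fractions. Negative uptake (hydraulic redistribution into the
    soil) is rejected. Returns ``(new_column, diagnostics)`` where the
    diagnostics dict carries infiltration, drainage, actual uptake and the
    mass-balance residual [m].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ret = column.retention
    theta = column.theta.copy()
    depths = column.depths
    if np.ndim(uptake) == 0:
        uptake_l = float(uptake) * column.root_w
    else:
        uptake_l = np.asarray(uptake, dtype=float)
    if np.any(uptake_l < -1e-18):
        raise ValueError("negative uptake (soil-direction backflow) is not allowed")

    w0 = float(np.dot(theta, depths))

    # root uptake, limited by available water per layer
    actual_uptake = 0.0
    for i in range(len(theta)):
        demand = uptake_l[i] * dt
        avail = max((theta[i] - ret.theta_r) * depths[i], 0.0)
        take = min(demand, avail)
        theta[i] -= take / depths[i]
        actual_uptake += take

    # gravity percolation (unit gradient) at the antecedent wetness, cascading
    # down with free drainage at the base
    drainage = 0.0
    for i in range(len(theta)):
        flux = min(
            float(unsat_conductivity(theta[i], ret)) * dt,
            max((theta[i] - ret.theta_r) * depths[i], 0.0),
        )
        theta[i] -= flux / depths[i]
        if i + 1 < len(theta):
            cap = (ret.theta_s - theta[i + 1]) * depths[i + 1]
            into = min(flux, cap)
            theta[i + 1] += into / depths[i + 1]
            drainage += flux - into  # bypass flow if the layer below is full
        else:
            drainage += flux

    # top-down infiltration fill last, so a soil-saturating storm leaves the
    # column saturated at the end of the step (drains from the next step on)
    infil = precip_mm_h / 1000.0 / 3600.0 * dt  # m over the step
    for i in range(len(theta)):
        cap = (ret.theta_s - theta[i]) * depths[i]
        add = min(infil, cap)
        theta[i] += add / depths[i]
        infil -= add
    runoff = infil  # saturation excess leaves the column

    w1 = float(np.dot(theta, depths))
    precip_total = precip_mm_h / 1000.0 / 3600.0 * dt
    residual = w1 - w0 - (precip_total - runoff - actual_uptake - drainage)
    diag = {
        "infiltration": precip_total - runoff,
        "runoff": runoff,
        "uptake": actual_uptake,
        "drainage": drainage,
        "balance_residual": residual,
    }
    return column.with_theta(theta), diag


def saturate(column: SoilColumn) -> SoilColumn:
    """Reset all layers to saturation (intense rainfall event)."""
    return column.with_theta([column.retention.theta_s] * len(column.layers))
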