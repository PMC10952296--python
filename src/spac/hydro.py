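"""Plant hydraulics core: vulnerability curves, the steady-state two-node
solve and the capacitance ODE system.

Two computational nodes represent the plant: trunk/stem xylem (potential
psi_x, conductance kx) and a lumped leaf (psi_l, kl). Water moves from soil
to xylem and xylem to leaf across conductances that are geometric means of
the node conductances evaluated at the unknown potentials:

    J_s->x = sqrt(kr * kx(psi_x)) * (psi_s - psi_x)
    J_x->l = sqrt(kx(psi_x) * kl(psi_l)) * (psi_x - psi_l)

The steady-state variant finds (psi_x, psi_l) such that both fluxes equal
the transpiration demand T(psi_s, psi_l, M), where T follows the Tuzet-style
stomatal model with the down-regulation factor fl(psi_s - psi_l). A Powell
hybrid root solve is the primary method; when its flux-conservation residual
exceeds 1% of T, a constrained multistart minimisation (trust-region
interior point, default 100 seeded random starts) takes over, subject to
psi_s >= psi_x >= psi_l.

The capacitance variant instead integrates

    dVx/dt = J_s->x - J_x->l        dVl/dt = J_x->l - T

with linear pressure-volume curves psi = c (1 - V/Vmax), an adaptive
embedded Runge-Kutta(2,3) pair, and a clamp J_s->x >= 0 (water may not move
from the xylem back into the soil; leaf-to-xylem backflow is allowed).
Gravitational potential is neglected throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import LinearConstraint, minimize, root

from .constants import PAR_FRACTION, RHO_W, UMOL_PER_J_PAR
from .forcing import ForcingRecord
from .gasx import (
    GasExchangeParams,
    GasSolution,
    fl_factor,
    fs_factor,
    solve_ci,
    transp_flux,
)

__all__ = [
    "PlantTraits",
    "HydraulicState",
    "xylem_vuln",
    "leaf_vuln",
    "conductance_scaling",
    "storage_capacities",
    "pv_psi",
    "pv_volume",
    "solve_steady",
    "rhs_capacitance",
    "step_capacitance",
    "SteadyResult",
]


@dataclass(frozen=True)
class PlantTraits:
    """Hydraulic, vulnerability, storage and structural traits of one canopy."""

    kxmax: float = 1.2e-7  # max xylem conductance [m s-1 MPa-1]
    qx: float = math.log(2.0) / 9.0  # xylem vulnerability coef (P50 = 3 MPa)
    px: float = 2.0
    klmax: float = 2.4e-7  # max leaf conductance [m s-1 MPa-1]
    ql: float = math.log(2.0) / 6.25  # leaf vulnerability coef (P50 = 2.5 MPa)
    pl: float = 2.0
    h: float = 25.0  # plant height [m]
    Ax: float = 2.5e-3  # xylem cross-section per ground area [m2 m-2]
    nx: float = 0.4  # xylem water-holding capacity [-]
    LMA: float = 0.12  # leaf mass per area [kg m-2]
    LDMC: float = 0.35  # leaf dry-matter content [g g-1]
    cx: float = -12.0  # xylem potential at zero storage [MPa]
    cl: float = -6.0  # leaf potential at zero storage [MPa]
    LAI: float = 3.0  # leaf area index [m2 m-2]

    def __post_init__(self):
        if self.kxmax <= 0 or self.klmax <= 0:
            raise ValueError("maximum conductances must be positive")
        if self.cx >= 0 or self.cl >= 0:
            raise ValueError("cx and cl are potentials at zero storage, < 0")
        if not 0.0 < self.LDMC < 1.0:
            raise ValueError("LDMC must lie in (0, 1)")
        if not 0.0 < self.nx <= 1.0:
            raise ValueError("nx must lie in (0, 1]")


@dataclass
class HydraulicState:
    """Instantaneous plant water state (storages only meaningful for HC)."""

    psix: float
    psil: float
    Vx: float = 0.0
    Vl: float = 0.0


def xylem_vuln(psix: float, traits: PlantTraits) -> float:
    """kx = kxmax * exp(-qx |psi_x|^px); potentials above 0 clamp to kxmax."""
    return traits.kxmax * math.exp(-traits.qx * abs(min(psix, 0.0)) ** traits.px)


def leaf_vuln(psil: float, traits: PlantTraits) -> float:
    """kl = klmax * exp(-ql |psi_l|^pl)."""
    return traits.klmax * math.exp(-traits.ql * abs(min(psil, 0.0)) ** traits.pl)


def conductance_scaling(kx_tissue: float, h: float, ax: float) -> float:
    """Tissue conductivity [kg m-1 s-1 MPa-1] -> whole-plant kxmax [m s-1 MPa-1].

    kxmax = k'x * Ax / (h * rho): conductivity over path length h, scaled by
    the sapwood area per ground area and converted from mass to volume flux.
    """
    if h <= 0 or ax <= 0:
        raise ValueError("height and xylem area must be positive")
    return kx_tissue * ax / (h * RHO_W)


def storage_capacities(traits: PlantTraits, lai: float | None = None):
    """(Vxmax, Vlmax) in m of water per unit ground area.

    Vxmax = h * Ax * nx; Vlmax = LAI * LMA * ((1 - LDMC)/LDMC) / rho.
    """
    if lai is None:
        lai = traits.LAI
    vxmax = traits.h * traits.Ax * traits.nx
    vlmax = lai * traits.LMA * ((1.0 - traits.LDMC) / traits.LDMC) / RHO_W
    return vxmax, vlmax


def pv_psi(v: float, vmax: float, c: float) -> float:
    """Linear pressure-volume curve psi = c (1 - V/Vmax); psi(Vmax)=0, psi(0)=c."""
    if vmax <= 0:
        raise ValueError("Vmax must be positive (leafless state handled upstream)")
    return c * (1.0 - v / vmax)


def pv_volume(psi: float, vmax: float, c: float) -> float:
    """Inverse of :func:`pv_psi`."""
    if vmax <= 0:
        raise ValueError("Vmax must be positive")
    return vmax * (1.0 - psi / c)


# ---------------------------------------------------------------------------
# demand side shared by both variants

_PAR_CONV = PAR_FRACTION * UMOL_PER_J_PAR


def _transpiration(
    psis: float,
    psil: float,
    rec: ForcingRecord,
    gp: GasExchangeParams,
    lai: float,
    stomata: str,
    fs: float,
):
    """Demand-side closure T(psi_s, psi_l, M) -> (T [m s-1], fl, GasSolution)."""
    if stomata == "tuzet":
        fl = fl_factor(psis, psil, gp.al, gp.gl)
    elif stomata in ("tuzet_no_fs", "tuzet_light_only"):
        fl = math.exp(-gp.as_ * abs(min(psil, 0.0)) ** gp.gs_)
    else:
        raise ValueError(f"hydraulic variants need a Tuzet-style model, got {stomata!r}")
    par = _PAR_CONV * rec.SWdown
    gas = solve_ci(rec.Ta, par, rec.D, rec.ca, gp, model=stomata, fs=fs, fl=fl)
    t = transp_flux(gas.gs, rec.D, rec.Patm, lai)
    return t, fl, gas


def _nested_steady(psis, kr, kxf, klf, demand, depth=8.0, n_scan=64):
    """Deterministic steady solve by nesting the flux-continuity condition.

    For a candidate psi_l, flux continuity J_s->x = J_x->l has a root in
    psi_x on [psi_l, psi_s] (bisection, 48 iterations); the outer residual
    supply(psi_l) - T(psi_l) changes sign exactly once on the scan when a
    solution exists. Returns ``((psi_x, psi_l), feasible)`` where
    ``feasible`` is False when the maximum supply never reaches the demand
    floor (the steady system has no root; the best compromise is returned).
    """

    def psix_of(psil):
        lo, hi = psil, psis  # g(lo) >= 0, g(hi) <= 0
        for _ in range(48):
            mid = 0.5 * (lo + hi)
            kx = kxf(mid)
            g = math.sqrt(max(kr * kx, 0.0)) * (psis - mid) - math.sqrt(
                max(kx * klf(psil), 0.0)
            ) * (mid - psil)
            if g > 0.0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def gap(psil):
        psix = psix_of(psil)
        supply = math.sqrt(max(kxf(psix) * klf(psil), 0.0)) * (psix - psil)
        return supply - demand(psil)[0], psix

    grid = np.linspace(psis, psis - depth, n_scan)
    prev_g, _ = gap(grid[0])
    best = (-math.inf, grid[0])
    bracket = None
    for psil in grid[1:]:
        g, _ = gap(psil)
        if g >= 0.0 and prev_g < 0.0:
            bracket = (psil, psil + depth / (n_scan - 1))
            break
        if g > best[0]:
            best = (g, psil)
        prev_g = g
    if bracket is None:
        psil = best[1]  # infeasible: demand floor above maximum supply
        return (psix_of(psil), psil), False
    lo, hi = bracket  # gap(lo) >= 0, gap(hi) < 0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        g, _ = gap(mid)
        if g >= 0.0:
            lo = mid
        else:
            hi = mid
    psil = 0.5 * (lo + hi)
    return (psix_of(psil), psil), True


class SteadyResult(NamedTuple):
    psix: float
    psil: float
    T: float
    jsx: float
    jxl: float
    kx: float
    kl: float
    fl: float
    gas: GasSolution
    method: str  # 'equilibrium' | 'hybr' | 'multistart' | 'failed'
    residual: float


def solve_steady(
    psis: float,
    rec: ForcingRecord,
    traits: PlantTraits,
    gp: GasExchangeParams,
    kr: float,
    stomata: str = "tuzet",
    lai: float | None = None,
    kx_fun: Callable[[float], float] | None = None,
    kl_fun: Callable[[float], float] | None = None,
    x0: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
    n_starts: int = 100,
    rel_tol: float = 0.01,
) -> SteadyResult:
    """Steady-state two-node solve for (psi_x, psi_l) given soil potential.

    ``kx_fun``/``kl_fun`` override the default vulnerability curves (used by
    the damage variants). The solution satisfies J_s->x = J_x->l = T to
    within ``rel_tol`` of T; otherwise the seeded constrained multistart
    fallback refines it.
    """
    if lai is None:
        lai = traits.LAI
    kxf = kx_fun if kx_fun is not None else (lambda p: xylem_vuln(p, traits))
    klf = kl_fun if kl_fun is not None else (lambda p: leaf_vuln(p, traits))
    fs = fs_factor(psis, gp.fs_p, gp.fs_q)

    def demand(psil: float):
        return _transpiration(psis, psil, rec, gp, lai, stomata, fs)

    # zero-demand equilibrium (dark with g0 = 0, or no leaf area)
    t_eq, fl_eq, gas_eq = demand(psis)
    if t_eq <= 1.0e-18 or lai <= 0.0:
        k_eq = kxf(psis)
        return SteadyResult(
            psis, psis, 0.0, 0.0, 0.0, k_eq, klf(psis), fl_eq, gas_eq, "equilibrium", 0.0
        )

    def residuals(x):
        psix, psil = x
        t, _, _ = demand(psil)
        ksx = math.sqrt(max(kr * kxf(psix), 0.0))
        kxl = math.sqrt(max(kxf(psix) * klf(psil), 0.0))
        return ksx * (psis - psix) - t, kxl * (psix - psil) - t

    def assess(x):
        r1, r2 = residuals(x)
        t, fl, gas = demand(x[1])
        resid = max(abs(r1), abs(r2))
        return resid, t, fl, gas

    if x0 is None:
        x0 = (psis - 0.05, psis - 0.10)
    sol = root(residuals, np.array(x0, dtype=float), method="hybr")
    x_best = np.minimum(sol.x, 0.0)
    resid, t, fl, gas = assess(x_best)
    method = "hybr"

    def better(cand):
        nonlocal x_best, resid, t, fl, gas
        r_c, t_c, fl_c, gas_c = assess(cand)
        if r_c < resid:
            x_best, resid, t, fl, gas = np.asarray(cand, float), r_c, t_c, fl_c, gas_c
        return r_c <= rel_tol * max(t_c, 1.0e-15)

    if resid > rel_tol * max(t, 1.0e-15):
        # deterministic refine: nested bisection along psi_l with flux
        # continuity solved exactly for psi_x at each candidate
        cand, feasible = _nested_steady(psis, kr, kxf, klf, demand)
        converged = better(cand)
        method = "nested"
        if not converged and feasible:
            # constrained multistart fallback (interior-point family);
            # skipped when the residual-conductance demand floor provably
            # exceeds the maximum hydraulic supply (no root exists)
            if rng is None:
                rng = np.random.default_rng(0)
            lo = psis - 8.0
            lin = LinearConstraint(
                [[1.0, 0.0], [-1.0, 1.0]], [-np.inf, -np.inf], [psis, 0.0]
            )

            def objective(x):
                r1, r2 = residuals(x)
                return r1 * r1 + r2 * r2

            starts = [np.array(x0), x_best.copy()]
            while len(starts) < n_starts:
                psil_s = rng.uniform(lo, psis)
                psix_s = rng.uniform(psil_s, psis)
                starts.append(np.array([psix_s, psil_s]))
            for s in starts:
                try:
                    res = minimize(
                        objective,
                        s,
                        method="trust-constr",
                        constraints=[lin],
                        options={"gtol": 1e-14, "xtol": 1e-12, "maxiter": 200},
                    )
                except Exception:
                    continue
                if better(np.minimum(res.x, 0.0)):
                    break
            method = "multistart"
        if resid > rel_tol * max(t, 1.0e-15):
            method = "failed"

    psix, psil = float(x_best[0]), float(x_best[1])
    kx = kxf(psix)
    kl = klf(psil)
    jsx = math.sqrt(max(kr * kx, 0.0)) * (psis - psix)
    jxl = math.sqrt(max(kx * kl, 0.0)) * (psix - psil)
    return SteadyResult(psix, psil, t, jsx, jxl, kx, kl, fl, gas, method, resid)


# ---------------------------------------------------------------------------
# capacitance variant


def rhs_capacitance(
    vx: float,
    vl: float,
    psis: float,
    rec: ForcingRecord,
    traits: PlantTraits,
    gp: GasExchangeParams,
    kr: float,
    stomata: str = "tuzet",
    lai: float | None = None,
    kx_fun: Callable[[float], float] | None = None,
    kl_fun: Callable[[float], float] | None = None,
    vxmax: float | None = None,
    vlmax: float | None = None,
):
    """Right-hand side of the storage ODEs.

    Returns ``(dVx/dt, dVl/dt, jsx, jxl, T, an_ground, psix, psil)``.
    J_s->x is clamped at zero from below (no xylem-to-soil water movement);
    J_x->l is bidirectional so leaves can refill overnight. Transpiration is
    smoothly throttled as the leaf store approaches empty (numerical
    desiccation guard).
    """
    if lai is None:
        lai = traits.LAI
    if vxmax is None or vlmax is None:
        vxmax_d, vlmax_d = storage_capacities(traits, lai)
        vxmax = vxmax if vxmax is not None else vxmax_d
        vlmax = vlmax if vlmax is not None else vlmax_d
    kxf = kx_fun if kx_fun is not None else (lambda p: xylem_vuln(p, traits))
    klf = kl_fun if kl_fun is not None else (lambda p: leaf_vuln(p, traits))

    psix = pv_psi(min(vx, vxmax), vxmax, traits.cx)
    psil = pv_psi(min(vl, vlmax), vlmax, traits.cl)
    fs = fs_factor(psis, gp.fs_p, gp.fs_q)
    t, fl, gas = _transpiration(psis, psil, rec, gp, lai, stomata, fs)
    # desiccation guard: throttle demand as the leaf store empties
    guard = min(max(vl / (0.05 * vlmax), 0.0), 1.0)
    t *= guard
    kx = kxf(psix)
    jsx = max(math.sqrt(max(kr * kx, 0.0)) * (psis - psix), 0.0)
    jxl = math.sqrt(max(kx * klf(psil), 0.0)) * (psix - psil)
    an_ground = gas.an * lai * guard
    return jsx - jxl, jxl - t, jsx, jxl, t, an_ground, psix, psil


class CapacitanceStep(NamedTuple):
    Vx: float
    Vl: float
    psix: float
    psil: float
    T_mean: float  # m s-1, hour average
    jsx_mean: float
    an_mean: float  # umol CO2 m-2 ground s-1, hour average
    psix_min: float
    psil_min: float
    balance_residual: float  # |dVx+dVl - integral(jsx - T)| over the step [m]
    nfev: int


def step_capacitance(
    state: HydraulicState,
    psis: float,
    rec: ForcingRecord,
    traits: PlantTraits,
    gp: GasExchangeParams,
    kr: float,
    dt: float = 3600.0,
    stomata: str = "tuzet",
    lai: float | None = None,
    kx_fun: Callable[[float], float] | None = None,
    kl_fun: Callable[[float], float] | None = None,
    method: str = "LSODA",
    rtol: float = 1e-6,
    atol: float = 1e-12,
    n_samples: int = 13,
) -> CapacitanceStep:
    """Integrate the storage ODEs over one coupling interval.

    The state vector is augmented with the cumulative soil-uptake,
    transpiration and assimilation integrals; because Runge-Kutta steps are
    linear in the right-hand side, dVx + dVl - (cumJ_s->x - cumT) is
    conserved to round-off, which is what the returned balance residual
    measures. Storage bounds are respected intrinsically: at V = Vmax the
    potential is zero and inflow reverses, at V -> 0 demand is throttled.
    """
    if lai is None:
        lai = traits.LAI
    vxmax, vlmax = storage_capacities(traits, lai)

    def rhs(t_, y):
        dvx, dvl, jsx, _, tr, an, _, _ = rhs_capacitance(
            y[0], y[1], psis, rec, traits, gp, kr, stomata, lai, kx_fun, kl_fun, vxmax, vlmax
        )
        return [dvx, dvl, jsx, tr, an]

    y0 = [state.Vx, state.Vl, 0.0, 0.0, 0.0]
    t_eval = np.linspace(0.0, dt, n_samples)
    sol = solve_ivp(rhs, (0.0, dt), y0, method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise RuntimeError(f"capacitance integration failed: {sol.message}; y0={y0}")
    vx_t, vl_t = sol.y[0], sol.y[1]
    vx1, vl1 = float(vx_t[-1]), float(vl_t[-1])
    cum_jsx, cum_t, cum_an = (float(sol.y[i][-1]) for i in (2, 3, 4))
    balance = abs((vx1 - state.Vx) + (vl1 - state.Vl) - (cum_jsx - cum_t))
    psix_t = np.array([pv_psi(min(v, vxmax), vxmax, traits.cx) for v in vx_t])
    psil_t = np.array([pv_psi(min(v, vlmax), vlmax, traits.cl) for v in vl_t])
    return CapacitanceStep(
        Vx=vx1,
        Vl=vl1,
        psix=float(psix_t[-1]),
        psil=float(psil_t[-1]),
        T_mean=cum_t / dt,
        jsx_mean=cum_jsx / dt,
        an_mean=cum_an / dt,
        psix_min=float(psix_t.min()),
        psil_min=float(psil_t.min()),
        balance_residual=balance,
        nfev=int(sol.nfev),
    )
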