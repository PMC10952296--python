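"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities from first principles (closed forms,
sorted-array statistics, exhaustive grid searches) without going through the
code paths they are meant to check.
"""

from __future__ import annotations

import math

import numpy as np

from spac.forcing import ForcingRecord, vpd_from_rh
from spac.gasx import GasExchangeParams, fl_factor, fs_factor, solve_ci, transp_flux
from spac.hydro import PlantTraits


def brute_percentile(values, q: float) -> float:
    """Sorted-array linear-interpolation percentile (matches the 'linear' rule)."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = (len(v) - 1) * q
    lo = int(math.floor(pos))
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return float(v[lo] * (1.0 - frac) + v[hi] * frac)


def random_steady_case(rng: np.random.Generator):
    """A randomized but physically sensible forcing/trait/soil case."""
    ta = rng.uniform(15.0, 35.0)
    rh = rng.uniform(0.2, 0.7)
    rec = ForcingRecord(
        Ta=ta,
        RH=rh,
        SWdown=rng.uniform(200.0, 1000.0),
        Patm=101325.0,
        wind=2.0,
        precip=0.0,
        ca=400.0,
        D=vpd_from_rh(ta, rh),
    )
    traits = PlantTraits(
        kxmax=rng.uniform(0.5, 3.0) * 1e-7,
        qx=math.log(2.0) / rng.uniform(4.0, 16.0),
        px=2.0,
        klmax=rng.uniform(1.0, 4.0) * 1e-7,
        ql=math.log(2.0) / rng.uniform(3.0, 10.0),
        pl=2.0,
        LAI=rng.uniform(1.5, 5.0),
    )
    gp = GasExchangeParams(Vcmax25=rng.uniform(40.0, 90.0))
    psis = rng.uniform(-0.8, -0.01)
    kr = 10.0 ** rng.uniform(-8.0, -5.0)
    return psis, rec, traits, gp, kr


def grid_steady_oracle(
    psis: float,
    rec: ForcingRecord,
    traits: PlantTraits,
    gp: GasExchangeParams,
    kr: float,
    depth: float = 6.0,
    step: float = 1e-3,
    rel_tol: float = 0.01,
):
    """Exhaustive (psi_x, psi_l) grid search for the steady hydraulic state.

    Minimises |J_s->x - T| + |J_x->l - T| over the full grid at ``step``
    resolution subject to psi_s >= psi_x >= psi_l. Because the system can
    have several roots (the supply curve is non-monotone under strong
    vulnerability), the physically continued branch is selected: the
    shallowest psi_l whose best psi_x brings the residual below
    ``rel_tol * T``. Returns (psi_x, psi_l, T, residual, converged).
    """
    n = int(round(depth / step)) + 1
    grid = psis - np.arange(n) * step  # shared psi_x / psi_l axis

    # demand T(psi_l): recomputed from first principles (fl, ci coupling, flux)
    fs = fs_factor(psis, gp.fs_p, gp.fs_q)
    par = 0.45 * 4.57 * rec.SWdown
    demand = np.empty(n)
    for j, psil in enumerate(grid):
        fl = fl_factor(psis, float(psil), gp.al, gp.gl)
        gas = solve_ci(rec.Ta, par, rec.D, rec.ca, gp, model="tuzet", fs=fs, fl=fl)
        demand[j] = transp_flux(gas.gs, rec.D, rec.Patm, traits.LAI)

    # vulnerability curves, written out directly
    kx_g = traits.kxmax * np.exp(-traits.qx * np.abs(np.minimum(grid, 0.0)) ** traits.px)
    kl_g = traits.klmax * np.exp(-traits.ql * np.abs(np.minimum(grid, 0.0)) ** traits.pl)
    supply_sx = np.sqrt(kr * kx_g) * (psis - grid)  # J_s->x at each psi_x

    col_min = np.full(n, np.inf)
    col_arg = np.zeros(n, dtype=int)
    chunk = 1000
    for s in range(0, n, chunk):
        sl = slice(s, min(s + chunk, n))
        kxl = np.sqrt(np.outer(kx_g, kl_g[sl]))
        r = np.abs(supply_sx[:, None] - demand[None, sl]) + np.abs(
            kxl * (grid[:, None] - grid[None, sl]) - demand[None, sl]
        )
        r[grid[:, None] < grid[None, sl]] = np.inf  # enforce psi_x >= psi_l
        col_min[sl] = r.min(axis=0)
        col_arg[sl] = r.argmin(axis=0)

    ok = col_min <= rel_tol * np.maximum(demand, 1e-15)
    if ok.any():
        j = int(np.argmax(ok))  # shallowest converged psi_l
        converged = True
    else:
        j = int(np.argmin(col_min / np.maximum(demand, 1e-15)))
        converged = False
    i = int(col_arg[j])
    return float(grid[i]), float(grid[j]), float(demand[j]), float(col_min[j]), converged
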