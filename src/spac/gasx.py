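"""Leaf gas exchange: Farquhar C3 photosynthesis, stress factors, stomata.

The module supplies

* the potential (unstressed) net assimilation ``Anpot`` from a Farquhar-type
  C3 model with peaked Arrhenius temperature responses,
* the empirical soil-water stress factor ``fs = exp(-q |psi_s|^p)`` that
  multiplies potential assimilation (realised An = fs * Anpot),
* the hydraulic down-regulation ``fl = exp(-al |psi_s - psi_l|^gl)`` that
  closes stomata as the soil-to-leaf water potential drop grows, with a
  closed-form calibration from two (drop, reduction) anchor points,
* the Leuning stomatal model (VPD-based) and a Tuzet-style family (fl-based,
  with decoupled variants), and
* the An-gs-ci diffusion fixed point and the transpiration flux T ~ gs * D.

Stomatal conductance is denominated as CO2 conductance [mol CO2 m-2 s-1];
water vapour conductance is 1.6 * gs. Leaf temperature is taken equal to air
temperature (no leaf energy balance) and the canopy is a single big leaf
scaled linearly by LAI.

All scalar functions use plain-Python floats deliberately: they sit inside
the innermost loops of the hydraulic solvers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .constants import MW_H2O, R_GAS, RHO_W

__all__ = [
    "GasExchangeParams",
    "fs_factor",
    "fl_factor",
    "calibrate_fl",
    "farquhar_anpot",
    "gs_leuning",
    "gs_tuzet",
    "solve_ci",
    "transp_flux",
    "GasSolution",
]

GS_MODES = ("leuning", "tuzet", "tuzet_no_fs", "tuzet_light_only")

# Arrhenius activation energies [J mol-1] and 25 degC base values
# (standard published C3 kinetic coefficients)
_KC25, _HA_KC = 404.9, 79430.0  # umol mol-1
_KO25, _HA_KO = 278.4, 36380.0  # mmol mol-1
_HA_GAMMA = 37830.0
_HA_VCMAX, _HD_VCMAX, _DS_VCMAX = 65330.0, 200000.0, 640.0
_HA_JMAX, _HD_JMAX, _DS_JMAX = 43540.0, 200000.0, 640.0
_HA_RD = 46390.0
_O2 = 210.0  # mmol mol-1
_ALPHA_J = 0.28  # quantum yield of electron transport [mol e- / mol photons]
_THETA_J = 0.9  # light-response curvature
_TREF = 298.15


@dataclass(frozen=True)
class GasExchangeParams:
    """Photosynthesis, stomatal and stress-factor parameters for one canopy."""

    Vcmax25: float = 60.0  # umol m-2 s-1
    Jmax25: float = 114.0  # umol m-2 s-1
    Rd25: float = 0.9  # umol m-2 s-1
    Gamma25: float = 42.75  # CO2 compensation point at 25 degC [umol mol-1]
    g0: float = 0.01  # residual conductance [mol CO2 m-2 s-1]
    a1: float = 7.0  # stomatal slope [-]
    D0: float = 1500.0  # Leuning VPD sensitivity [Pa]
    # empirical soil stress fs = exp(-q |psi_s|^p)
    fs_q: float = math.log(2.0)
    fs_p: float = 2.0
    # hydraulic down-regulation fl = exp(-al |psi_s - psi_l|^gl);
    # defaults calibrated so a 1.0 (0.2) MPa drop gives a 50% (10%) reduction
    al: float = field(default=math.log(2.0))
    gl: float = field(
        default=math.log(math.log(0.9) / math.log(0.5)) / math.log(0.2)
    )
    # decoupled-variant fl* = exp(-as |psi_l|^gs) parameters
    as_: float = field(default=math.log(2.0))
    gs_: float = field(
        default=math.log(math.log(0.9) / math.log(0.5)) / math.log(0.2)
    )


def fs_factor(psi_s: float, p: float, q: float) -> float:
    """Empirical soil-water stress factor fs = exp(-q |psi_s|^p) in (0, 1]."""
    return math.exp(-q * abs(min(psi_s, 0.0)) ** p)


def fl_factor(psi_s: float, psi_l: float, al: float, gl: float) -> float:
    """Stomatal down-regulation fl = exp(-al |psi_s - psi_l|^gl) in (0, 1]."""
    drop = abs(psi_s - psi_l)
    if drop == 0.0:
        return 1.0
    return math.exp(-al * drop**gl)


def calibrate_fl(anchor1: tuple[float, float], anchor2: tuple[float, float]):
    """Closed-form (al, gl) from two (potential drop [MPa], reduction) anchors.

    Solves exp(-al d^gl) = 1 - r at both anchors:
    gl = ln(ln(1-r1)/ln(1-r2)) / ln(d1/d2), al = -ln(1-r1)/d1^gl.
    Anchors must be monotone-consistent (larger drop, larger reduction).
    """
    (d1, r1), (d2, r2) = anchor1, anchor2
    if d1 == d2:
        raise ValueError("anchors need distinct potential drops")
    for r in (r1, r2):
        if not 0.0 < r < 1.0:
            raise ValueError("anchor reductions must lie in (0, 1)")
    if (d1 - d2) * (r1 - r2) <= 0:
        raise ValueError("inconsistent anchors: reduction must grow with the drop")
    gl = math.log(math.log(1.0 - r1) / math.log(1.0 - r2)) / math.log(d1 / d2)
    al = -math.log(1.0 - r1) / d1**gl
    return al, gl


def _arrhenius(k25: float, ha: float, tk: float) -> float:
    return k25 * math.exp(ha * (tk - _TREF) / (_TREF * R_GAS * tk))


def _peaked(k25: float, ha: float, hd: float, ds: float, tk: float) -> float:
    num = 1.0 + math.exp((_TREF * ds - hd) / (_TREF * R_GAS))
    den = 1.0 + math.exp((tk * ds - hd) / (tk * R_GAS))
    return _arrhenius(k25, ha, tk) * num / den


class LeafKinetics(NamedTuple):
    """Temperature- and light-dependent quantities, fixed during a ci solve."""

    vcmax: float
    j: float
    rd: float
    gamma: float
    kco: float  # Kc * (1 + O/Ko)


def leaf_kinetics(ta: float, par: float, p: GasExchangeParams) -> LeafKinetics:
    """Evaluate the temperature and light responses once per (Ta, PAR)."""
    tk = ta + 273.15
    vcmax = _peaked(p.Vcmax25, _HA_VCMAX, _HD_VCMAX, _DS_VCMAX, tk)
    jmax = _peaked(p.Jmax25, _HA_JMAX, _HD_JMAX, _DS_JMAX, tk)
    rd = _arrhenius(p.Rd25, _HA_RD, tk)
    gamma = _arrhenius(p.Gamma25, _HA_GAMMA, tk)
    kc = _arrhenius(_KC25, _HA_KC, tk)
    ko = _arrhenius(_KO25, _HA_KO, tk)
    # non-rectangular hyperbola light response of electron transport
    i2 = _ALPHA_J * par
    b = i2 + jmax
    j = (b - math.sqrt(max(b * b - 4.0 * _THETA_J * i2 * jmax, 0.0))) / (2.0 * _THETA_J)
    return LeafKinetics(vcmax, j, rd, gamma, kc * (1.0 + _O2 / ko))


def _anpot_from_kin(kin: LeafKinetics, ci: float) -> float:
    ac = kin.vcmax * (ci - kin.gamma) / (ci + kin.kco)
    aj = 0.25 * kin.j * (ci - kin.gamma) / (ci + 2.0 * kin.gamma)
    return min(ac, aj) - kin.rd


def farquhar_anpot(ta: float, par: float, ci: float, params: GasExchangeParams) -> float:
    """Potential net assimilation Anpot = min(Ac, Aj) - Rd [umol CO2 m-2 s-1]."""
    if ci <= 0:
        raise ValueError("ci must be positive")
    return _anpot_from_kin(leaf_kinetics(ta, par, params), ci)


def gs_leuning(
    anpot: float,
    fs: float,
    ci: float,
    gamma: float,
    d: float,
    params: GasExchangeParams,
) -> float:
    """Leuning stomatal conductance gs = g0 + a1 fs Anpot / ((ci-Gamma)(1+D/D0)).

    Floored at g0; the supply term is dropped when ci <= Gamma.
    """
    if ci <= gamma or anpot <= 0.0:
        return params.g0
    gs = params.g0 + params.a1 * fs * anpot / ((ci - gamma) * (1.0 + d / params.D0))
    return max(gs, params.g0)


def gs_tuzet(
    anpot: float,
    fs: float,
    fl: float,
    ci: float,
    gamma: float,
    params: GasExchangeParams,
    mode: str = "tuzet",
) -> float:
    """Tuzet-style stomatal conductance with hydraulic down-regulation fl.

    ``mode``:
      * ``tuzet`` - gs = g0 + a1 (Anpot fs)/(ci - Gamma) * fl
      * ``tuzet_no_fs`` - gs = g0 + a1 Anpot/(ci - Gamma) * fl*  (fl* from |psi_l|)
      * ``tuzet_light_only`` - gs = g0 + a1 Anpot * fl* (no ci coupling)
    The caller supplies the appropriate fl (or fl*) value.
    """
    if mode == "tuzet":
        if ci <= gamma or anpot <= 0.0:
            return params.g0
        gs = params.g0 + params.a1 * anpot * fs / (ci - gamma) * fl
    elif mode == "tuzet_no_fs":
        if ci <= gamma or anpot <= 0.0:
            return params.g0
        gs = params.g0 + params.a1 * anpot / (ci - gamma) * fl
    elif mode == "tuzet_light_only":
        if anpot <= 0.0:
            return params.g0
        gs = params.g0 + params.a1 * 1e-3 * anpot * fl
    else:
        raise ValueError(f"unknown stomatal mode {mode!r}; choose from {GS_MODES}")
    return max(gs, params.g0)


class GasSolution(NamedTuple):
    ci: float  # umol mol-1
    an: float  # realised (stressed) net assimilation [umol m-2 s-1]
    anpot: float  # potential net assimilation at the solved ci
    gs: float  # CO2 stomatal conductance [mol m-2 s-1]


def solve_ci(
    ta: float,
    par: float,
    d: float,
    ca: float,
    params: GasExchangeParams,
    model: str = "leuning",
    fs: float = 1.0,
    fl: float = 1.0,
    tol_iters: int = 48,
) -> GasSolution:
    """Fixed point of the An-gs-ci diffusion coupling.

    Solves fs * Anpot(ci) = gs(Anpot, ci) * (ca - ci) for ci by bisection on a
    bracket that always contains the root (the residual is monotone decreasing
    in ci). Realised assimilation is reported as An = fs * Anpot.
    """
    if ca <= 0:
        raise ValueError("ca must be positive")
    kin = leaf_kinetics(ta, par, params)
    gamma = kin.gamma
    if params.g0 <= 0.0:
        anpot_ca = _anpot_from_kin(kin, ca)
        if anpot_ca <= 0.0:  # closed stomata in the dark: no diffusion, ci pinned at ca
            return GasSolution(ca, fs * anpot_ca, anpot_ca, 0.0)

    def gs_of(ci: float, anpot: float) -> float:
        if model == "leuning":
            return gs_leuning(anpot, fs, ci, gamma, d, params)
        return gs_tuzet(anpot, fs, fl, ci, gamma, params, mode=model)

    def resid(ci: float) -> float:
        anpot = _anpot_from_kin(kin, ci)
        gs = gs_of(ci, anpot)
        return gs * (ca - ci) - fs * anpot

    lo = gamma * 0.2 + 1e-9
    hi = ca
    r_hi = resid(hi)
    # dark / respiring leaf: the root sits above ca (ci enriched by respiration)
    tries = 0
    while r_hi > 0.0 and tries < 60:
        hi += max(50.0, 0.5 * hi)
        r_hi = resid(hi)
        tries += 1
    if resid(lo) < 0.0 or r_hi > 0.0:
        raise RuntimeError(
            f"ci bracket failed (ta={ta}, par={par}, d={d}, ca={ca}, model={model})"
        )
    for _ in range(tol_iters):
        mid = 0.5 * (lo + hi)
        if resid(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    ci = 0.5 * (lo + hi)
    anpot = _anpot_from_kin(kin, ci)
    gs = gs_of(ci, anpot)
    return GasSolution(ci, fs * anpot, anpot, gs)


def transp_flux(gs: float, d: float, patm: float, lai: float) -> float:
    """Canopy transpiration [m s-1 ground] from leaf CO2 conductance.

    T = 1.6 * gs * LAI * (D / Patm) * Mw / rho_w; water conductance is 1.6x
    the CO2 conductance and the big-leaf canopy scales linearly with LAI.
    """
    if patm <= 0:
        raise ValueError("Patm must be positive")
    return 1.6 * gs * lai * (max(d, 0.0) / patm) * MW_H2O / RHO_W
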