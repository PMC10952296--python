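"""Scenario drivers, the hourly simulator loop and flux diagnostics.

Five model variants share one hourly loop:

* ``baseline`` - empirical soil-stress model: Leuning stomata, assimilation
  down-regulated by fs(psi_s) only; no plant water potentials are resolved.
* ``H`` - steady-state two-node plant hydraulics (Tuzet-style stomata with
  the fl down-regulation), no storage.
* ``HC`` - plant water storage (capacitance ODEs) on top of H.
* ``H-d`` / ``HC-d`` - as above with irreversible, cohort-tracked
  conductivity loss.

Experiment E1 is a 250-day precipitation-free dry-down driven by a repeated
percentile day (75th-percentile temperature and radiation, 10th- or
90th-percentile relative humidity) starting from saturated soil with static
vegetation. Experiment E2 dries the system down until the empirical stress
factor reaches fs = 0.2, then applies a soil-saturating rain event and
follows the recovery with dynamic vegetation; the dry-down length is
determined once (from the no-damage run) so every variant sees identical
pre-relief forcing.

Diagnostics include the 90%->50% GPP decline time, pre-drought water-use
efficiency, normalised diurnal composites, Penman-Monteith surface
conductance inversion and 200-Pa VPD binning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import damage as dmg
from . import soil as soilmod
from . import veg as vegmod
from .constants import (
    CP_AIR,
    KGC_PER_UMOLCO2_DAY,
    LAMBDA_VAP,
    PAR_FRACTION,
    SECONDS_PER_HOUR,
    UMOL_PER_J_PAR,
)
from .forcing import (
    ForcingRecord,
    esat_scalar,
    iter_records,
    make_percentile_day,
    repeat_forcing,
    synthetic_archive,
)
from .gasx import GasExchangeParams, fs_factor, solve_ci, transp_flux
from .hydro import (
    HydraulicState,
    PlantTraits,
    leaf_vuln,
    pv_volume,
    solve_steady,
    step_capacitance,
    storage_capacities,
    xylem_vuln,
)

__all__ = [
    "ModelConfig",
    "ExperimentConfig",
    "RunResult",
    "MicrometState",
    "run_simulation",
    "run_e1",
    "run_e2",
    "run_generic",
    "metric_decline_time",
    "metric_wue",
    "diurnal_composite",
    "invert_penman_monteith",
    "forward_penman_monteith",
    "bin_gs_vpd",
]

VARIANTS = ("baseline", "H", "HC", "H-d", "HC-d")

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DamageConfig:
    n_classes_xylem: int = 3650  # daily classes, 10-year sapwood
    n_classes_leaf: int = 365  # daily classes, 1-year leaves
    distribution: str = "exponential"
    suspend_when_dormant: bool = True  # no psimin tracking while leafless


@dataclass(frozen=True)
class ModelConfig:
    """Everything one variant needs to run on a forcing series."""

    variant: str = "H"
    stomata: str | None = None  # default: leuning for baseline, tuzet otherwise
    traits: PlantTraits = field(default_factory=PlantTraits)
    gasx: GasExchangeParams = field(default_factory=GasExchangeParams)
    soil: soilmod.SoilColumn = None  # type: ignore[assignment]
    pools: vegmod.CarbonPools = field(default_factory=vegmod.CarbonPools)
    damage: DamageConfig = field(default_factory=DamageConfig)
    seed: int = 0
    n_starts: int = 100  # multistart fallback budget
    ode_method: str = "LSODA"
    rtol: float = 1e-6
    atol: float = 1e-12
    soil_substeps: int = 1  # soil recoupling intervals per forcing hour
    lai_floor: float = 0.05

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.soil is None:
            object.__setattr__(self, "soil", default_soil_column())
        stom = self.stomata
        if self.variant == "baseline":
            if stom not in (None, "leuning"):
                raise ValueError("the baseline variant uses the Leuning model")
            stom = "leuning"
        elif stom is None:
            stom = "tuzet"
        elif stom == "leuning":
            raise ValueError("hydraulic variants need a Tuzet-style stomatal model")
        object.__setattr__(self, "stomata", stom)

    @property
    def has_capacitance(self) -> bool:
        return self.variant in ("HC", "HC-d")

    @property
    def has_damage(self) -> bool:
        return self.variant in ("H-d", "HC-d")


def default_soil_column() -> soilmod.SoilColumn:
    """Three-layer loam column, saturated, depth-weighted roots."""
    ret = soilmod.VanGenuchten()
    layers = tuple(
        soilmod.SoilLayer(theta=ret.theta_s, depth=d, w=w)
        for d, w in [(0.3, 0.5), (0.3, 0.3), (0.4, 0.2)]
    )
    return soilmod.SoilColumn(layers=layers, retention=ret)


@dataclass
class SimState:
    """Restartable simulator state (valid at a day boundary)."""

    soil: soilmod.SoilColumn
    hyd: HydraulicState
    cohorts_x: dmg.CohortSet | None
    cohorts_l: dmg.CohortSet | None
    pools: vegmod.CarbonPools
    lai: float
    hour: int  # absolute hour index, drives the fallback RNG stream


@dataclass
class RunResult:
    hourly: pd.DataFrame
    daily: pd.DataFrame
    meta: dict
    state: SimState


def _init_state(cfg: ModelConfig, dynamic_veg: bool) -> SimState:
    soil = cfg.soil
    psis0 = soilmod.root_weighted_psi(soil)
    lai = (
        max(vegmod.lai_from_leaf_carbon(cfg.pools), cfg.lai_floor)
        if dynamic_veg
        else cfg.traits.LAI
    )
    vxmax, vlmax = storage_capacities(cfg.traits, lai)
    hyd = HydraulicState(
        psix=psis0,
        psil=psis0,
        Vx=pv_volume(psis0, vxmax, cfg.traits.cx),
        Vl=pv_volume(psis0, vlmax, cfg.traits.cl),
    )
    cx = cl = None
    if cfg.has_damage:
        cx = dmg.init_cohorts(
            cfg.damage.n_classes_xylem, 1.0, cfg.damage.distribution, tissue="xylem"
        )
        cl = dmg.init_cohorts(
            cfg.damage.n_classes_leaf, 1.0, cfg.damage.distribution, tissue="leaf"
        )
    return SimState(soil, hyd, cx, cl, cfg.pools, lai, 0)


def _damage_curves(cfg: ModelConfig, state: SimState):
    t = cfg.traits
    if not cfg.has_damage:
        return None, None
    cx, cl = state.cohorts_x, state.cohorts_l

    def kx_fun(psi):
        return dmg.effective_conductivity_at(cx, psi, t.kxmax, t.qx, t.px)

    def kl_fun(psi):
        return dmg.effective_conductivity_at(cl, psi, t.klmax, t.ql, t.pl)

    return kx_fun, kl_fun


def run_simulation(
    forcing: pd.DataFrame,
    cfg: ModelConfig,
    dynamic_veg: bool = False,
    saturate_at: int | None = None,
    stop_when_fs_below: float | None = None,
    state: SimState | None = None,
) -> RunResult:
    """Drive one model variant over an hourly forcing series.

    ``saturate_at`` resets the soil to saturation at the start of that hour
    (the relief rain event). ``stop_when_fs_below`` ends the run at the end
    of the day in which the empirical stress factor first drops below the
    threshold (the E2 dry-down probe). A ``state`` from a previous call
    continues the run bit-identically (restart safety); it must sit at a day
    boundary.
    """
    if state is None:
        state = _init_state(cfg, dynamic_veg)
    if state.hour % 24 != 0:
        raise ValueError("restart state must be at a day boundary")
    traits, gp = cfg.traits, cfg.gasx
    rows = []
    n_fallback = 0
    stop_hour: int | None = None
    day_gpp: list[float] = []

    for i, rec in enumerate(iter_records(forcing)):
        abs_hour = state.hour + i
        if saturate_at is not None and i == saturate_at:
            state.soil = soilmod.saturate(state.soil)
        psis = soilmod.root_weighted_psi(state.soil)
        kr = soilmod.soil_root_conductance(state.soil)
        fs = fs_factor(psis, gp.fs_p, gp.fs_q)
        lai = state.lai
        kx_fun, kl_fun = _damage_curves(cfg, state)

        if cfg.variant == "baseline":
            par = PAR_FRACTION * UMOL_PER_J_PAR * rec.SWdown
            gas = solve_ci(rec.Ta, par, rec.D, rec.ca, gp, model="leuning", fs=fs)
            t_flux = transp_flux(gas.gs, rec.D, rec.Patm, lai)
            uptake = t_flux
            psix = psil = psis
            fl = 1.0
            kx = kl = math.nan
            gpp = gas.an * lai
            psix_min = psil_min = psis
            method = "empirical"
        elif cfg.has_capacitance:
            step = step_capacitance(
                state.hyd, psis, rec, traits, gp, kr,
                dt=SECONDS_PER_HOUR, stomata=cfg.stomata, lai=lai,
                kx_fun=kx_fun, kl_fun=kl_fun, method=cfg.ode_method,
                rtol=cfg.rtol, atol=cfg.atol,
            )
            state.hyd = HydraulicState(step.psix, step.psil, step.Vx, step.Vl)
            psix, psil = step.psix, step.psil
            t_flux = step.T_mean
            uptake = step.jsx_mean
            gpp = step.an_mean
            psix_min, psil_min = step.psix_min, step.psil_min
            kxf = kx_fun if kx_fun else (lambda p: xylem_vuln(p, traits))
            klf = kl_fun if kl_fun else (lambda p: leaf_vuln(p, traits))
            kx, kl = kxf(psix), klf(psil)
            fl = math.nan
            gas = None
            method = "ode"
        else:  # steady-state hydraulics
            rng = np.random.default_rng([cfg.seed, abs_hour])
            res = solve_steady(
                psis, rec, traits, gp, kr, stomata=cfg.stomata, lai=lai,
                kx_fun=kx_fun, kl_fun=kl_fun,
                x0=(state.hyd.psix, state.hyd.psil), rng=rng, n_starts=cfg.n_starts,
            )
            if res.method in ("multistart", "failed"):
                n_fallback += 1
                # fallback hours mark the drought-stress regime where the
                # primary solve is unreliable; always on the record
                logger.info(
                    "steady fallback at hour %d (psis=%.3f, method=%s, residual=%.2e)",
                    abs_hour, psis, res.method, res.residual,
                )
            psix, psil = res.psix, res.psil
            state.hyd = HydraulicState(psix, psil, state.hyd.Vx, state.hyd.Vl)
            t_flux = res.T
            uptake = max(res.jsx, 0.0)  # soil sees actual root extraction
            gpp = res.gas.an * lai
            kx, kl, fl = res.kx, res.kl, res.fl
            gas = res.gas
            psix_min, psil_min = psix, psil
            method = res.method

        # irreversible-damage memory (suspended while effectively leafless)
        if cfg.has_damage and not (
            cfg.damage.suspend_when_dormant and lai <= cfg.lai_floor
        ):
            state.cohorts_x = dmg.update_min_potential(state.cohorts_x, min(psix_min, 0.0))
            state.cohorts_l = dmg.update_min_potential(state.cohorts_l, min(psil_min, 0.0))

        # damage bookkeeping for output: memory-only effective conductivity
        if cfg.has_damage:
            kx_eff = dmg.effective_conductivity(state.cohorts_x, traits.kxmax, traits.qx, traits.px)
            kl_eff = dmg.effective_conductivity(state.cohorts_l, traits.klmax, traits.ql, traits.pl)
        else:
            kx_eff, kl_eff = kx, kl

        state.soil, sdiag = soilmod.step_soil_water(
            state.soil, uptake, rec.precip, SECONDS_PER_HOUR
        )
        day_gpp.append(gpp)
        rows.append(
            (
                psis, psix, psil, state.hyd.Vx, state.hyd.Vl, kx, kl, kx_eff, kl_eff,
                kr, fs, fl, gpp, t_flux, uptake, lai,
                gas.gs if gas is not None else math.nan,
                gas.ci if gas is not None else math.nan,
                sdiag["balance_residual"], 1.0 if method in ("multistart", "failed") else 0.0,
            )
        )

        if i % 24 == 23:  # end of day
            gpp_day = float(np.mean(day_gpp))
            day_gpp = []
            if dynamic_veg:
                state.pools, rates = vegmod.step_carbon(
                    state.pools, max(gpp_day, 0.0) * KGC_PER_UMOLCO2_DAY
                )
                new_lai = max(vegmod.lai_from_leaf_carbon(state.pools), cfg.lai_floor)
                if cfg.has_capacitance and new_lai != state.lai:
                    # leaf store tracks leaf area at constant water status
                    _, vlmax_new = storage_capacities(traits, new_lai)
                    state.hyd.Vl = pv_volume(state.hyd.psil, vlmax_new, traits.cl)
                state.lai = new_lai
            else:
                rates = vegmod.TurnoverRates(0.0, 0.0, 0.0, 0.0)
            if cfg.has_damage:
                state.cohorts_x = dmg.advance_cohorts(
                    state.cohorts_x, rates.lam_sap, rates.mu_sap, 1.0
                )
                state.cohorts_l = dmg.advance_cohorts(
                    state.cohorts_l, rates.lam_leaf, rates.mu_leaf, 1.0
                )
            if stop_when_fs_below is not None and fs <= stop_when_fs_below:
                stop_hour = i + 1
                break

    n = len(rows)
    hourly = pd.DataFrame(
        rows,
        columns=[
            "psis", "psix", "psil", "Vx", "Vl", "kx", "kl", "kx_eff", "kl_eff",
            "kr", "fs", "fl", "gpp", "T", "uptake", "lai", "gs", "ci",
            "soil_balance", "fallback",
        ],
    )
    hourly.insert(0, "time", forcing["time"].iloc[:n].to_numpy())
    for col in ("Ta", "RH", "SWdown", "D", "precip"):
        hourly[col] = forcing[col].iloc[:n].to_numpy()
    state.hour += n
    daily = _daily_aggregates(hourly)
    meta = {
        "variant": cfg.variant,
        "stomata": cfg.stomata,
        "n_hours": n,
        "n_fallback": n_fallback,
        "stop_hour": stop_hour,
        "seed": cfg.seed,
    }
    return RunResult(hourly=hourly, daily=daily, meta=meta, state=state)


def _daily_aggregates(hourly: pd.DataFrame) -> pd.DataFrame:
    n_days = len(hourly) // 24
    if n_days == 0:
        return pd.DataFrame()
    h = hourly.iloc[: n_days * 24]
    day = np.repeat(np.arange(n_days), 24)
    g = h.groupby(day)
    out = pd.DataFrame(
        {
            "gpp": g["gpp"].mean(),  # umol CO2 m-2 s-1 daily mean
            "T_mm": g["T"].sum() * SECONDS_PER_HOUR * 1000.0,  # mm day-1
            "psis": g["psis"].mean(),
            "psil_min": g["psil"].min(),
            "fs": g["fs"].mean(),
            "lai": g["lai"].last(),
            "kx_eff": g["kx_eff"].last(),
        }
    )
    out.index.name = "day"
    return out


# ---------------------------------------------------------------------------
# experiments


@dataclass(frozen=True)
class ExperimentConfig:
    """Scenario description for the synthetic experiments."""

    scenario: str = "e1a"  # e1a | e1b | e2a | e2b | generic
    variants: tuple[str, ...] = ("baseline", "H", "HC")
    n_days: int = 250
    post_relief_days: int = 100
    stop_fs: float = 0.2
    max_drydown_days: int = 400
    months: tuple[int, ...] = (6, 7, 8)
    archive_years: int = 3
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)

    @property
    def rh_percentile(self) -> float:
        if self.scenario.endswith("a"):
            return 0.10
        if self.scenario.endswith("b"):
            return 0.90
        raise ValueError(f"scenario {self.scenario!r} has no RH percentile")


def _scenario_day(cfg: ExperimentConfig) -> pd.DataFrame:
    archive = synthetic_archive(n_years=cfg.archive_years, seed=cfg.seed)
    return make_percentile_day(archive, cfg.months, cfg.rh_percentile)


def _variant_cfg(cfg: ExperimentConfig, variant: str) -> ModelConfig:
    return replace(cfg.model, variant=variant, stomata=None, seed=cfg.seed)


def run_e1(cfg: ExperimentConfig) -> dict[str, RunResult]:
    """Dry-down E1: repeated percentile day, static vegetation, saturated start."""
    day = _scenario_day(cfg)
    forcing = repeat_forcing(day, cfg.n_days)
    out = {}
    for variant in cfg.variants:
        out[variant] = run_simulation(forcing, _variant_cfg(cfg, variant), dynamic_veg=False)
    return out


def run_e2(cfg: ExperimentConfig) -> dict[str, RunResult]:
    """Dry-down to fs = stop_fs, saturating rain, >= post_relief_days recovery.

    Dynamic vegetation is on. The relief hour is found once with the
    no-damage capacitance run, then imposed on every requested variant so
    all share identical pre-relief forcing.
    """
    variants = cfg.variants if cfg.variants != ("baseline", "H", "HC") else ("HC", "HC-d")
    day = _scenario_day(cfg)
    probe_forcing = repeat_forcing(day, cfg.max_drydown_days)
    probe_variant = "HC" if any(v.startswith("HC") for v in variants) else "H"
    probe = run_simulation(
        probe_forcing,
        _variant_cfg(cfg, probe_variant),
        dynamic_veg=True,
        stop_when_fs_below=cfg.stop_fs,
    )
    if probe.meta["stop_hour"] is None:
        raise RuntimeError(
            f"fs never reached {cfg.stop_fs} within {cfg.max_drydown_days} days"
        )
    relief_hour = probe.meta["stop_hour"]
    total_days = relief_hour // 24 + cfg.post_relief_days
    forcing = repeat_forcing(day, total_days)
    out = {}
    for variant in variants:
        res = run_simulation(
            forcing, _variant_cfg(cfg, variant), dynamic_veg=True, saturate_at=relief_hour
        )
        res.meta["relief_hour"] = relief_hour
        out[variant] = res
    return out


def run_generic(
    forcing: pd.DataFrame,
    model: ModelConfig,
    dynamic_veg: bool = False,
    state: SimState | None = None,
) -> RunResult:
    """Multiyear run of any variant on supplied forcing (restart-safe)."""
    return run_simulation(forcing, model, dynamic_veg=dynamic_veg, state=state)


# ---------------------------------------------------------------------------
# diagnostics


def metric_decline_time(gpp_daily: Sequence[float], n_init: int = 5) -> float:
    """Days for daily GPP to fall from 90% to 50% of its initial rate.

    The initial rate is the mean of the first ``n_init`` pre-drought days;
    crossing times are linearly interpolated at the first downward crossing.
    Returns NaN (undefined) if the series never reaches 50%.
    """
    g = np.asarray(gpp_daily, dtype=float)
    if len(g) < n_init + 1:
        return math.nan
    g0 = float(g[:n_init].mean())
    if g0 <= 0:
        return math.nan
    t90 = _first_crossing(g, 0.9 * g0)
    t50 = _first_crossing(g, 0.5 * g0)
    if math.isnan(t90) or math.isnan(t50):
        return math.nan
    return t50 - t90


def _first_crossing(g: np.ndarray, level: float) -> float:
    below = np.nonzero(g <= level)[0]
    if below.size == 0:
        return math.nan
    k = int(below[0])
    if k == 0:
        return 0.0
    g1, g2 = g[k - 1], g[k]
    return (k - 1) + (g1 - level) / (g1 - g2)


def metric_wue(
    gpp_daily: Sequence[float],
    transp_daily: Sequence[float],
    window: slice | None = None,
) -> float:
    """Mean daily GPP / transpiration over a window (zero-T days excluded)."""
    g = np.asarray(gpp_daily, dtype=float)
    t = np.asarray(transp_daily, dtype=float)
    if window is not None:
        g, t = g[window], t[window]
    ok = t > 0
    if not ok.any():
        raise ValueError("no days with positive transpiration in window")
    return float(np.mean(g[ok] / t[ok]))


def diurnal_composite(series_hourly: Sequence[float], normalize: bool = False) -> np.ndarray:
    """Per-hour mean over complete days; optionally normalised to max = 1."""
    s = np.asarray(series_hourly, dtype=float)
    n_days = len(s) // 24
    if n_days < 1:
        raise ValueError("need at least one complete day")
    comp = s[: n_days * 24].reshape(n_days, 24).mean(axis=0)
    if normalize:
        m = comp.max()
        if m > 0:
            comp = comp / m
    return comp


@dataclass(frozen=True)
class MicrometState:
    """Micrometeorological bundle for the Penman-Monteith inversion."""

    Rn: float  # net radiation [W m-2]
    G: float = 0.0  # ground heat flux [W m-2]
    Ga: float = 0.05  # aerodynamic conductance [m s-1]
    Ta: float = 20.0  # air temperature [degC]
    Patm: float = 101325.0

    @property
    def gamma(self) -> float:
        # psychrometric constant [Pa K-1]
        return CP_AIR * self.Patm / (0.622 * LAMBDA_VAP)

    @property
    def delta(self) -> float:
        # slope of the saturation vapour pressure curve [Pa K-1]
        eps = 0.1
        return (esat_scalar(self.Ta + eps) - esat_scalar(self.Ta - eps)) / (2 * eps)

    @property
    def rho_air(self) -> float:
        return self.Patm / (287.05 * (self.Ta + 273.15))


def forward_penman_monteith(m: MicrometState, d: float, gs: float) -> float:
    """Latent heat flux [W m-2] for surface conductance ``gs`` [m s-1]."""
    num = m.delta * (m.Rn - m.G) + m.rho_air * CP_AIR * d * m.Ga
    den = m.delta + m.gamma * (1.0 + m.Ga / gs)
    return num / den


def invert_penman_monteith(m: MicrometState, d: float, le: float) -> float:
    """Surface conductance Gs [m s-1] from latent heat flux by PM inversion.

    Gs = gamma * lE * Ga / (Delta (Rn - G) + rho_a cp D Ga - lE (Delta + gamma)).
    Returns NaN when the denominator is non-physical (<= 0).
    """
    if le == 0.0:
        return 0.0
    den = m.delta * (m.Rn - m.G) + m.rho_air * CP_AIR * d * m.Ga - le * (m.delta + m.gamma)
    if den <= 0:
        return math.nan
    return m.gamma * le * m.Ga / den


def bin_gs_vpd(
    gs_series: Sequence[float],
    d_series: Sequence[float],
    bin_width: float = 200.0,
) -> pd.DataFrame:
    """Mean surface conductance in half-open VPD bins [k*w, (k+1)*w)."""
    gs = np.asarray(gs_series, dtype=float)
    d = np.asarray(d_series, dtype=float)
    if gs.shape != d.shape:
        raise ValueError("series must be aligned")
    ok = np.isfinite(gs) & np.isfinite(d)
    idx = np.floor(d[ok] / bin_width).astype(int)
    frame = pd.DataFrame({"bin": idx, "gs": gs[ok]})
    g = frame.groupby("bin")["gs"]
    out = pd.DataFrame(
        {
            "bin_center": (g.mean().index + 0.5) * bin_width,
            "gs_mean": g.mean().to_numpy(),
            "n": g.count().to_numpy(),
        }
    ).reset_index(drop=True)
    return out
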