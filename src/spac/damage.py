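"""Irreversible conductivity loss through age-structured tissue cohorts.

Each conducting tissue (xylem sapwood, leaves) is described by an age
distribution p(alpha) together with the minimum water potential each age
class has experienced. Because embolised conduits do not refill, a cohort's
conductivity is evaluated at its lifetime-minimum potential; the effective
tissue conductivity is the cohort-weighted mean

    k_eff = sum_i p_i * kmax * exp(-q |psimin_i|^p)

Conductivity is only regained by turnover: the oldest (typically most
damaged) cohorts are removed first and new tissue is recruited at age zero
with an undamaged water status ("born full of water"). The age distribution
advects along age with an upwind shift and is renormalised to sum to one
after recruitment/turnover, so p stays a probability density.

Default discretisation is daily age classes, with a 10-year maximum sapwood
age and a 1-year maximum leaf age; the last class is absorbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CohortSet",
    "init_cohorts",
    "update_min_potential",
    "effective_conductivity",
    "effective_conductivity_at",
    "advance_cohorts",
]


@dataclass(frozen=True)
class CohortSet:
    """Age-structured cohort state for one tissue."""

    p: np.ndarray  # per-class density, sums to 1
    psimin: np.ndarray  # per-class minimum experienced potential [MPa, <= 0]
    width_days: float = 1.0  # age-class width
    tissue: str = "xylem"

    def __post_init__(self):
        if self.p.shape != self.psimin.shape:
            raise ValueError("p and psimin must have matching shapes")
        if abs(float(self.p.sum()) - 1.0) > 1e-9:
            raise ValueError("cohort density must sum to 1")
        if np.any(self.psimin > 0.0):
            raise ValueError("psimin must be non-positive")

    @property
    def n_classes(self) -> int:
        return self.p.size

    @property
    def max_age_days(self) -> float:
        return self.n_classes * self.width_days


def init_cohorts(
    n_classes: int,
    width_days: float = 1.0,
    distribution: str = "exponential",
    turnover_per_day: float | None = None,
    tissue: str = "xylem",
) -> CohortSet:
    """Initial cohort state with undamaged water status (psimin = 0).

    ``distribution='uniform'`` gives p_i = 1/n; ``'exponential'`` the
    steady-age distribution implied by a constant turnover rate (truncated
    exponential over the age span), defaulting the rate to 1/max_age.
    """
    if n_classes < 1:
        raise ValueError("need at least one age class")
    if distribution == "uniform":
        p = np.full(n_classes, 1.0 / n_classes)
    elif distribution == "exponential":
        mu = turnover_per_day if turnover_per_day is not None else 1.0 / (n_classes * width_days)
        if mu < 0:
            raise ValueError("turnover rate must be non-negative")
        ages = (np.arange(n_classes) + 0.5) * width_days
        w = np.exp(-mu * ages)
        total = float(w.sum())
        if not math.isfinite(total) or total <= 0:
            raise ValueError("non-normalizable age distribution")
        p = w / total
    else:
        raise ValueError(f"unknown initial distribution {distribution!r}")
    return CohortSet(p=p, psimin=np.zeros(n_classes), width_days=width_days, tissue=tissue)


def update_min_potential(cohorts: CohortSet, psi_now: float) -> CohortSet:
    """Deepen each class's minimum-potential memory with the current potential."""
    if psi_now > 0.0:
        raise ValueError("psi_now must be non-positive")
    if psi_now >= float(cohorts.psimin.max()):
        pass  # still need the elementwise min; cheap either way
    return replace(cohorts, psimin=np.minimum(cohorts.psimin, psi_now))


def effective_conductivity(
    cohorts: CohortSet, kmax: float, q: float, p_shape: float
) -> float:
    """Cohort-weighted conductivity k = sum_i p_i kmax exp(-q |psimin_i|^p)."""
    return float(
        kmax * np.dot(cohorts.p, np.exp(-q * np.abs(cohorts.psimin) ** p_shape))
    )


def effective_conductivity_at(
    cohorts: CohortSet, psi: float, kmax: float, q: float, p_shape: float
) -> float:
    """Damaged vulnerability curve at a candidate potential.

    Each cohort responds to the deeper of the candidate potential and its own
    memory, so the curve tracks the undamaged one at the running minimum and
    never exceeds it. Used inside the hydraulic solvers of the -d variants;
    the memory itself is only committed from realised potentials.
    """
    eff = np.minimum(cohorts.psimin, min(psi, 0.0))
    return float(kmax * np.dot(cohorts.p, np.exp(-q * np.abs(eff) ** p_shape)))


def advance_cohorts(
    cohorts: CohortSet,
    lam: float,
    mu: float,
    dt_days: float,
) -> CohortSet:
    """Age, turn over and recruit cohorts over ``dt_days``.

    ``lam`` is the fractional recruitment rate and ``mu`` the fractional
    turnover rate [fraction of the tissue pool per day]. Aging is an upwind
    shift along the age axis (``dt_days`` must not exceed the class width;
    the oldest class is absorbing). Turnover removes mass oldest-first; new
    tissue enters at age zero undamaged. The density is renormalised, which
    makes the fractional recruitment/turnover rates consistent with a
    probability-density reading of p(alpha).
    """
    if lam < 0 or mu < 0:
        raise ValueError("rates must be non-negative")
    if dt_days > cohorts.width_days + 1e-12:
        raise ValueError("dt must not exceed the age-class width")
    p = cohorts.p.astype(float).copy()
    psimin = cohorts.psimin.copy()
    n = p.size

    # upwind advection along age; oldest class absorbs
    f = dt_days / cohorts.width_days
    if f > 1e-12:
        inflow = f * p[:-1]
        merged_old = p[-1] + inflow[-1] if n > 1 else p[-1]
        if n > 1 and inflow[-1] > 0 and merged_old > 0:
            # mass entering the absorbing class carries its own memory
            psimin[-1] = min(psimin[-1], psimin[-2])
        p[1:] += inflow
        p[:-1] -= inflow
        if f >= 1.0 - 1e-12 and n > 1:
            # pure shift: memories move with their mass
            psimin[1:-1] = cohorts.psimin[0:-2]
            psimin[0] = 0.0

    # oldest-first turnover
    remove = mu * dt_days
    if remove > float(p.sum()) + 1e-12:
        raise ValueError("turnover demand exceeds total tissue mass")
    i = n - 1
    while remove > 1e-16 and i >= 0:
        take = min(remove, p[i])
        p[i] -= take
        remove -= take
        if p[i] <= 1e-16:
            p[i] = 0.0
            psimin[i] = 0.0  # empty class forgets
        i -= 1

    # recruitment at age zero, born full of water
    add = lam * dt_days
    if add > 0:
        p[0] += add
        if p[0] > 0 and add >= p[0] - 1e-16:
            psimin[0] = 0.0
        # mixed young class: keep the (conservative) existing memory for the
        # surviving fraction; with daily steps the young class is newborn mass
    total = float(p.sum())
    if total <= 0:
        raise ValueError("cohort mass vanished")
    return replace(cohorts, p=p / total, psimin=psimin)
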