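"""Radionuclide compartment kinetics and cellular microdosimetry.

The in vitro system is described by five ligand concentrations: the
medium (c_m), the surface and cytoplasm of living cells (c_acs, c_acy)
and the surface and cytoplasm of dead cells (c_dcs, c_dcy).  Ligand
binds to surface receptors, is internalized and released by living
cells, and is carried from the living to the dead compartments at the
instantaneous cell-death rate.  The ligand molecule itself is chemically
stable; radioactive decay enters only through the activity A(t) that
scales the absorbed-dose rate.

The dose rate to living-cell nuclei follows the MIRD cellular S-value
formalism with a medium crossfire term::

    dD/dt = A(t) * [S_m * sum(c) + S_cs * c_acs + S_cy * c_acy]
            / (sum(c) * max(N_alive, 1))

As printed, the population-level gain terms of the surface compartments
do not balance the loss term of the medium equation; by default the
per-cell receptor symbols are read as the population pools
R_alive = r_cell * N_alive and R_dead = r_cell * N_dead, which restores
exact mass conservation.  The literal single-cell reading is available
behind ``literal_receptor_terms``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import KineticParams, ReceptorModel, SValueSet

__all__ = [
    "CompartmentState",
    "DoseState",
    "compartment_rates",
    "dose_rate",
    "activity_at",
    "apply_washout",
    "SECONDS_PER_HOUR",
]

SECONDS_PER_HOUR = 3600.0

# Relative slack for the bound-ligand <= receptor-capacity domain check;
# adaptive integration can overshoot the bound by solver-tolerance amounts.
_OCCUPANCY_SLACK = 1.0e-7


@dataclass
class CompartmentState:
    """Ligand concentrations (nmol/L) in the five compartments."""

    c_m: float = 0.0
    c_acs: float = 0.0
    c_dcs: float = 0.0
    c_acy: float = 0.0
    c_dcy: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.c_m, self.c_acs, self.c_dcs, self.c_acy, self.c_dcy])

    @classmethod
    def from_array(cls, arr) -> "CompartmentState":
        return cls(*(float(x) for x in arr))

    @property
    def total(self) -> float:
        return self.c_m + self.c_acs + self.c_dcs + self.c_acy + self.c_dcy


@dataclass
class DoseState:
    """Activity bookkeeping and cumulative absorbed dose.

    ``a0_bq`` is the activity at the reference time ``t_ref_h``; after a
    washout the pair is rebased to the retained activity at the washout
    time, so A(t) = a0_bq * exp(-mu_dec * (t - t_ref_h)) always holds.
    """

    a0_bq: float
    t_ref_h: float = 0.0
    cumulative_gy: float = 0.0

    def activity(self, t_h: float, mu_dec: float) -> float:
        return self.a0_bq * math.exp(-mu_dec * (t_h - self.t_ref_h))


def compartment_rates(
    state: CompartmentState,
    params: KineticParams,
    receptors: ReceptorModel,
    n_alive: float,
    n_dead: float,
    mu_dea: float,
    *,
    literal_receptor_terms: bool = False,
    validate: bool = True,
) -> np.ndarray:
    """Time derivatives (per hour) of the five compartment concentrations.

    With the population-level receptor pools (default) the five
    derivatives sum to zero: ligand is only moved between compartments.
    """
    c_m, c_acs, c_dcs, c_acy, c_dcy = (
        state.c_m,
        state.c_acs,
        state.c_dcs,
        state.c_acy,
        state.c_dcy,
    )
    r_alive = receptors.r_alive(n_alive)
    r_dead = receptors.r_dead(n_dead)
    if validate:
        vals = (c_m, c_acs, c_dcs, c_acy, c_dcy, n_alive, n_dead, mu_dea)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("compartment state, populations and mu_dea must be finite")
        if any(v < 0.0 for v in vals):
            raise ValueError("compartment state, populations and mu_dea must be >= 0")
        slack = _OCCUPANCY_SLACK * max(receptors.r_cell, r_alive, 1.0)
        if c_acs > r_alive + slack:
            raise ValueError("bound ligand c_acs exceeds living receptor capacity")
        if c_dcs > r_dead + slack:
            raise ValueError("bound ligand c_dcs exceeds dead receptor capacity")

    capacity_alive = receptors.r_cell if literal_receptor_terms else r_alive
    capacity_dead = r_dead  # population pool in both readings

    d_m = params.k_off * (c_acs + c_dcs) - params.k_on * c_m * (r_alive + r_dead - c_acs - c_dcs)
    d_acs = (
        params.k_on * c_m * (capacity_alive - c_acs)
        + params.k_rel * c_acy
        - (params.k_off + params.k_int + mu_dea) * c_acs
    )
    d_dcs = params.k_on * c_m * (capacity_dead - c_dcs) + mu_dea * c_acs - params.k_off * c_dcs
    d_acy = params.k_int * c_acs - (params.k_rel + mu_dea) * c_acy
    d_dcy = mu_dea * c_acy
    return np.array([d_m, d_acs, d_dcs, d_acy, d_dcy])


def dose_rate(
    state: CompartmentState,
    activity_bq: float,
    svals: SValueSet,
    n_alive: float,
) -> float:
    """Absorbed-dose rate to living-cell nuclei, Gy per hour.

    The S values are per decay (Gy/decay) and the activity in Bq
    (decays/s); the medium term is the crossfire contribution.  With no
    ligand anywhere the expression is 0/0 and the dose rate is zero.
    For dosimetry the living-cell count is floored at one.
    """
    if activity_bq < 0.0:
        raise ValueError("activity must be >= 0")
    total = state.total
    if total <= 0.0:
        return 0.0
    n_eff = max(n_alive, 1.0)
    gy_per_s = (
        activity_bq
        * (svals.s_m * total + svals.s_cs * state.c_acs + svals.s_cy * state.c_acy)
        / (total * n_eff)
    )
    return gy_per_s * SECONDS_PER_HOUR


def activity_at(t_h: float, dose_state: DoseState, params: KineticParams) -> float:
    """Activity A(t) = A0 * exp(-mu_dec * t) from the current reference."""
    if t_h < 0.0:
        raise ValueError("time must be >= 0")
    if t_h < dose_state.t_ref_h:
        raise ValueError("time precedes the activity reference (washout) time")
    return dose_state.activity(t_h, params.mu_dec)


def apply_washout(
    state: CompartmentState,
    n_alive: float,
    n_dead: float,
    dose_state: DoseState,
    t_h: float,
    params: KineticParams,
) -> tuple[CompartmentState, float, float, DoseState]:
    """Remove medium and dead cells at the end of radionuclide exposure.

    The washing step removes the medium and excises dead cells, so
    c_m, c_dcs and c_dcy are set to zero, N_dead is reset and the
    remaining activity is the pre-washout activity scaled by the ligand
    fraction retained on and in living cells.

    Returns (state, n_alive, n_dead, dose_state) after the washout.
    """
    if t_h < 0.0:
        raise ValueError("washout before the start of exposure")
    total_pre = state.total
    a_pre = dose_state.activity(t_h, params.mu_dec)
    retained = (state.c_acs + state.c_acy) / total_pre if total_pre > 0.0 else 0.0
    new_state = replace(state, c_m=0.0, c_dcs=0.0, c_dcy=0.0)
    new_dose = DoseState(
        a0_bq=a_pre * retained,
        t_ref_h=t_h,
        cumulative_gy=dose_state.cumulative_gy,
    )
    return new_state, n_alive, 0.0, new_dose
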