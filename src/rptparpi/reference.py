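"""Brute-force reference integrators for verification.

These deliberately naive implementations share the model right-hand
sides with the production engine but replace the adaptive multi-step
solver by fixed-step explicit Euler stepping, providing an independent
integration path for cross-checking endpoint results.  They are orders
of magnitude slower and exist only for validation.
"""

from __future__ import annotations

import math

import numpy as np

from .engine import (
    _enter_phase,
    _make_rhs,
    _pack,
    _subsegments,
    _unpack,
    apply_instantaneous_dose,
    build_phase_schedule,
)
from .kinetics import CompartmentState, DoseState, apply_washout
from .damage import DamageState
from .params import ModelParams, PARPI_NONE, Protocol, SolverOptions

__all__ = ["euler_endpoint_state", "euler_endpoint_survival"]


def euler_endpoint_state(
    start_index: int,
    protocol: Protocol,
    params: ModelParams,
    dt: float = 1.0e-3,
    options: SolverOptions = SolverOptions(),
):
    """Fixed-step explicit-Euler integration of one trajectory.

    Follows the same phase schedule, protocol events and transition
    maps as the production engine, but advances the state with plain
    Euler steps of size ``dt`` hours.  Returns the final
    (survival, n_alive, n_dead, dose_gy).
    """
    cc = params.cellcycle
    endpoint = protocol.endpoint_h
    schedule = build_phase_schedule(cc, start_index, endpoint)
    mu_inter = cc.mu_inter

    n_alive = protocol.n_seeded * math.exp(cc.mu_gr * protocol.seeding_offset_h)
    n_dead = 0.0
    surv = 1.0
    comp = CompartmentState(
        c_m=protocol.c_m0_nmol_per_l if protocol.delivery == "compartment" else 0.0
    )
    dose_state = DoseState(a0_bq=protocol.a0_bq if protocol.delivery == "compartment" else 0.0)
    d_gy = 0.0

    first = schedule[0]
    dmg = DamageState(s_prog=first.s_entry) if first.phase == "S" else DamageState()
    if protocol.ebrt_dose_gy > 0.0:
        dmg = apply_instantaneous_dose(dmg, protocol.ebrt_dose_gy, params, first.phase, mu_inter)
        d_gy += protocol.ebrt_dose_gy

    prev_phase = first.phase
    t_cursor = 0.0
    for seg, t0, t1 in _subsegments(schedule, protocol):
        if seg.phase != prev_phase:
            dmg = _enter_phase(seg.phase, prev_phase, dmg, seg.s_entry,
                               options.carry_full_counts_at_mitosis)
            prev_phase = seg.phase
        parpi = params.parpi if t0 < protocol.parpi_exposure_h - 1.0e-12 else PARPI_NONE
        t0_int = min(t_cursor, t1)
        t1_int = t1
        if seg.phase == "S" and math.isclose(t1, seg.t_end):
            s_end = seg.s_entry + mu_inter * (seg.t_end - seg.t_start)
            if s_end >= 1.0 - options.s_prog_eps:
                t1_int = t1 - options.s_prog_eps / mu_inter
        t_cursor = t1_int
        if t1_int <= t0_int:
            continue
        rhs = _make_rhs(seg.phase, params, parpi, dose_state, protocol, options)
        y = _pack(seg.phase, comp, d_gy, dmg, surv, n_alive, n_dead)
        t = t0_int
        while t < t1_int - 1.0e-12:
            h = min(dt, t1_int - t)
            y = np.maximum(y + h * rhs(t, y), 0.0)
            t += h
        comp, d_gy, dmg, surv, n_alive, n_dead = _unpack(seg.phase, y)
        if math.isclose(t1, protocol.rpt_exposure_h) and t1 < endpoint - 1.0e-12:
            comp, n_alive, n_dead, dose_state = apply_washout(
                comp, n_alive, n_dead, dose_state, t1, params.kinetics
            )
    return surv, n_alive, n_dead, d_gy


def euler_endpoint_survival(
    start_index: int,
    protocol: Protocol,
    params: ModelParams,
    dt: float = 1.0e-3,
    options: SolverOptions = SolverOptions(),
) -> float:
    return euler_endpoint_state(start_index, protocol, params, dt, options)[0]
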