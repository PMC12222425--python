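"""Coupled kinetics--dose--damage--survival--population trajectories.

A single trajectory follows one representative cell that starts the
experiment at a given position in the cell cycle and integrates the
full ODE system piecewise over cell-cycle phase segments and protocol
events (radionuclide washout, end of PARPi exposure, an optional
external-beam impulse at t = 0).  Population growth and death are
carried alongside via the Malthusian equations, and the survival
probability S(t) integrates the instantaneous death rate.

An ensemble averages ``n_starts`` evenly spaced starting positions
(linear interpolation onto a common grid), which represents an
asynchronous cell population; the experimental read-out is the
endpoint number of surviving cells relative to an untreated control
run under the same protocol handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .damage import DamageState, PhaseContext, repair_probabilities
from .kinetics import CompartmentState, DoseState, apply_washout, dose_rate
from .params import PARPI_NONE, CellCycleConfig, ModelParams, PHASES, Protocol, SolverOptions

__all__ = [
    "PhaseSpan",
    "TrajectoryResult",
    "EnsembleResult",
    "EngineError",
    "build_phase_schedule",
    "simulate_trajectory",
    "ensemble_simulate",
    "phase_death_rates",
    "apply_instantaneous_dose",
]


class EngineError(RuntimeError):
    """Raised when integration fails or produces an unphysical state."""


# ----------------------------------------------------------------------
# Phase schedule

@dataclass(frozen=True)
class _Segment:
    phase: str
    t_start: float
    t_end: float
    s_entry: float  # S-phase progression at segment entry (0 unless partial)
    completed: bool  # covers a full phase duration


def build_phase_schedule(
    config: CellCycleConfig, start_index: int, horizon: float
) -> list[_Segment]:
    """Ordered phase segments covering [0, horizon] for one start point.

    Start offsets are evenly spaced: start ``k`` sits k/n_starts of a
    cycle past the beginning of G1.  The first segment is the remainder
    of the phase containing the offset; phases then repeat with
    durations in the configured proportions.
    """
    if not (0 <= start_index < config.n_starts):
        raise ValueError("start_index out of range")
    if horizon <= 0.0:
        raise ValueError("horizon must be > 0")
    durations = config.phase_durations()
    offset = start_index / config.n_starts * config.cycle_length

    # locate the phase containing the offset
    pos = offset
    idx = 0
    while pos >= durations[PHASES[idx]] - 1.0e-12:
        pos -= durations[PHASES[idx]]
        idx = (idx + 1) % 4
    segments: list[_Segment] = []
    t = 0.0
    pos_in_phase = pos
    while t < horizon - 1.0e-12:
        phase = PHASES[idx]
        dur = durations[phase]
        remaining = dur - pos_in_phase
        t_end = min(t + remaining, horizon)
        s_entry = pos_in_phase / dur if phase == "S" else 0.0
        completed = pos_in_phase == 0.0 and t + remaining <= horizon + 1.0e-12
        segments.append(_Segment(phase, t, t_end, s_entry, completed))
        t = t_end
        pos_in_phase = 0.0
        idx = (idx + 1) % 4
    return segments


# ----------------------------------------------------------------------
# State packing: layout depends on the phase.
#   interphase (13): 5 compartments, D, n_ssb, n_f, n_s, n_m, S, N_alive, N_dead
#   S phase   (17): 5 compartments, D, ssb_url, ssb_rl, f_url, f_rl,
#                   s_url, s_rl, m, s_prog, S, N_alive, N_dead

def _pack(phase: str, comp: CompartmentState, d_gy: float, dmg: DamageState,
          surv: float, n_alive: float, n_dead: float) -> np.ndarray:
    head = [comp.c_m, comp.c_acs, comp.c_dcs, comp.c_acy, comp.c_dcy, d_gy]
    if phase == "S":
        body = [dmg.n_ssb_url, dmg.n_ssb_rl, dmg.n_dsb_f_url, dmg.n_dsb_f_rl,
                dmg.n_dsb_s_url, dmg.n_dsb_s_rl, dmg.n_dsb_m, dmg.s_prog]
    else:
        body = [dmg.n_ssb, dmg.n_dsb_f, dmg.n_dsb_s, dmg.n_dsb_m]
    return np.array(head + body + [surv, n_alive, n_dead])


def _unpack(phase: str, y: np.ndarray):
    comp = CompartmentState(*(float(v) for v in y[:5]))
    d_gy = float(y[5])
    if phase == "S":
        dmg = DamageState(
            n_ssb_url=float(y[6]), n_ssb_rl=float(y[7]),
            n_dsb_f_url=float(y[8]), n_dsb_f_rl=float(y[9]),
            n_dsb_s_url=float(y[10]), n_dsb_s_rl=float(y[11]),
            n_dsb_m=float(y[12]), s_prog=float(y[13]),
        )
        tail = y[14:]
    else:
        dmg = DamageState(
            n_ssb=float(y[6]), n_dsb_f=float(y[7]),
            n_dsb_s=float(y[8]), n_dsb_m=float(y[9]),
        )
        tail = y[10:]
    return comp, d_gy, dmg, float(tail[0]), float(tail[1]), float(tail[2])


def _enter_phase(new_phase: str, old_phase: str, dmg: DamageState,
                 s_entry: float, carry_full: bool) -> DamageState:
    """Map the lesion state across a phase boundary.

    S entry splits the pools (everything is unreplicated); S exit merges
    unreplicated residuals into the corresponding G2 pools; mitosis
    halves the counts (lesions partition between the daughters) unless
    ``carry_full`` is set.
    """
    if old_phase == "S" and new_phase != "S":
        dmg = DamageState(
            n_ssb=dmg.n_ssb_url + dmg.n_ssb_rl,
            n_dsb_f=dmg.n_dsb_f_url + dmg.n_dsb_f_rl,
            n_dsb_s=dmg.n_dsb_s_url + dmg.n_dsb_s_rl,
            n_dsb_m=dmg.n_dsb_m,
        )
    if old_phase == "M" and new_phase == "G1" and not carry_full:
        dmg = DamageState(
            n_ssb=0.5 * dmg.n_ssb, n_dsb_f=0.5 * dmg.n_dsb_f,
            n_dsb_s=0.5 * dmg.n_dsb_s, n_dsb_m=0.5 * dmg.n_dsb_m,
        )
    if new_phase == "S" and old_phase != "S":
        dmg = DamageState(
            n_ssb_url=dmg.n_ssb, n_dsb_f_url=dmg.n_dsb_f,
            n_dsb_s_url=dmg.n_dsb_s, n_dsb_m=dmg.n_dsb_m,
            s_prog=s_entry,
        )
    return dmg


def apply_instantaneous_dose(
    dmg: DamageState, dose_gy: float, params: ModelParams, phase: str, mu_inter: float
) -> DamageState:
    """Impulse (EBRT-style) damage induction as a state jump.

    Lesion pools jump by the per-Gy yields with the same genome-number
    and replication weighting the continuous induction terms use; the
    dose-rate-driven apoptosis term receives no impulse contribution.
    """
    ctx = PhaseContext(phase, mu_inter)
    rp = params.repair
    if phase == "S":
        s = dmg.s_prog
        return replace(
            dmg,
            n_ssb_url=dmg.n_ssb_url + rp.k_ssb * (1.0 - s) * dose_gy,
            n_ssb_rl=dmg.n_ssb_rl + rp.k_ssb * s * dose_gy,
            n_dsb_f_url=dmg.n_dsb_f_url + rp.k_dsb * (1.0 - s) * dose_gy,
            n_dsb_s_url=dmg.n_dsb_s_url + rp.k_dsb * (1.0 - s) * dose_gy,
            n_dsb_f_rl=dmg.n_dsb_f_rl + 2.0 * rp.k_dsb * s * dose_gy,
            n_dsb_s_rl=dmg.n_dsb_s_rl + 2.0 * rp.k_dsb * s * dose_gy,
            n_dsb_m=dmg.n_dsb_m + 2.0 * rp.k_dsb * s * dose_gy,
        )
    p_f, p_s, p_m = repair_probabilities(rp.p_c, rp.p_hr, ctx)
    n_gen = ctx.n_gen
    return replace(
        dmg,
        n_ssb=dmg.n_ssb + n_gen * rp.k_ssb * dose_gy,
        n_dsb_f=dmg.n_dsb_f + p_f * n_gen * rp.k_dsb * dose_gy,
        n_dsb_s=dmg.n_dsb_s + p_s * n_gen * rp.k_dsb * dose_gy,
        n_dsb_m=dmg.n_dsb_m + p_m * n_gen * rp.k_dsb * dose_gy,
    )


# ----------------------------------------------------------------------
# Results

@dataclass
class PhaseSpan:
    """One phase occurrence along a trajectory with its survival drop."""

    phase: str
    t_start: float
    t_end: float
    ln_s_start: float
    ln_s_end: float
    completed: bool

    @property
    def reduction(self) -> float:
        """Reduction in log survival probability across the span."""
        return self.ln_s_start - self.ln_s_end


_COLUMNS = (
    "c_m", "c_acs", "c_dcs", "c_acy", "c_dcy", "a_bq", "doserate_gy_per_h",
    "d_gy", "n_ssb", "n_dsb_f", "n_dsb_s", "n_dsb_m", "n_dsb",
    "n_dsb_url", "n_dsb_rl", "s_prog", "survival", "n_alive", "n_dead",
)


@dataclass
class TrajectoryResult:
    start_index: int
    start_offset_h: float
    t: np.ndarray
    columns: dict[str, np.ndarray]
    phase_log: list[PhaseSpan] = field(default_factory=list)

    @property
    def endpoint_survival(self) -> float:
        return float(self.columns["survival"][-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_h": self.t})
        for col in _COLUMNS:
            df[col] = self.columns[col]
        return df


@dataclass
class EnsembleResult:
    t: np.ndarray
    columns: dict[str, np.ndarray]
    trajectories: list[TrajectoryResult]
    relative_n_alive: np.ndarray
    control: "EnsembleResult | None" = None

    @property
    def endpoint_relative_survival(self) -> float:
        return float(self.relative_n_alive[-1])

    @property
    def endpoint_dose_gy(self) -> float:
        return float(self.columns["d_gy"][-1])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_h": self.t})
        for col in _COLUMNS:
            df[col] = self.columns[col]
        df["relative_n_alive"] = self.relative_n_alive
        return df


# ----------------------------------------------------------------------
# Trajectory integration

def _make_rhs(phase: str, params: ModelParams, parpi, dose_state: DoseState,
              protocol: Protocol, options: SolverOptions):
    """Build the per-segment right-hand side.

    The hot path is hand-inlined scalar arithmetic; it is pinned to the
    public module-level rate functions by a dedicated equivalence test.
    """
    ctx = PhaseContext(phase, params.cellcycle.mu_inter)
    kin = params.kinetics
    rp = params.repair
    sp = params.survival
    sv = params.svalues
    k_on, k_off, k_int, k_rel, mu_dec = kin.k_on, kin.k_off, kin.k_int, kin.k_rel, kin.mu_dec
    r_cell = params.receptors.r_cell
    s_m, s_cs, s_cy = sv.s_m, sv.s_cs, sv.s_cy
    mu_gr = params.cellcycle.mu_gr
    mu_inter = ctx.mu_inter
    in_s = phase == "S"
    n_gen = ctx.n_gen
    p_f, p_s, p_m = repair_probabilities(rp.p_c, rp.p_hr, ctx)
    denom = p_s + p_m
    w_s = p_s / denom if denom > 0.0 else 1.0
    w_m = 1.0 - w_s if denom > 0.0 else 0.0
    k_ssb, k_dsb = rp.k_ssb, rp.k_dsb
    lam_ssb0, lam_f, lam_s, lam_m = rp.lambda_ssb, rp.lambda_f, rp.lambda_s, rp.lambda_m
    eps = options.s_prog_eps
    literal = options.literal_receptor_terms

    mode = parpi.mode
    mu_parpi = parpi.mu_parpi if mode != "none" else 1.0
    decay_exp = parpi.decay_form == "exp"
    lam_red = parpi.lambda_red or 0.0
    lam_override = parpi.lambda_ssb_override

    if in_s:
        a0, b0, a1, b1 = sp.a0, sp.b0, sp.a1, sp.b1
    else:
        a_ph, b_ph = sp.ab(phase)
    psi_k = sp.psi * k_dsb
    apop_active = phase == "G1" or (in_s and sp.apoptosis_in_s)
    mitot_active = phase in ("G2", "M") or (in_s and sp.mitotic_in_s)
    phi, cap = sp.phi, sp.dsb_checkpoint_cap

    delivery = protocol.delivery
    compartment = delivery == "compartment"
    const_rate = (
        protocol.external_dose_gy / protocol.rpt_exposure_h
        if delivery == "constant_rate" else 0.0
    )
    rpt_end = protocol.rpt_exposure_h
    a0_bq, t_ref = dose_state.a0_bq, dose_state.t_ref_h

    def rhs(t, y):
        c_m = y[0] if y[0] > 0.0 else 0.0
        c_acs = y[1] if y[1] > 0.0 else 0.0
        c_dcs = y[2] if y[2] > 0.0 else 0.0
        c_acy = y[3] if y[3] > 0.0 else 0.0
        c_dcy = y[4] if y[4] > 0.0 else 0.0
        if in_s:
            ssb_url = y[6] if y[6] > 0.0 else 0.0
            ssb_rl = y[7] if y[7] > 0.0 else 0.0
            f_url = y[8] if y[8] > 0.0 else 0.0
            f_rl = y[9] if y[9] > 0.0 else 0.0
            s_url = y[10] if y[10] > 0.0 else 0.0
            s_rl = y[11] if y[11] > 0.0 else 0.0
            n_m = y[12] if y[12] > 0.0 else 0.0
            s_prog = min(max(y[13], 0.0), 1.0)
            surv, n_alive, n_dead = max(y[14], 0.0), max(y[15], 0.0), max(y[16], 0.0)
        else:
            n_ssb = y[6] if y[6] > 0.0 else 0.0
            n_f = y[7] if y[7] > 0.0 else 0.0
            n_s = y[8] if y[8] > 0.0 else 0.0
            n_m = y[9] if y[9] > 0.0 else 0.0
            surv, n_alive, n_dead = max(y[10], 0.0), max(y[11], 0.0), max(y[12], 0.0)

        # dose rate (Gy/h)
        if compartment:
            total = c_m + c_acs + c_dcs + c_acy + c_dcy
            if total > 0.0:
                a_bq = a0_bq * math.exp(-mu_dec * (t - t_ref))
                n_eff = n_alive if n_alive > 1.0 else 1.0
                dr = a_bq * (s_m * total + s_cs * c_acs + s_cy * c_acy) \
                    / (total * n_eff) * 3600.0
            else:
                dr = 0.0
        elif const_rate and t < rpt_end:
            dr = const_rate
        else:
            dr = 0.0

        # survival factors
        if in_s:
            n_url = f_url + s_url
            n_rl = f_rl + s_rl + n_m
            f0 = (a0 * n_url + b0) * n_url + 1.0
            f1 = (a1 * n_rl + b1) * n_rl + 1.0
            mu_loss = (f0 if f0 > 0.0 else 0.0) * (f1 if f1 > 0.0 else 0.0)
            n_dsb_present = n_url + n_rl
        else:
            n_dsb_present = n_f + n_s + n_m
            mu_loss = (a_ph * n_dsb_present + b_ph) * n_dsb_present + 1.0
        if mu_loss < 0.0:
            mu_loss = 0.0
        elif mu_loss > 1.0:
            mu_loss = 1.0
        factor = mu_loss * mu_parpi
        if apop_active and dr > 0.0:
            factor *= math.exp(-psi_k * dr)
        if mitot_active and n_dsb_present > 0.0:
            factor *= math.exp(-phi * (n_dsb_present if n_dsb_present < cap else cap))
        mu_dea = 1.0 - factor

        # compartment transfer
        r_alive = r_cell * n_alive
        r_dead = r_cell * n_dead
        cap_alive = r_cell if literal else r_alive
        d_m = k_off * (c_acs + c_dcs) - k_on * c_m * (r_alive + r_dead - c_acs - c_dcs)
        d_acs = k_on * c_m * (cap_alive - c_acs) + k_rel * c_acy \
            - (k_off + k_int + mu_dea) * c_acs
        d_dcs = k_on * c_m * (r_dead - c_dcs) + mu_dea * c_acs - k_off * c_dcs
        d_acy = k_int * c_acs - (k_rel + mu_dea) * c_acy
        d_dcy = mu_dea * c_acy

        # SSB repair rate under PARPi
        if mode in ("none", "constant_only"):
            lam_ssb = lam_ssb0
        elif mode == "reduced_ssb_repair":
            lam_ssb = lam_override
        else:
            n_tot_ssb = (ssb_url + ssb_rl) if in_s else n_ssb
            if decay_exp:
                lam_ssb = lam_ssb0 * math.exp(-lam_red * n_tot_ssb)
            else:
                lam_ssb = lam_ssb0 / (1.0 + lam_red * n_tot_ssb)

        out = np.empty(17 if in_s else 13)
        out[0], out[1], out[2], out[3], out[4] = d_m, d_acs, d_dcs, d_acy, d_dcy
        out[5] = dr
        if in_s:
            oms = 1.0 - s_prog
            if oms < eps:
                oms = eps
            transfer = mu_inter / oms
            conv = transfer * (2.0 * s_url + ssb_url)
            out[6] = k_ssb * oms * dr - (lam_ssb + transfer) * ssb_url
            out[7] = k_ssb * s_prog * dr - lam_ssb * ssb_rl
            out[8] = k_dsb * oms * dr - (lam_f + transfer) * f_url
            out[9] = 2.0 * k_dsb * s_prog * dr + 2.0 * transfer * f_url - lam_f * f_rl
            out[10] = k_dsb * oms * dr - (lam_s + transfer) * s_url
            out[11] = 2.0 * k_dsb * s_prog * dr + w_s * conv - lam_s * s_rl
            out[12] = 2.0 * k_dsb * s_prog * dr + w_m * conv - lam_m * n_m
            out[13] = mu_inter
            out[14] = -mu_dea * surv
            out[15] = (mu_gr - mu_dea) * n_alive
            out[16] = mu_dea * n_alive
        else:
            out[6] = n_gen * k_ssb * dr - lam_ssb * n_ssb
            out[7] = p_f * n_gen * k_dsb * dr - lam_f * n_f
            out[8] = p_s * n_gen * k_dsb * dr - lam_s * n_s
            out[9] = p_m * n_gen * k_dsb * dr - lam_m * n_m
            out[10] = -mu_dea * surv
            out[11] = (mu_gr - mu_dea) * n_alive
            out[12] = mu_dea * n_alive
        return out

    return rhs


def _subsegments(segments: list[_Segment], protocol: Protocol) -> list[tuple[_Segment, float, float]]:
    """Split phase segments at protocol event times."""
    events = sorted({
        protocol.rpt_exposure_h,
        protocol.parpi_exposure_h,
    })
    out = []
    for seg in segments:
        cuts = [seg.t_start] + [e for e in events if seg.t_start < e < seg.t_end] + [seg.t_end]
        for a, b in zip(cuts[:-1], cuts[1:]):
            out.append((seg, a, b))
    return out


def simulate_trajectory(
    start_index: int,
    protocol: Protocol,
    params: ModelParams,
    options: SolverOptions = SolverOptions(),
) -> TrajectoryResult:
    """Integrate one cell-cycle starting point through the full protocol."""
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

    grid = np.linspace(0.0, endpoint, options.grid_points)
    times: list[float] = []
    rows: list[np.ndarray] = []
    phase_log: list[PhaseSpan] = []

    def record(t, phase, comp, d_gy, dmg, surv, n_alive, n_dead, parpi):
        if protocol.delivery == "compartment":
            a_bq = dose_state.activity(t, params.kinetics.mu_dec)
            dr = dose_rate(comp, a_bq, params.svalues, n_alive)
        elif protocol.delivery == "constant_rate":
            a_bq = 0.0
            dr = (protocol.external_dose_gy / protocol.rpt_exposure_h
                  if t < protocol.rpt_exposure_h else 0.0)
        else:
            a_bq, dr = 0.0, 0.0
        if phase == "S":
            n_ssb = dmg.n_ssb_url + dmg.n_ssb_rl
            n_f = dmg.n_dsb_f_url + dmg.n_dsb_f_rl
            n_s = dmg.n_dsb_s_url + dmg.n_dsb_s_rl
            n_url, n_rl, s_prog = dmg.n_dsb_url, dmg.n_dsb_rl, dmg.s_prog
        else:
            n_ssb, n_f, n_s = dmg.n_ssb, dmg.n_dsb_f, dmg.n_dsb_s
            n_url, n_rl, s_prog = 0.0, 0.0, 0.0
        n_m = dmg.n_dsb_m
        row = np.array([
            comp.c_m, comp.c_acs, comp.c_dcs, comp.c_acy, comp.c_dcy, a_bq, dr,
            d_gy, n_ssb, n_f, n_s, n_m, n_f + n_s + n_m,
            n_url, n_rl, s_prog, surv, n_alive, n_dead,
        ])
        if times and math.isclose(times[-1], t, abs_tol=1.0e-12):
            rows[-1] = row
        else:
            times.append(t)
            rows.append(row)

    prev_phase = first.phase
    span_start_t = 0.0
    span_ln_s = 0.0
    prev_phase_completed = first.completed
    t_cursor = 0.0  # actual integration time; S ends eps/mu_inter early

    for seg, t0, t1 in _subsegments(schedule, protocol):
        if seg.phase != prev_phase:
            # close the previous phase span, open a new one
            phase_log.append(PhaseSpan(prev_phase, span_start_t, t0,
                                       span_ln_s, math.log(surv), prev_phase_completed))
            dmg = _enter_phase(seg.phase, prev_phase, dmg, seg.s_entry,
                               options.carry_full_counts_at_mitosis)
            prev_phase = seg.phase
            span_start_t = t0
            span_ln_s = math.log(surv)
        prev_phase_completed = seg.completed

        parpi = params.parpi if t0 < protocol.parpi_exposure_h - 1.0e-12 else PARPI_NONE
        # shave the S -> G2 boundary so 1 - s_prog stays >= eps; the
        # cursor hands the sliver to the next phase so no time is lost
        t0_int = min(t_cursor, t1)
        t1_int = t1
        if seg.phase == "S" and math.isclose(t1, seg.t_end):
            s_end = seg.s_entry + mu_inter * (seg.t_end - seg.t_start)
            if s_end >= 1.0 - options.s_prog_eps:
                t1_int = t1 - options.s_prog_eps / mu_inter
        t_cursor = t1_int
        if t1_int <= t0_int:
            continue

        if not times:
            record(t0_int, seg.phase, comp, d_gy, dmg, surv, n_alive, n_dead, parpi)

        y0 = _pack(seg.phase, comp, d_gy, dmg, surv, n_alive, n_dead)
        rhs = _make_rhs(seg.phase, params, parpi, dose_state, protocol, options)
        inner = grid[(grid > t0_int + 1.0e-12) & (grid < t1_int - 1.0e-12)]
        t_eval = np.concatenate([[t0_int], inner, [t1_int]])
        sol = solve_ivp(
            rhs, (t0_int, t1_int), y0, method=options.method, rtol=options.rtol,
            atol=options.atol, t_eval=t_eval, max_step=options.max_step,
        )
        if not sol.success:
            raise EngineError(
                f"solver failed in phase {seg.phase} on [{t0:.3f}, {t1_int:.3f}] "
                f"(start {start_index}): {sol.message}"
            )
        if np.min(sol.y) < -1.0e-6 * max(1.0, np.max(np.abs(sol.y))):
            raise EngineError(
                f"negative state beyond tolerance in phase {seg.phase} "
                f"on [{t0:.3f}, {t1_int:.3f}] (start {start_index})"
            )
        for i in range(1, len(sol.t)):
            c_i, d_i, g_i, s_i, na_i, nd_i = _unpack(seg.phase, np.maximum(sol.y[:, i], 0.0))
            record(sol.t[i], seg.phase, c_i, d_i, g_i, s_i, na_i, nd_i, parpi)
        comp, d_gy, dmg, surv, n_alive, n_dead = _unpack(
            seg.phase, np.maximum(sol.y[:, -1], 0.0)
        )

        # protocol events at the end of this sub-segment
        if math.isclose(t1, protocol.rpt_exposure_h) and t1 < endpoint - 1.0e-12:
            comp, n_alive, n_dead, dose_state = apply_washout(
                comp, n_alive, n_dead, dose_state, t1, params.kinetics
            )
            record(t1, seg.phase, comp, d_gy, dmg, surv, n_alive, n_dead, parpi)

    phase_log.append(PhaseSpan(prev_phase, span_start_t, endpoint,
                               span_ln_s, math.log(surv), prev_phase_completed))

    t_arr = np.array(times)
    data = np.vstack(rows)
    columns = {name: data[:, i] for i, name in enumerate(_COLUMNS)}
    offset = start_index / cc.n_starts * cc.cycle_length
    return TrajectoryResult(start_index, offset, t_arr, columns, phase_log)


# ----------------------------------------------------------------------
# Ensemble

def _is_untreated(protocol: Protocol, params: ModelParams) -> bool:
    return (
        protocol.a0_bq == 0.0
        and protocol.ebrt_dose_gy == 0.0
        and protocol.external_dose_gy == 0.0
        and params.parpi.mode == "none"
    )


def ensemble_simulate(
    protocol: Protocol,
    params: ModelParams,
    options: SolverOptions = SolverOptions(),
    *,
    include_control: bool = True,
    n_starts: int | None = None,
) -> EnsembleResult:
    """Average ``n_starts`` cell-cycle starting points on a common grid.

    The relative surviving cell number is the ensemble-mean N_alive
    divided by that of an untreated control simulated with identical
    protocol handling (same washout schedule, zero activity, no drug).
    """
    cc = params.cellcycle
    if n_starts is not None:
        cc = replace(cc, n_starts=n_starts)
        params = params.with_(cellcycle=cc)
    grid = np.linspace(0.0, protocol.endpoint_h, options.grid_points)
    trajs = [
        simulate_trajectory(k, protocol, params, options)
        for k in range(cc.n_starts)
    ]
    columns = {
        col: np.mean([np.interp(grid, tr.t, tr.columns[col]) for tr in trajs], axis=0)
        for col in _COLUMNS
    }
    if _is_untreated(protocol, params):
        relative = np.ones_like(grid)
        control = None
    elif include_control:
        control_protocol = replace(
            protocol, a0_bq=0.0, ebrt_dose_gy=0.0, external_dose_gy=0.0, delivery="none"
        )
        control = ensemble_simulate(
            control_protocol, params.with_(parpi=PARPI_NONE), options,
            include_control=False,
        )
        relative = columns["n_alive"] / control.columns["n_alive"]
    else:
        relative = np.ones_like(grid)
        control = None
    return EnsembleResult(grid, columns, trajs, relative, control)


def phase_death_rates(result: EnsembleResult, *, completed_only: bool = False) -> pd.DataFrame:
    """Per-phase reductions in log survival probability.

    One row per phase occurrence per starting point; ``reduction`` is
    the drop in ln S across the span, so summing every span of one
    trajectory reassembles -ln S(endpoint) exactly.
    """
    rows = []
    for tr in result.trajectories:
        for span in tr.phase_log:
            if completed_only and not span.completed:
                continue
            rows.append({
                "start_index": tr.start_index,
                "phase": span.phase,
                "t_start": span.t_start,
                "t_end": span.t_end,
                "completed": span.completed,
                "reduction": span.reduction,
            })
    return pd.DataFrame(rows)
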