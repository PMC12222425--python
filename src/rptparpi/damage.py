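"""Phase-resolved DNA damage induction, repair and the composite survival rate.

Outside S phase, single-strand breaks (SSBs) and double-strand breaks
(DSBs) are induced in proportion to the dose rate and the number of
present genomes and repaired with first-order kinetics.  DSBs are split
by repair kinetics: fast (non-complex, NHEJ-like), slow (complex,
HR-routed) and very slow (MMEJ backup, used when HR fails in G2/M under
homologous-recombination deficiency).

During S phase every lesion pool is split into unreplicated (url) and
replicated (rl) DNA.  Replication transfers unreplicated lesions at rate
mu_inter / (1 - s_prog): DSBs are duplicated onto the replicated copy,
while unreplicated SSBs are converted into DSBs at the fork (the
PARP-trapping route) and distributed between the slow and MMEJ pools
with weights p_s/(p_s+p_m) and p_m/(p_s+p_m).

Cell death combines four multiplicative hourly survival factors: a
genomic-loss quadratic in the present DSB count, dose-rate-driven
apoptosis (interphase), mitotic catastrophe in G2/M (DSB count capped at
the checkpoint threshold) and a constant PARPi monotherapy term:

    mu_dea = 1 - mu_loss * mu_apop * mu_mitot * mu_PARPi   [per hour]
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import PARPiModel, RepairParams, SurvivalParams

__all__ = [
    "PhaseContext",
    "DamageState",
    "repair_probabilities",
    "effective_ssb_repair",
    "interphase_damage_rates",
    "s_phase_damage_rates",
    "genomic_loss_factor",
    "survival_rate",
    "INTERPHASE_LESIONS",
    "S_PHASE_LESIONS",
]

INTERPHASE_LESIONS = ("n_ssb", "n_dsb_f", "n_dsb_s", "n_dsb_m")
S_PHASE_LESIONS = (
    "n_ssb_url",
    "n_ssb_rl",
    "n_dsb_f_url",
    "n_dsb_f_rl",
    "n_dsb_s_url",
    "n_dsb_s_rl",
    "n_dsb_m",
)


@dataclass(frozen=True)
class PhaseContext:
    """Cell-cycle phase and the quantities that depend on it.

    n_gen is the number of present genomes (1 in G1, 2 in G2/M; during S
    the progression variable takes its place).  mu_inter is the S-phase
    progression rate per hour.  HRD routing (p_hr < 1) applies wherever
    a replicated sister chromatid exists: S (replicated pools), G2, M.
    """

    phase: str
    mu_inter: float = 0.0

    def __post_init__(self) -> None:
        if self.phase not in ("G1", "S", "G2", "M"):
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def n_gen(self) -> int:
        return 1 if self.phase in ("G1", "S") else 2

    @property
    def hrd_active(self) -> bool:
        return self.phase in ("S", "G2", "M")


@dataclass
class DamageState:
    """Lesion counts per cell.

    Outside S phase only (n_ssb, n_dsb_f, n_dsb_s, n_dsb_m) are live;
    during S phase the unreplicated/replicated split plus the MMEJ pool
    and the progression variable s_prog in [0, 1) are live.
    """

    n_ssb: float = 0.0
    n_dsb_f: float = 0.0
    n_dsb_s: float = 0.0
    n_dsb_m: float = 0.0
    n_ssb_url: float = 0.0
    n_ssb_rl: float = 0.0
    n_dsb_f_url: float = 0.0
    n_dsb_f_rl: float = 0.0
    n_dsb_s_url: float = 0.0
    n_dsb_s_rl: float = 0.0
    s_prog: float = 0.0

    @property
    def n_dsb_total(self) -> float:
        return self.n_dsb_f + self.n_dsb_s + self.n_dsb_m

    @property
    def n_dsb_url(self) -> float:
        return self.n_dsb_f_url + self.n_dsb_s_url

    @property
    def n_dsb_rl(self) -> float:
        return self.n_dsb_f_rl + self.n_dsb_s_rl + self.n_dsb_m


def repair_probabilities(p_c: float, p_hr: float, context: PhaseContext) -> tuple[float, float, float]:
    """Routing probabilities (p_f, p_s, p_m) for newly induced DSBs.

    p_f = 1 - p_c always.  With full HR capability, or in G1 where no
    sister chromatid exists, p_s = p_c and p_m = 0.  Where HRD applies
    (S-replicated, G2, M) p_s = p_c * p_hr and p_m = p_c * (1 - p_hr).
    The three probabilities always sum to one.
    """
    p_f = 1.0 - p_c
    if context.hrd_active:
        p_s = p_c * p_hr
        p_m = p_c * (1.0 - p_hr)
    else:
        p_s = p_c
        p_m = 0.0
    return p_f, p_s, p_m


def effective_ssb_repair(lambda_ssb: float, parpi: PARPiModel, n_ssb: float) -> float:
    """SSB repair rate (per hour) under the configured PARPi mechanism."""
    if n_ssb < 0.0:
        raise ValueError("n_ssb must be >= 0")
    if parpi.mode in ("none", "constant_only"):
        return lambda_ssb
    if parpi.mode == "reduced_ssb_repair":
        return parpi.lambda_ssb_override
    # decaying_ssb_repair: PARP-trap clearance slows with trap abundance
    if parpi.decay_form == "exp":
        return lambda_ssb * math.exp(-parpi.lambda_red * n_ssb)
    return lambda_ssb / (1.0 + parpi.lambda_red * n_ssb)


def interphase_damage_rates(
    damage: DamageState,
    doserate: float,
    params: RepairParams,
    context: PhaseContext,
    parpi: PARPiModel = PARPiModel(),
) -> np.ndarray:
    """Lesion derivatives (per hour) outside S phase.

    Returns d/dt of (n_ssb, n_dsb_f, n_dsb_s, n_dsb_m).  Induction
    scales with the number of present genomes; each pool repairs with
    first-order kinetics, the SSB rate possibly modified by PARPi.
    """
    if context.phase == "S":
        raise ValueError("use s_phase_damage_rates during S phase")
    n_gen = context.n_gen
    p_f, p_s, p_m = repair_probabilities(params.p_c, params.p_hr, context)
    lam_ssb = effective_ssb_repair(params.lambda_ssb, parpi, damage.n_ssb)
    d_ssb = n_gen * params.k_ssb * doserate - lam_ssb * damage.n_ssb
    d_f = p_f * n_gen * params.k_dsb * doserate - params.lambda_f * damage.n_dsb_f
    d_s = p_s * n_gen * params.k_dsb * doserate - params.lambda_s * damage.n_dsb_s
    d_m = p_m * n_gen * params.k_dsb * doserate - params.lambda_m * damage.n_dsb_m
    return np.array([d_ssb, d_f, d_s, d_m])


def s_phase_damage_rates(
    damage: DamageState,
    doserate: float,
    params: RepairParams,
    context: PhaseContext,
    parpi: PARPiModel = PARPiModel(),
    *,
    s_prog_eps: float = 1.0e-6,
) -> np.ndarray:
    """Lesion and progression derivatives (per hour) during S phase.

    Returns d/dt of (n_ssb_url, n_ssb_rl, n_dsb_f_url, n_dsb_f_rl,
    n_dsb_s_url, n_dsb_s_rl, n_dsb_m, s_prog).  Induction on
    unreplicated DNA scales with the unreplicated fraction (1 - s_prog)
    and on replicated DNA with 2 * s_prog (both copies are hit);
    replication transfers unreplicated lesions at rate
    mu_inter / (1 - s_prog), duplicating DSBs onto the new copy.
    Converted SSBs and transferred slow DSBs are shared between the
    replicated slow and MMEJ pools with weights p_s / (p_s + p_m) and
    p_m / (p_s + p_m).  1 - s_prog is clamped at ``s_prog_eps`` to keep
    the transfer rate finite at the S -> G2 boundary.
    """
    if not (0.0 <= damage.s_prog <= 1.0):
        raise ValueError("s_prog must lie in [0, 1); the S->G2 transition must fire at 1")
    s = damage.s_prog
    one_minus_s = max(1.0 - s, s_prog_eps)
    mu_i = context.mu_inter
    transfer = mu_i / one_minus_s
    _, p_s, p_m = repair_probabilities(params.p_c, params.p_hr, context)
    denom = p_s + p_m
    if denom > 0.0:
        w_s, w_m = p_s / denom, p_m / denom
    else:  # p_c = 0: no complex route exists; keep conversion on the slow pool
        w_s, w_m = 1.0, 0.0

    n_ssb_total = damage.n_ssb_url + damage.n_ssb_rl
    lam_ssb = effective_ssb_repair(params.lambda_ssb, parpi, n_ssb_total)

    d_ssb_url = params.k_ssb * one_minus_s * doserate - (lam_ssb + transfer) * damage.n_ssb_url
    d_ssb_rl = params.k_ssb * s * doserate - lam_ssb * damage.n_ssb_rl

    d_f_url = params.k_dsb * one_minus_s * doserate - (params.lambda_f + transfer) * damage.n_dsb_f_url
    d_f_rl = (
        2.0 * params.k_dsb * s * doserate
        + 2.0 * transfer * damage.n_dsb_f_url
        - params.lambda_f * damage.n_dsb_f_rl
    )

    converted = transfer * (2.0 * damage.n_dsb_s_url + damage.n_ssb_url)
    d_s_url = params.k_dsb * one_minus_s * doserate - (params.lambda_s + transfer) * damage.n_dsb_s_url
    d_s_rl = 2.0 * params.k_dsb * s * doserate + w_s * converted - params.lambda_s * damage.n_dsb_s_rl
    d_m = 2.0 * params.k_dsb * s * doserate + w_m * converted - params.lambda_m * damage.n_dsb_m

    return np.array([d_ssb_url, d_ssb_rl, d_f_url, d_f_rl, d_s_url, d_s_rl, d_m, mu_i])


def genomic_loss_factor(damage: DamageState, sparams: SurvivalParams, context: PhaseContext) -> float:
    """Hourly survival factor from genomic loss, clamped to [0, 1].

    Outside S phase: [a * N_dsb + b] * N_dsb + 1 with phase-specific
    (a, b) <= 0.  During S phase the unreplicated and replicated pools
    contribute one quadratic factor each and the factors multiply.
    """
    if context.phase == "S":
        n_url = damage.n_dsb_url
        n_rl = damage.n_dsb_rl
        f0 = (sparams.a0 * n_url + sparams.b0) * n_url + 1.0
        f1 = (sparams.a1 * n_rl + sparams.b1) * n_rl + 1.0
        val = max(f0, 0.0) * max(f1, 0.0)
    else:
        a, b = sparams.ab(context.phase)
        n = damage.n_dsb_total
        val = (a * n + b) * n + 1.0
    return min(max(val, 0.0), 1.0)


def survival_rate(
    damage: DamageState,
    doserate: float,
    params: RepairParams,
    sparams: SurvivalParams,
    parpi: PARPiModel,
    context: PhaseContext,
) -> float:
    """Instantaneous cell-death rate mu_dea (per hour).

    mu_dea = 1 - mu_loss * mu_apop * mu_mitot * mu_PARPi, where inactive
    factors are one.  Apoptosis (exp(-psi * N_ind), N_ind = k_dsb *
    dose-rate) acts in interphase (G1 and, by default, S); mitotic
    catastrophe (exp(-phi * min(N_dsb, cap))) acts in G2/M with the DSB
    count capped at the G2/M checkpoint threshold.
    """
    mu_loss = genomic_loss_factor(damage, sparams, context)

    apop_active = context.phase == "G1" or (context.phase == "S" and sparams.apoptosis_in_s)
    mu_apop = math.exp(-sparams.psi * params.k_dsb * doserate) if apop_active else 1.0

    mitot_active = context.phase in ("G2", "M") or (context.phase == "S" and sparams.mitotic_in_s)
    if mitot_active:
        n_dsb = damage.n_dsb_url + damage.n_dsb_rl if context.phase == "S" else damage.n_dsb_total
        mu_mitot = math.exp(-sparams.phi * min(n_dsb, sparams.dsb_checkpoint_cap))
    else:
        mu_mitot = 1.0

    mu_parpi = parpi.mu_parpi if parpi.mode != "none" else 1.0
    return 1.0 - mu_loss * mu_apop * mu_mitot * mu_parpi
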