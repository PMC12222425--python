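"""Parameter containers for the RPT + PARPi treatment simulator.

Every physical quantity carries its unit in the field name or docstring.
Internal units are: hours for time, nmol/L for ligand and receptor
concentrations, Bq for activity and Gy for absorbed dose.  All containers
validate their physical invariants on construction so that an invalid
parameter set fails loudly before any integration starts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

__all__ = [
    "KineticParams",
    "ReceptorModel",
    "SValueSet",
    "RepairParams",
    "PARPiModel",
    "PARPI_NONE",
    "SurvivalParams",
    "CellCycleConfig",
    "Protocol",
    "SolverOptions",
    "ModelParams",
    "PHASES",
]

PHASES = ("G1", "S", "G2", "M")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class KineticParams:
    """Radiopharmaceutical transfer rates between compartments.

    k_on : association rate, per (nmol/L) per hour
    k_off : dissociation rate, per hour
    k_int : internalization rate (cell surface -> cytoplasm), per hour
    k_rel : release rate (cytoplasm -> cell surface), per hour
    mu_dec : physical decay rate of the radionuclide, per hour
    """

    k_on: float
    k_off: float
    k_int: float
    k_rel: float
    mu_dec: float

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_int", "k_rel", "mu_dec"):
            _require(getattr(self, name) >= 0.0, f"{name} must be >= 0")


@dataclass(frozen=True)
class ReceptorModel:
    """Surface-receptor pool expressed as a concentration per cell.

    r_cell is the receptor concentration contributed by a single cell in
    the culture volume (nmol/L per cell); the population-level pools are
    R_alive(t) = r_cell * N_alive(t) and R_dead(t) = r_cell * N_dead(t).
    """

    r_cell: float

    def __post_init__(self) -> None:
        _require(self.r_cell > 0.0, "r_cell must be > 0")

    def r_alive(self, n_alive: float) -> float:
        return self.r_cell * n_alive

    def r_dead(self, n_dead: float) -> float:
        return self.r_cell * n_dead


@dataclass(frozen=True)
class SValueSet:
    """MIRD cellular S values: mean absorbed dose to the nucleus per decay.

    s_m : decay in the medium (crossfire), Gy/decay
    s_cs : decay on the cell surface, Gy/decay
    s_cy : decay in the cytoplasm, Gy/decay
    """

    s_m: float
    s_cs: float
    s_cy: float

    def __post_init__(self) -> None:
        for name in ("s_m", "s_cs", "s_cy"):
            _require(getattr(self, name) >= 0.0, f"{name} must be >= 0")
        if not (self.s_cy >= self.s_cs >= self.s_m):
            # Expected ordering for beta emitters in spherical geometry.
            warnings.warn(
                "S values do not satisfy s_cy >= s_cs >= s_m; check geometry",
                stacklevel=2,
            )


@dataclass(frozen=True)
class RepairParams:
    """DNA lesion induction yields and first-order repair rates.

    k_ssb / k_dsb : induced SSBs / DSBs per Gy per genome
    lambda_ssb : SSB repair rate, per hour
    lambda_f, lambda_s, lambda_m : DSB repair rates for fast, slow and
        MMEJ (very slow) kinetics, per hour
    p_c : probability that a radiation-induced DSB is complex
    p_hr : probability that a homologous-recombination event succeeds
        (1 = full HR capability, 0 = complete HRD)
    """

    k_ssb: float
    lambda_ssb: float
    k_dsb: float
    lambda_f: float
    lambda_s: float
    lambda_m: float
    p_c: float
    p_hr: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_ssb", "lambda_ssb", "k_dsb", "lambda_f", "lambda_s", "lambda_m"):
            _require(getattr(self, name) >= 0.0, f"{name} must be >= 0")
        _require(0.0 <= self.p_c <= 1.0, "p_c must be in [0, 1]")
        _require(0.0 <= self.p_hr <= 1.0, "p_hr must be in [0, 1]")


@dataclass(frozen=True)
class PARPiModel:
    """PARP-inhibitor mechanism.

    mode selects how the drug enters the model:
      * ``none`` -- no drug.
      * ``constant_only`` -- only the constant monotherapy survival term
        ``mu_parpi`` (Olaparib-style, no radiosensitization).
      * ``reduced_ssb_repair`` -- constant term plus a fixed replacement
        SSB repair rate ``lambda_ssb_override``.
      * ``decaying_ssb_repair`` -- constant term plus an SSB repair rate
        that decays with SSB abundance (PARP trapping; Rucaparib-style):
        lambda_eff = lambda_ssb * exp(-lambda_red * N_ssb), or the
        rational form lambda_ssb / (1 + lambda_red * N_ssb).

    mu_parpi is a dimensionless multiplicative survival-rate factor in
    (0, 1]; 1 - mu_parpi is the monotherapy kill rate per hour.
    """

    mode: str = "none"
    mu_parpi: float = 1.0
    lambda_ssb_override: float | None = None
    lambda_red: float | None = None
    decay_form: str = "exp"

    def __post_init__(self) -> None:
        _require(
            self.mode in ("none", "constant_only", "reduced_ssb_repair", "decaying_ssb_repair"),
            f"unknown PARPi mode {self.mode!r}",
        )
        _require(0.0 < self.mu_parpi <= 1.0, "mu_parpi must be in (0, 1]")
        _require(self.decay_form in ("exp", "rational"), "decay_form must be 'exp' or 'rational'")
        if self.mode == "reduced_ssb_repair":
            _require(
                self.lambda_ssb_override is not None and self.lambda_ssb_override >= 0.0,
                "reduced_ssb_repair mode requires lambda_ssb_override >= 0",
            )
        if self.mode == "decaying_ssb_repair":
            _require(
                self.lambda_red is not None and self.lambda_red >= 0.0,
                "decaying_ssb_repair mode requires lambda_red >= 0",
            )


PARPI_NONE = PARPiModel(mode="none")


def _default_ab() -> dict[str, tuple[float, float]]:
    return {"G1": (-1.5e-4, -4e-3), "G2": (-1.5e-4, -4e-3), "M": (-1.5e-4, -4e-3)}


@dataclass(frozen=True)
class SurvivalParams:
    """Coefficients of the composite survival rate.

    ab_by_phase maps each non-S phase to the genomic-loss quadratic
    coefficients (a, b), both <= 0; (a0, b0) and (a1, b1) are the
    analogous coefficients for unreplicated and replicated DNA during S.
    psi (per induced DSB) and phi (per present DSB) scale apoptosis and
    mitotic catastrophe; the mitotic term caps the DSB count at
    dsb_checkpoint_cap (G2/M checkpoint).
    """

    ab_by_phase: dict[str, tuple[float, float]] = field(default_factory=_default_ab)
    a0: float = -1.5e-4
    b0: float = -4e-3
    a1: float = -1.5e-4
    b1: float = -4e-3
    psi: float = 0.004
    phi: float = 0.04
    dsb_checkpoint_cap: float = 20.0
    apoptosis_in_s: bool = True
    mitotic_in_s: bool = False

    def __post_init__(self) -> None:
        for ph, (a, b) in self.ab_by_phase.items():
            _require(ph in PHASES, f"unknown phase {ph!r} in ab_by_phase")
            _require(a <= 0.0 and b <= 0.0, f"loss coefficients for {ph} must be <= 0")
        for name in ("a0", "b0", "a1", "b1"):
            _require(getattr(self, name) <= 0.0, f"{name} must be <= 0")
        _require(self.psi >= 0.0 and self.phi >= 0.0, "psi and phi must be >= 0")
        _require(self.dsb_checkpoint_cap > 0.0, "dsb_checkpoint_cap must be > 0")

    def ab(self, phase: str) -> tuple[float, float]:
        return self.ab_by_phase[phase]


@dataclass(frozen=True)
class CellCycleConfig:
    """Cell-cycle timing and the population growth rate.

    proportions are the G1:S:G2:M duration ratios (default 11:8:4:1);
    mu_gr is the Malthusian growth rate per hour, so the cycle length is
    ln 2 / mu_gr and mu_inter = 1 / (S-phase duration) is the S-phase
    progression rate.  n_starts evenly spaced starting positions across
    the cycle represent the asynchronous population.
    """

    mu_gr: float = math.log(2.0) / 24.0
    proportions: tuple[float, float, float, float] = (11.0, 8.0, 4.0, 1.0)
    n_starts: int = 24

    def __post_init__(self) -> None:
        _require(self.mu_gr > 0.0, "mu_gr must be > 0")
        _require(all(p > 0.0 for p in self.proportions), "phase proportions must be > 0")
        _require(len(self.proportions) == 4, "need 4 phase proportions (G1, S, G2, M)")
        _require(self.n_starts >= 1, "n_starts must be >= 1")

    @property
    def cycle_length(self) -> float:
        """Cycle duration in hours (population doubling time)."""
        return math.log(2.0) / self.mu_gr

    def phase_durations(self) -> dict[str, float]:
        total = sum(self.proportions)
        cyc = self.cycle_length
        return {ph: p / total * cyc for ph, p in zip(PHASES, self.proportions)}

    @property
    def mu_inter(self) -> float:
        """S-phase progression rate, per hour."""
        return 1.0 / self.phase_durations()["S"]

    @property
    def one_genome_fraction(self) -> float:
        """Fraction of the cycle spent with one predominant genome (G1 + S/2)."""
        g1, s, _, _ = self.proportions
        return (g1 + 0.5 * s) / sum(self.proportions)


@dataclass(frozen=True)
class Protocol:
    """Experimental protocol.

    a0_bq : initial radiopharmaceutical activity (0 = untreated/control)
    molar_activity_bq_per_mol, volume_l : convert activity to the
        initial medium ligand concentration c_m(0) = A0 / (MA * V)
    n_seeded : cells seeded seeding_offset_h hours before t = 0
    rpt_exposure_h : radionuclide washout time (medium + dead cells removed)
    parpi_exposure_h : PARPi exposure window starting at t = 0
    endpoint_h : read-out time after experiment start
    ebrt_dose_gy : optional instantaneous external-beam dose at t = 0
    delivery : 'compartment' (kinetic model), 'constant_rate' (uniform
        dose rate of external_dose_gy over rpt_exposure_h) or 'none'
    """

    a0_bq: float = 0.0
    molar_activity_bq_per_mol: float = 1.0e16
    volume_l: float = 1.0e-4
    n_seeded: float = 5000.0
    seeding_offset_h: float = 24.0
    rpt_exposure_h: float = 24.0
    parpi_exposure_h: float = 72.0
    endpoint_h: float = 72.0
    ebrt_dose_gy: float = 0.0
    external_dose_gy: float = 0.0
    delivery: str = "compartment"

    def __post_init__(self) -> None:
        _require(self.a0_bq >= 0.0, "a0_bq must be >= 0")
        _require(self.molar_activity_bq_per_mol > 0.0, "molar_activity_bq_per_mol must be > 0")
        _require(self.volume_l > 0.0, "volume_l must be > 0")
        _require(self.n_seeded > 0.0, "n_seeded must be > 0")
        _require(self.seeding_offset_h >= 0.0, "seeding_offset_h must be >= 0")
        _require(self.rpt_exposure_h > 0.0, "rpt_exposure_h must be > 0")
        _require(self.parpi_exposure_h > 0.0, "parpi_exposure_h must be > 0")
        _require(self.endpoint_h >= max(self.rpt_exposure_h, 0.0), "endpoint_h must cover the RPT exposure")
        _require(self.ebrt_dose_gy >= 0.0, "ebrt_dose_gy must be >= 0")
        _require(self.delivery in ("compartment", "constant_rate", "none"), f"unknown delivery {self.delivery!r}")

    @property
    def c_m0_nmol_per_l(self) -> float:
        """Initial medium ligand concentration, nmol/L."""
        return self.a0_bq / (self.molar_activity_bq_per_mol * self.volume_l) * 1.0e9


@dataclass(frozen=True)
class SolverOptions:
    """Numerical settings for trajectory integration."""

    method: str = "LSODA"
    rtol: float = 1.0e-8
    atol: float = 1.0e-10
    grid_points: int = 289
    s_prog_eps: float = 1.0e-6
    literal_receptor_terms: bool = False
    carry_full_counts_at_mitosis: bool = False
    max_step: float = math.inf


@dataclass(frozen=True)
class ModelParams:
    """Bundle of every parameter block needed for one simulation."""

    kinetics: KineticParams
    receptors: ReceptorModel
    svalues: SValueSet
    repair: RepairParams
    survival: SurvivalParams
    cellcycle: CellCycleConfig
    parpi: PARPiModel = PARPI_NONE

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)
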