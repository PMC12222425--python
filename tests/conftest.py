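"""Shared fixtures: a frozen baseline parameter set and fast solver options."""

from __future__ import annotations

import math

import pytest

from rptparpi.params import (
    CellCycleConfig,
    KineticParams,
    ModelParams,
    PARPiModel,
    Protocol,
    ReceptorModel,
    RepairParams,
    SolverOptions,
    SurvivalParams,
    SValueSet,
)

AB = (-2.0e-5, -8.0e-4)


@pytest.fixture(scope="session")
def base_params() -> ModelParams:
    """Baseline parameter set matching the packaged default scenario."""
    return ModelParams(
        kinetics=KineticParams(k_on=0.005, k_off=0.1, k_int=0.15, k_rel=0.02,
                               mu_dec=math.log(2.0) / 159.53),
        receptors=ReceptorModel(r_cell=1.66e-5),
        svalues=SValueSet(s_m=2.2e-10, s_cs=8.0e-4, s_cy=2.0e-3),
        repair=RepairParams(k_ssb=700.0, lambda_ssb=2.0, k_dsb=35.0,
                            lambda_f=2.77, lambda_s=0.26, lambda_m=0.02,
                            p_c=0.3, p_hr=1.0),
        survival=SurvivalParams(ab_by_phase={p: AB for p in ("G1", "G2", "M")},
                                a0=AB[0], b0=AB[1], a1=AB[0], b1=AB[1],
                                psi=5.0e-4, phi=2.0e-3),
        cellcycle=CellCycleConfig(),
    )


@pytest.fixture(scope="session")
def rucaparib() -> PARPiModel:
    return PARPiModel(mode="decaying_ssb_repair", mu_parpi=0.9965, lambda_red=5.0e-3)


@pytest.fixture(scope="session")
def olaparib() -> PARPiModel:
    return PARPiModel(mode="constant_only", mu_parpi=0.9965)


@pytest.fixture(scope="session")
def protocol_100kbq() -> Protocol:
    return Protocol(a0_bq=1.0e5)


@pytest.fixture(scope="session")
def fast_opts() -> SolverOptions:
    """Loosened tolerances for tests that only need qualitative accuracy."""
    return SolverOptions(rtol=1.0e-6, atol=1.0e-9, grid_points=49)
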