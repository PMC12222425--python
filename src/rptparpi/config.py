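"""Configuration loading, validation, result export and run provenance.

Configurations are human-editable YAML with one block per parameter
group; every physical quantity carries its unit as a key suffix
(``_per_h``, ``_bq``, ``_gy`` ...) to prevent unit drift.  Validation
is strict: unknown keys, missing required keys and invariant
violations fail with messages naming the offending key.  Derived
quantities (cycle length, S-phase progression rate, the one-genome
predominance fraction) are computed, never configured, so they cannot
drift out of consistency.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import (
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

__all__ = ["RunConfig", "RunRecord", "load_and_validate", "loads_and_validate",
           "default_config_dict", "dump_config", "export_results",
           "packaged_config", "list_packaged_configs", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file violated the schema or an invariant."""


# Schema: block -> {key: (required, type hint for the error message)}
_SCHEMA: dict[str, dict[str, bool]] = {
    "kinetics": {
        "k_on_per_nm_h": True, "k_off_per_h": True, "k_int_per_h": True,
        "k_rel_per_h": True, "mu_dec_per_h": True,
    },
    "receptors": {"r_cell_nm": True, "provenance": False},
    "svalues": {
        "s_m_gy_per_decay": True, "s_cs_gy_per_decay": True,
        "s_cy_gy_per_decay": True, "provenance": False,
    },
    "radiobiology": {
        "k_ssb_per_gy": True, "lambda_ssb_per_h": True, "k_dsb_per_gy": True,
        "lambda_f_per_h": True, "lambda_s_per_h": True, "lambda_m_per_h": True,
        "p_c": True, "p_hr": False,
    },
    "survival": {
        "a_per_dsb2": True, "b_per_dsb": True, "ab_by_phase": False,
        "a0_per_dsb2": False, "b0_per_dsb": False,
        "a1_per_dsb2": False, "b1_per_dsb": False,
        "psi_per_dsb": True, "phi_per_dsb": True,
        "dsb_checkpoint_cap": False, "apoptosis_in_s": False, "mitotic_in_s": False,
    },
    "cellcycle": {"mu_gr_per_h": True, "proportions": False, "n_starts": False},
    "protocol": {
        "a0_bq": False, "molar_activity_bq_per_mol": False, "volume_l": False,
        "n_seeded": False, "seeding_offset_h": False, "rpt_exposure_h": False,
        "parpi_exposure_h": False, "endpoint_h": False, "ebrt_dose_gy": False,
        "external_dose_gy": False, "delivery": False,
    },
    "parpi": {
        "mode": False, "mu_parpi": False, "lambda_ssb_override_per_h": False,
        "lambda_red_per_ssb": False, "decay_form": False,
    },
    "solver": {
        "method": False, "rtol": False, "atol": False, "grid_points": False,
        "s_prog_eps": False, "literal_receptor_terms": False,
        "carry_full_counts_at_mitosis": False, "max_step": False,
    },
    "seeds": {"master": False},
    "meta": {"name": False, "description": False, "provenance": False},
}

_REQUIRED_BLOCKS = ("kinetics", "receptors", "svalues", "radiobiology",
                    "survival", "cellcycle", "protocol")


@dataclass
class RunConfig:
    """A fully validated configuration ready for simulation."""

    params: ModelParams
    protocol: Protocol
    solver: SolverOptions
    seed: int
    raw: dict = field(repr=False, default_factory=dict)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(self.raw, sort_keys=True).encode()
        ).hexdigest()


@dataclass
class RunRecord:
    """Provenance of one executed run; serialized next to the outputs."""

    config_hash: str
    seed: int
    solver: dict
    software_version: str
    timestamp_utc: str
    outputs: list[str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _check_block(name: str, block: dict) -> None:
    if not isinstance(block, dict):
        raise ConfigError(f"block '{name}' must be a mapping")
    schema = _SCHEMA[name]
    unknown = set(block) - set(schema)
    if unknown:
        raise ConfigError(f"unknown keys in block '{name}': {sorted(unknown)}")
    missing = [k for k, req in schema.items() if req and k not in block]
    if missing:
        raise ConfigError(f"missing required keys in block '{name}': {missing}")


def _coerce_numbers(obj):
    # YAML 1.1 reads "1.0e5" (no signed exponent) as a string; accept it.
    if isinstance(obj, dict):
        return {k: _coerce_numbers(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_coerce_numbers(v) for v in obj]
    if isinstance(obj, str):
        try:
            return float(obj)
        except ValueError:
            return obj
    return obj


def loads_and_validate(text: str) -> RunConfig:
    """Validate a YAML configuration string and build a RunConfig."""
    doc = _coerce_numbers(yaml.safe_load(text))
    if not isinstance(doc, dict):
        raise ConfigError("configuration must be a mapping of blocks")
    unknown_blocks = set(doc) - set(_SCHEMA)
    if unknown_blocks:
        raise ConfigError(f"unknown blocks: {sorted(unknown_blocks)}")
    missing_blocks = [b for b in _REQUIRED_BLOCKS if b not in doc]
    if missing_blocks:
        needed = {b: [k for k, req in _SCHEMA[b].items() if req] for b in missing_blocks}
        raise ConfigError(f"missing required blocks (with required keys): {needed}")
    for name in doc:
        _check_block(name, doc[name])

    def build(cls, block_name, mapping):
        try:
            return cls(**mapping)
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"block '{block_name}': {exc}") from exc

    kin = doc["kinetics"]
    kinetics = build(KineticParams, "kinetics", dict(
        k_on=kin["k_on_per_nm_h"], k_off=kin["k_off_per_h"],
        k_int=kin["k_int_per_h"], k_rel=kin["k_rel_per_h"],
        mu_dec=kin["mu_dec_per_h"],
    ))
    receptors = build(ReceptorModel, "receptors",
                      dict(r_cell=doc["receptors"]["r_cell_nm"]))
    sv = doc["svalues"]
    svalues = build(SValueSet, "svalues", dict(
        s_m=sv["s_m_gy_per_decay"], s_cs=sv["s_cs_gy_per_decay"],
        s_cy=sv["s_cy_gy_per_decay"],
    ))
    rb = doc["radiobiology"]
    repair = build(RepairParams, "radiobiology", dict(
        k_ssb=rb["k_ssb_per_gy"], lambda_ssb=rb["lambda_ssb_per_h"],
        k_dsb=rb["k_dsb_per_gy"], lambda_f=rb["lambda_f_per_h"],
        lambda_s=rb["lambda_s_per_h"], lambda_m=rb["lambda_m_per_h"],
        p_c=rb["p_c"], p_hr=rb.get("p_hr", 1.0),
    ))
    sc = doc["survival"]
    a, b = sc["a_per_dsb2"], sc["b_per_dsb"]
    if "ab_by_phase" in sc:
        ab = {ph: tuple(v) for ph, v in sc["ab_by_phase"].items()}
    else:
        ab = {ph: (a, b) for ph in ("G1", "G2", "M")}
    survival = build(SurvivalParams, "survival", dict(
        ab_by_phase=ab,
        a0=sc.get("a0_per_dsb2", a), b0=sc.get("b0_per_dsb", b),
        a1=sc.get("a1_per_dsb2", a), b1=sc.get("b1_per_dsb", b),
        psi=sc["psi_per_dsb"], phi=sc["phi_per_dsb"],
        dsb_checkpoint_cap=sc.get("dsb_checkpoint_cap", 20.0),
        apoptosis_in_s=sc.get("apoptosis_in_s", True),
        mitotic_in_s=sc.get("mitotic_in_s", False),
    ))
    cyc = doc["cellcycle"]
    cellcycle = build(CellCycleConfig, "cellcycle", dict(
        mu_gr=cyc["mu_gr_per_h"],
        proportions=tuple(cyc.get("proportions", (11.0, 8.0, 4.0, 1.0))),
        n_starts=cyc.get("n_starts", 24),
    ))
    parpi_doc = doc.get("parpi", {})
    parpi = build(PARPiModel, "parpi", dict(
        mode=parpi_doc.get("mode", "none"),
        mu_parpi=parpi_doc.get("mu_parpi", 1.0),
        lambda_ssb_override=parpi_doc.get("lambda_ssb_override_per_h"),
        lambda_red=parpi_doc.get("lambda_red_per_ssb"),
        decay_form=parpi_doc.get("decay_form", "exp"),
    ))
    protocol = build(Protocol, "protocol", dict(doc.get("protocol", {})))
    sol = dict(doc.get("solver", {}))
    if sol.get("max_step") in (None, "inf"):
        sol.pop("max_step", None)
    solver = build(SolverOptions, "solver", sol)
    seed = int(doc.get("seeds", {}).get("master", 0))

    params = ModelParams(
        kinetics=kinetics, receptors=receptors, svalues=svalues,
        repair=repair, survival=survival, cellcycle=cellcycle, parpi=parpi,
    )
    return RunConfig(params=params, protocol=protocol, solver=solver,
                     seed=seed, raw=doc)


def load_and_validate(path: str | Path) -> RunConfig:
    """Load, schema-check and build a configuration from a YAML file."""
    return loads_and_validate(Path(path).read_text())


def default_config_dict() -> dict:
    """The packaged default parameter set as a plain dictionary.

    Defaults describe a generic receptor-expressing suspension cell line
    under a Lu-177-labelled ligand: literature-scale lesion yields and
    repair rates, synthetic placeholder kinetic/dosimetric values chosen
    to put the endpoint dose and survival in the experimentally observed
    range (the calibrated per-cell-line values are not published).
    """
    return yaml.safe_load(packaged_config_text("defaults.yaml"))


def dump_config(config: RunConfig) -> str:
    """Serialize the raw configuration back to canonical YAML."""
    return yaml.safe_dump(config.raw, sort_keys=True)


def packaged_config_text(name: str) -> str:
    return resources.files("rptparpi.data").joinpath(name).read_text()


def packaged_config(name: str) -> RunConfig:
    """Load one of the packaged example scenario configurations."""
    return loads_and_validate(packaged_config_text(name))


def list_packaged_configs() -> list[str]:
    return sorted(
        p.name for p in resources.files("rptparpi.data").iterdir()
        if p.name.endswith(".yaml")
    )


def export_results(
    results: dict[str, "pd.DataFrame | dict"],
    out_prefix: str | Path,
    config: RunConfig,
) -> RunRecord:
    """Write result tables (CSV) and metadata (JSON) plus a run record.

    Re-running with an identical configuration and seed reproduces the
    CSV outputs bit-identically for deterministic operations.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            path = Path(f"{out_prefix}_{name}.csv")
            obj.to_csv(path, index=False, float_format="%.12g")
        else:
            path = Path(f"{out_prefix}_{name}.json")
            path.write_text(json.dumps(obj, indent=2, default=_json_default))
        written.append(str(path))
    try:
        from importlib.metadata import version
        ver = version("rptparpi")
    except Exception:  # pragma: no cover - not installed
        ver = "unknown"
    record = RunRecord(
        config_hash=config.config_hash,
        seed=config.seed,
        solver=asdict(config.solver),
        software_version=ver,
        timestamp_utc=datetime.now(timezone.utc).isoformat(),
        outputs=written,
    )
    record_path = Path(f"{out_prefix}_run.json")
    record_path.write_text(record.to_json())
    return record


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)!r}")
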