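# rptparpi

A mechanistic simulator of combined radiopharmaceutical therapy (RPT) and
PARP-inhibitor (PARPi) treatment of cancer cells in vitro, with
translational extensions to external-beam comparison, in vivo tumor-growth
integration and clinical combination-protocol predictions.

It is written for radiopharmaceutical dosimetry and radiobiology modelers
who want to ask quantitative questions about protracted irradiation
combined with DNA-repair inhibition: how much dose do cell nuclei absorb
from a receptor-targeted Lu-177 ligand, how does PARP trapping convert
single-strand breaks into lethal double-strand breaks during replication,
and how does homologous-recombination deficiency (HRD) change the answer.

## Model

Three coupled layers are integrated as one ODE system per cell-cycle
starting point:

1. **Compartment kinetics + microdosimetry.** Ligand concentrations in
   the medium, on living/dead cell surfaces and in living/dead cytoplasm
   exchange via association/dissociation (k_on, k_off against the
   receptor pools R_alive, R_dead), internalization/release (k_int,
   k_rel) and cell death. The nucleus dose rate follows the MIRD cellular
   S-value formalism with medium crossfire:
   dD/dt = A(t)[S_m Σc + S_cs c_acs + S_cy c_acy] / (Σc · N_alive),
   with A(t) = A0 e^(−μ_dec t).
2. **Phase-resolved damage and repair.** SSBs and DSBs (fast / slow /
   MMEJ kinetics) are induced ∝ dD/dt and repaired first-order. During S
   phase, unreplicated lesions transfer at rate μ_inter/(1−s_prog):
   DSBs duplicate, SSBs convert into DSBs at the fork (PARP trapping) and
   are routed between the HR-dependent slow pool and the MMEJ backup with
   weights p_HR and 1−p_HR.
3. **Survival.** dS/dt = −μ_dea S with
   μ_dea = 1 − μ_loss·μ_apop·μ_mitot·μ_PARPi: a genomic-loss quadratic in
   the DSB count, dose-rate-driven apoptosis (interphase), mitotic
   catastrophe in G2/M capped at the 20-DSB checkpoint, and a constant
   PARPi monotherapy term. The same rate drives the population and the
   living→dead ligand transfer.

An experiment averages 24 evenly spaced cell-cycle starting points
(G1:S:G2:M = 11:8:4:1) and reports the endpoint surviving-cell number
relative to an untreated control. Calibration fits the kinetic rates and
the PARPi parameters to survival-vs-activity data by bounded nonlinear
least squares on log survival. See `docs/methods.md` for the full model
description and its limitations.

## Worked example

```python
from dataclasses import replace
from rptparpi import ensemble_simulate, packaged_config

cfg = packaged_config("defaults.yaml")          # Lu-177 ligand scenario
proto = replace(cfg.protocol, a0_bq=1.0e4)      # 10 kBq initial activity
res = ensemble_simulate(proto, cfg.params, cfg.solver)
print(f"endpoint dose to nuclei : {res.endpoint_dose_gy:.2f} Gy")
print(f"relative survival (72 h): {res.endpoint_relative_survival:.4f}")
```

prints

```
endpoint dose to nuclei : 1.50 Gy
relative survival (72 h): 0.4047
```

i.e. a 10 kBq, 24-h exposure in a 100 µL well delivers about 1.5 Gy to
the cell nuclei by the 72-h read-out and leaves ~40% as many living cells
as the untreated control. The same run is available from the shell:

```sh
rpt-parpi simulate --activity 1e4 --out run
rpt-parpi simulate --activity 1e4 --parpi decaying_ssb_repair --hrd 0.0 --out run_hrd
```

which writes the ensemble time courses (`run_ensemble.csv`), per-phase
death-rate reductions (`run_phases.csv`) and a provenance record
(`run_run.json`). Other subcommands: `fit-kinetics`, `fit-parpi`,
`make-synthetic`, `compare-ebrt`, `dose-curve`, `stability`, `invivo`,
`predict` (see `rpt-parpi --help`).

The packaged scenario configurations (`rptparpi/data/*.yaml`) ship
clearly marked synthetic placeholder values for the per-cell-line
calibrated parameters; calibrate against your own survival data with
`fit-kinetics` / `fit-parpi` before quantitative use.

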