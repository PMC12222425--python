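meta:
  name: nci-h69-mono
  description: >
    Lu-177-labelled somatostatin-analog monotherapy of an SSTR2-expressing
    small-cell lung cancer suspension line (NCI-H69-like scenario shape).
  provenance: >
    Lesion yields and repair rates are literature-scale values for X-ray /
    beta LET; kinetic rates, receptor density, S values and the survival
    coefficients are synthetic placeholders chosen so that the 1-100 kBq
    protocol spans sub-Gy to ~10 Gy nucleus doses and survival from ~1 to
    below 1e-3 (the per-cell-line calibrated values are unpublished).

kinetics:
  k_on_per_nm_h: 0.005        # association, per (nmol/L) per hour
  k_off_per_h: 0.1           # dissociation
  k_int_per_h: 0.15          # internalization
  k_rel_per_h: 0.02          # release
  mu_dec_per_h: 4.3446e-3    # Lu-177, half-life 159.53 h

receptors:
  r_cell_nm: 1.66e-5         # ~1e6 receptors per cell in 100 uL
  provenance: synthetic placeholder (geometry-derived value unpublished)

svalues:
  s_m_gy_per_decay: 2.2e-10
  s_cs_gy_per_decay: 8.0e-4
  s_cy_gy_per_decay: 2.0e-3
  provenance: synthetic placeholder (Monte-Carlo S values unpublished)

radiobiology:
  k_ssb_per_gy: 700.0        # SSBs per Gy per genome
  lambda_ssb_per_h: 2.0
  k_dsb_per_gy: 35.0         # DSBs per Gy per genome
  lambda_f_per_h: 2.77       # fast (NHEJ-like), t1/2 ~ 15 min
  lambda_s_per_h: 0.26       # slow (complex, HR-routed)
  lambda_m_per_h: 0.02       # MMEJ backup
  p_c: 0.3                   # complex-DSB probability
  p_hr: 1.0                  # full HR capability

survival:
  a_per_dsb2: -2.0e-5
  b_per_dsb: -8.0e-4
  psi_per_dsb: 5.0e-4        # apoptosis per induced DSB
  phi_per_dsb: 2.0e-3        # mitotic catastrophe per present DSB
  dsb_checkpoint_cap: 20.0   # G2/M checkpoint threshold

cellcycle:
  mu_gr_per_h: 2.88811e-2    # doubling time 24 h
  proportions: [11, 8, 4, 1] # G1:S:G2:M
  n_starts: 24

protocol:
  a0_bq: 1.0e5
  molar_activity_bq_per_mol: 1.0e16
  volume_l: 1.0e-4
  n_seeded: 5000
  seeding_offset_h: 24
  rpt_exposure_h: 24
  parpi_exposure_h: 72
  endpoint_h: 72
  delivery: compartment

parpi:
  mode: none

solver:
  method: LSODA
  rtol: 1.0e-8
  atol: 1.0e-10

seeds:
  master: 0
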