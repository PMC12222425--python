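# Methods

`rptparpi` simulates the in vitro response of a receptor-expressing cancer
cell population to a radionuclide-labelled ligand (radiopharmaceutical
therapy, RPT), alone or combined with a PARP inhibitor (PARPi), and layers
a set of translational analyses on top of the calibrated in vitro model.
This note documents the model, its assumptions, the numerical choices and
the known limitations.

## Compartment kinetics and microdosimetry

Ligand concentrations (nmol/L) are tracked in five compartments: medium
`c_m`, living-cell surface `c_acs`, dead-cell surface `c_dcs`, living-cell
cytoplasm `c_acy` and dead-cell cytoplasm `c_dcy`. Binding is
receptor-limited (`k_on`, `k_off` against the population receptor pools
`R_alive = r_cell N_alive`, `R_dead = r_cell N_dead`), internalization and
release (`k_int`, `k_rel`) occur only in living cells, and the
instantaneous death rate `mu_dea(t)` carries surface and cytoplasmic
ligand from the living to the dead compartments. With the population-level
receptor pools in every gain term the five derivatives sum to zero exactly
(ligand is chemically stable; transfer only moves it). A config switch
(`literal_receptor_terms`) restores the non-conserving single-cell reading
of the surface gain term for comparison.

The absorbed-dose rate to living-cell nuclei follows the MIRD cellular
S-value formalism with a medium crossfire term,

    dD/dt = A(t) [S_m * sum(c) + S_cs * c_acs + S_cy * c_acy]
            / (sum(c) * max(N_alive, 1)),

with `A(t) = A0 exp(-mu_dec t)` (exact exponential decay, rebased after
washout). Decay acts only through `A(t)`; the compartment equations track
ligand molecules. The `N_alive >= 1` floor applies to dosimetry only.
`sum(c) = 0` returns zero dose rate (the expression is otherwise 0/0).
Washout at the end of radionuclide exposure (default 24 h) zeroes the
medium and the dead-cell compartments, resets the dead-cell count, and
rebases the activity by the ligand fraction retained on and in living
cells. The cytoplasm S value is applied to living-cell cytoplasmic ligand
only; dead-cell compartments contribute through the crossfire term.

## Damage and survival

Lesions per representative cell: single-strand breaks (SSBs) and
double-strand breaks (DSBs) split by repair kinetics — fast (non-complex),
slow (complex, homologous-recombination routed) and MMEJ (very slow
backup). Outside S phase, induction is `N_gen * k_{ssb,dsb} * dD/dt`
partitioned by `p_f = 1 - p_c`, `p_s`, `p_m`, and each pool repairs with
first-order kinetics. With full HR capability `p_s = p_c` everywhere;
under HR deficiency (`p_hr < 1`) and wherever a sister chromatid exists
(S-replicated pools, G2, M), `p_s = p_c p_hr` and `p_m = p_c (1 - p_hr)`.

During S phase every pool splits into unreplicated/replicated halves.
Replication progression `s_prog` advances at the constant rate
`mu_inter = 1 / (S duration)`; unreplicated lesions transfer at rate
`mu_inter / (1 - s_prog)` (each lesion's replication time is uniform over
the remaining S phase). Transferred DSBs duplicate (factor 2) onto the
replicated copy; transferred SSBs convert into DSBs at the fork — the
PARP-trapping route — and, together with transferred slow DSBs, are
shared between the replicated-slow and MMEJ pools with weights
`p_s/(p_s+p_m)` and `p_m/(p_s+p_m)` (= `p_hr` and `1 - p_hr`). The
S-phase induction terms are implemented in their printed form: the
unreplicated fast and slow pools each receive the full `k_dsb (1-s) dD/dt`
induction (no `p_f/p_s` partition) and the replicated pools, including
MMEJ, each receive `2 k_dsb s dD/dt`. When `p_c = 0` the conversion route
is degenerate and all converted lesions are kept on the slow pool.

The hourly death rate composes four multiplicative survival factors,

    mu_dea = 1 - mu_loss * mu_apop * mu_mitot * mu_PARPi,

with genomic loss `mu_loss = (a N_dsb + b) N_dsb + 1` (per-phase `a, b <=
0`; during S the unreplicated and replicated pools contribute one
quadratic factor each), dose-rate-driven apoptosis `exp(-psi k_dsb dD/dt)`
active in interphase (G1 and, by default, S — apoptosis is an interphase
death mode; a config toggle restricts it to G1), mitotic catastrophe
`exp(-phi min(N_dsb, 20))` in G2/M with the DSB count capped at the G2/M
checkpoint threshold, and a constant PARPi monotherapy term `mu_PARPi` in
(0, 1]. `mu_loss` is clamped to [0, 1]: the quadratic goes negative at
large lesion burdens, and a survival factor cannot be negative — this
clamp also bounds the hourly kill rate at 1/h. The same `mu_dea` drives
the population equations (`dN_alive = (mu_gr - mu_dea) N_alive`,
`dN_dead = mu_dea N_alive`) and the compartment death transfer.

PARPi mechanisms: `constant_only` applies only `mu_PARPi`
(Olaparib-style, no radiosensitization); `reduced_ssb_repair` replaces the
SSB repair rate by a fitted constant; `decaying_ssb_repair`
(Rucaparib-style PARP trapping) uses
`lambda_eff = lambda_ssb exp(-lambda_red N_ssb)` — a single-rate decaying
function of trap abundance; the rational alternative
`lambda_ssb / (1 + lambda_red N_ssb)` is selectable. Slower SSB repair
raises the SSB census, which raises the S-phase conversion flux into
near-permanent DSB pools: this is the radiosensitization and, combined
with HR deficiency, produces super-multiplicative (synthetically lethal)
kill, which the tests verify directionally.

## Cell-cycle heterogeneity and the trajectory engine

The cycle is split G1:S:G2:M = 11:8:4:1 (one-genome predominance
`(G1 + S/2)/total = 62.5%`), scaled to the doubling time `ln 2 / mu_gr`.
An experiment is represented by `n_starts = 24` trajectories whose start
positions are evenly spaced across the cycle; ensemble curves are the
mean of the per-start trajectories linearly interpolated onto a common
grid, and the experimental read-out is the endpoint surviving-cell number
relative to an untreated control run with identical event handling
(same washout schedule, zero activity, no drug).

Integration is piecewise over phase segments and protocol events
(washout, end of PARPi exposure, an optional instantaneous external-beam
dose at t = 0 applied as a lesion-state jump with the same genome-number
weighting as the continuous induction; the dose-rate-driven apoptosis
term receives no impulse contribution). `scipy.integrate.solve_ivp`
(LSODA by default; method and tolerances configurable, default rtol 1e-8
/ atol 1e-10) advances each segment. At G1→S the lesion pools move to the
unreplicated side; the S→G2 transition fires at `s_prog = 1 - eps`
(`eps = 1e-6`), where the unreplicated pools are empty up to O(eps) and
residuals merge into the G2 pools (conservation over convenience); the
shaved `eps/mu_inter` sliver of time is handed to the next segment so no
integration time is lost. At mitosis the lesion counts halve (lesions
partition between daughters; `carry_full_counts_at_mitosis` selects the
alternative) while the population equations handle growth. The engine's
inlined right-hand side is pinned to the public per-module rate functions
by an equivalence test, and the adaptive solver is cross-checked against
a fixed-step explicit Euler reference integrator (dt = 1e-3 h) to within
0.5% endpoint survival.

## Default parameter set

Lesion yields and repair rates are literature-scale values for low-LET
radiation: `k_ssb = 700 /Gy/genome`, `k_dsb = 35 /Gy/genome`,
`lambda_ssb = 2 /h`, `lambda_f = 2.77 /h`, `lambda_s = 0.26 /h`,
`lambda_m = 0.02 /h`, `p_c = 0.3`. The decay rate is Lu-177
(`ln 2 / 159.53 h`). Kinetic rates, receptor density, S values and the
survival coefficients are synthetic placeholders (marked as such in the
packaged configs): the per-cell-line calibrated values are not published,
so the defaults were chosen once so that the standard protocol (5,000
cells seeded 24 h before a 24-h, 1–100 kBq exposure in 100 µL, read out
at 72 h) spans sub-Gy to ~10 Gy nucleus doses and relative survival from
~1 down to below 1e-2 — the ranges the assay design probes. Binding is
deliberately in a kinetically resolved regime (`k_on = 0.005 /(nmol/L)/h`,
`k_off = 0.1 /h`, Kd = 20 nmol/L): with fast dissociation only the ratio
`k_off/k_on` is observable and the staged kinetic fit would be exactly
degenerate. Survival coefficients: `a = -2e-5`, `b = -8e-4` (all phases
and both S-phase factors), `psi = 5e-4`, `phi = 2e-3`, checkpoint cap 20.

## Calibration and the synthetic-data generator

Calibration is staged like the model: the four kinetic rates are fitted
on monotherapy survival-vs-activity data with the radiobiology fixed,
then the PARPi parameters (one for `constant_only`, two for the
`reduced`/`decaying` variants) on the combination arm with the kinetics
frozen. Residuals are on log relative survival (the data span orders of
magnitude), weighted by relative SEM when available, minimised with
bounded trust-region least squares (`trf`, log10 parameterization,
Jacobian-based column scaling, seeded multistart).

The generator emulates the replicate structure of the assay: per
activity, `3 x 6` technical replicates multiply the model prediction by
a mean-one lognormal factor with the stated CV, reported as mean ± SEM,
fully reproducible per seed. It emulates measurement noise only — not
plate effects, edge effects, or biological drift between repeats — so
recovery studies certify the fitting machinery, not robustness to real
assay artifacts.

A structural caveat, quantified in the decisions record and visible in
the acceptance report: the endpoint-survival read-out constrains only
about two of the four kinetic log-sensitivity directions (singular values
~13 : 2.3 : 0.03 : 0.002), so fitted kinetic rates are effective values
that reproduce the data without being individually identified. The
fitted PARPi parameters are identifiable and recover exactly on noiseless
data.

## Translational analyses

* EBRT comparison: the same nucleus dose delivered instantaneously at
  t = 0 versus at a constant rate over the 24-h exposure window. In this
  parameterization the protracted delivery is the more lethal modality
  throughout the examined range, because continuous irradiation feeds
  SSBs into replication forks in every cycle while an impulse's SSBs
  repair before S phase; the comparison reports the survival curves and
  the crossover dose when one exists.
* Stability analysis: one-at-a-time scaling of any registered parameter,
  reporting endpoint survival per multiplier; flat responses flag
  insignificant parameters (e.g. the medium and surface S values at
  saturating activity).
* In vivo integration: for a tumor arm `N(t)` with control growth rate
  `mu_gr`, the implied survival is `S(t) = N(t) / (N(0) exp(mu_gr t))`
  and a single-rate exponential fit through `S(0) = 1` gives `mu_dea`.
  A PARPi monotherapy arm inverts to `mu_PARPi = 1 + g - mu_gr` with `g`
  the fitted net exponent; this sign convention follows from inserting
  the survival-rate composition into the population equation and
  reproduces consistent rate pairs (e.g. growth 0.182 /d with net
  exponent 0.141 /d inverts to 0.959 /d).
* Concentration-effect: the radiosensitizer effect (death-rate ratio
  relative to RPT alone) is linear in the tumor PARPi concentration
  within a configured therapeutic window; tumor concentration is the
  body concentration times a tumor-to-body ratio of 7.2e-3; drugs scale
  the slope inversely with IC50.
* Clinical combination predictions: drug amount and body weight map to a
  body concentration through a one-compartment distribution volume
  proportional to body mass (2.26 L/kg default, exponent configurable);
  the effect E then scales the in vivo RPT death rate, giving a relative
  tumor size `exp(-(E-1) h mu_rpt T)` versus RPT monotherapy after T
  days. The HRD amplification `h(p_hr)` is derived from the in vitro
  simulator at an anchor activity (25.9 kBq, 3 days): it is the ratio of
  the combination-minus-monotherapy death-rate increment at reduced HR
  capability to the increment at full capability. The 95% CI propagates
  a configurable normal relative SD on the effect increment. The
  anchor-activity mapping and the body-weight scaling rule are stated
  assumptions, not derived results.

## Numerical choices and degenerate inputs

* `sum(c) = 0` → zero dose rate; `p_c = 0` → conversion routed to the
  slow pool; `N_alive` floored at 1 in dosimetry only.
* States are clamped non-negative inside the right-hand side; a
  negative excursion beyond 1e-6 relative aborts with a diagnostic.
* Solver-tolerance refinement changes endpoint survival by < 0.1%, and
  doubling `n_starts` from 24 to 48 changes the ensemble endpoint by
  < 1% (both tested).
* Tests and the acceptance script run reduced problem sizes chosen for
  desk-scale runtimes — typically 1–8 cycle start points and rtol 1e-6
  for qualitative checks, with the strict defaults wherever a
  closed-form comparison demands them; the generator and fitter always
  share settings in recovery studies.

## Limitations

* No explicit cell-cycle arrest: the G2/M checkpoint is a cap on the DSB
  count in the mitotic-catastrophe term, which makes impulse irradiation
  comparatively survivable and is the main driver of the EBRT/RPT
  ordering above.
* No chromosome-level misrepair tracking, senescence state, PBPK drug
  distribution, or microenvironment heterogeneity; dead cells keep
  binding ligand at full receptor capacity.
* All shipped parameter values are scenario placeholders; quantitative
  agreement with any specific cell line requires calibrating against
  that line's data via the provided fitting commands.
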