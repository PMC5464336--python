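# Methods

## Scope and model structure

`teapbpk` simulates the disposition of the four major green-tea catechins
— epigallocatechin gallate (EGCg), epicatechin gallate (ECg),
epigallocatechin (EGC) and epicatechin (EC) — after a single oral dose in
rats and humans, and links the single-catechin models into a ternary
mixture model with no pharmacokinetic interaction between members.

Each catechin is described by a first-order, blood-flow-limited
(perfusion-limited) PBPK model with 13 anatomical compartments: lung,
arterial and venous blood, liver, gut tissue, spleen, kidney, muscle,
skin, adipose, bone, brain, heart, and a lumped rest-of-body. The state
vector additionally carries two gut-lumen pools, a bile transit stage, a
distal intestinal pool, and cumulative urine and feces, for 20 slots in
all. For a perfused tissue *t* with blood flow *Q_t*, volume *V_t* and
tissue:blood partition coefficient *P_t*,

    V_t dC_t/dt = Q_t (C_art − C_t / P_t),

i.e. uptake is instantaneous relative to perfusion and the venous outflow
leaves at C_t / P_t. The lung receives the total venous return (cardiac
output, CO) and vents to arterial blood. Gut tissue and spleen drain into
the liver (portal circulation); the liver's tabulated flow is **total**
hepatic flow, so the hepatic-artery flow is the liver entry minus the gut
and spleen entries — the only reading under which the tabulated flow
fractions balance to 100 % of CO (rat: 115.1 − 13.1 − 2.0; human:
119 − 17 − 2). The single tabulated blood volume is split one third
arterial / two thirds venous, the conventional PBPK partition.

### Oral absorption and the empirical bioavailability factor

At `t = tlag` the dose `D = dose × BW × 1000 µg` is split into an
absorbable lumen pool `F·D`, which drains into gut tissue at the
first-order rate `k_a`, and a non-absorbable pool `(1−F)·D`, which drains
to feces at `k_f`. `F` is an *empirical bioavailability factor* of this
absorption description, not classical absolute bioavailability. The split
conserves mass exactly and keeps the system linear in the dose. One
consequence worth stating plainly: because the whole model is linear, `F`
acts purely as a dose multiplier, so the elasticity (log-normalized
sensitivity) of any concentration with respect to `F` is identically 1.
Published sensitivity analyses of this model family report much larger
values for `F`, which implies a nonlinear `F` implementation in code we do
not have; our tests therefore pin the elasticity-1 property rather than a
magnitude.

The lag is implemented as a delayed impulse (integration starts at
`tlag` with the lumen pools filled), not as a transit compartment; all
outputs before `tlag` are exactly zero.

### Enterohepatic recirculation and elimination

The liver lumps metabolism (glucuronide/sulfate conjugation) and biliary
secretion into one biliary clearance `CL_b`; conjugates are not tracked as
separate species. Biliary output enters a single first-order bile transit
stage with rate `1/R_t` (`R_t` = mean bile residence time), then a distal
intestinal pool where reabsorption (`k_ra`, into gut tissue and hence the
portal circulation) competes with fecal loss (`k_f`). De-conjugation by
gut flora is implicit and complete. `R_t = 0` is honoured as instantaneous
transit. Renal clearance `CL_r` moves drug from the kidney to cumulative
urine. Both clearances reference the *plasma* concentration leaving the
organ: flux = `CL · (C_organ/P_organ) / BLPLR`, because the clearances
were derived from plasma data; the convention is isolated in the RHS
closure so the blood-referenced alternative is a one-line change. (At late
time points the plasma convention makes the net sensitivity of plasma
concentration to BLPLR slightly positive, where a blood-referenced model
gives ≈ −1; this is the main observable difference between the two.)

### Units and scaling

Internally everything is hours, litres, micrograms, kilograms; tissue
density is 1 g/mL so % body weight converts directly to litres. The rat
parameter table is stored in its printed per-minute / mL units and
converted on load. Allometry: `CO = c·BW^0.75` (c = 14.0 rat, 16.1 human,
L/h·kg⁻⁰·⁷⁵), first-order rates `k = k_c·BW^−0.3`, clearances
`CL = CL_c·BW^0.66`. `F` and `k_ac` were fitted per source study in the
original calibration; the registry keys these variants by `study_id`
(`chow2001`, `chow2003`, `lee2002`) with documented defaults. EGC in rats
and ECg in humans were never parameterized; the registry raises a
"parameter not published" error rather than fabricating values, and
accepts explicit user overrides. The rat EGCg `F` is published only as
the range 0.0003–0.038; the upper end is the packaged default and the
range is exported as `RAT_EGCG_F_RANGE`.

## Partitioning chemistry

Tissue:blood partition coefficients can be predicted from fractional
tissue composition (neutral fat `V_n`, phospholipids `V_ph`, water `V_w`):

    P_tb(non-adipose) = [P_ow(V_nt + 0.3 V_pht) + (V_wt + 0.7 V_pht)]
                      / [P_ow(V_np + 0.3 V_php) + (V_wp + 0.7 V_php)]
                      × f_up / (f_ut · BLPLR)

with the adipose variant driven by the vegetable-oil:water distribution
coefficient `D_vow` (which includes the ionized species) and without the
tissue-binding term. Catechins are treated as monoprotic acids (the
relevant pKa are phenolic), so the non-ionized fraction at pH 7.4 is
`1/(1+10^(pH−pKa))`, and `D_vow = 10^(1.115·log10(P_ow) − 1.35) ×
f_nonionized` — the published oil:water regression, which reproduces the
packaged `D_vow` values within 1 % (or half a printed digit).
`f_ut = 1/[1+((1−f_up)/f_up)·0.5]` and
`BLPLR = (hct·P_e + (1−hct)·P_p)/P_p` with hematocrit 0.37. Human BLPLR
equals rat BLPLR by assumption.

The exact compositions used to produce the published PC tables are not
printed, so the packaged PC tables are the canonical simulator input and
the composition-driven path is best-effort (our literature-style
composition table reproduces the rat EGCg adipose coefficient within 10 %
and liver within 15 %). The rest-of-body coefficient is pinned at 1.00 by
convention (unpinnable only for sensitivity perturbation).

## Mixture dosimetry

Mixture members are integrated independently (superposition is structural
and pinned by test to < 1e-10 relative). The integrated tea-catechin-
mixture (TCM) level is the inhibitory-equivalence-weighted sum

    TCM = Σ_i C_i × IEF_i,   IEF_i = IC50_i / IC50_EGCg,

with EROD-inhibition IC50s 1175 (EGCg), 530 (ECg), 1000 (EGC), 2600 (EC)
µmol/L. Note this convention weights *weaker* EROD inhibitors more — the
opposite of usual potency normalization — but it is the convention behind
the published factors 1.00 / 0.45 / 0.85 / 2.21 and is kept as such. The
default table carries the factors rounded to those two published decimals,
because the published dose metrics (e.g. 6.06 and 12.46 mg EGCg-eq/kg)
are reproduced only with the rounded factors. The dose-response summary is
an ordinary least-squares regression of plasma EGCg equivalents on the
administered EGCg-equivalent dose, intercept estimated (not forced through
the origin).

## Evaluation machinery

* **MAPE** `(100/N) Σ |C_obs − C_pred|/C_obs`, with predictions linearly
  interpolated from the dense solver grid onto observation times; < 50 %
  is the conventional two-fold goodness-of-fit band. Undefined at zero
  observations (the CLI drops them from the report).
* **LSP** (elasticity `d ln R/d ln X`) by central differences in log
  space at a ±1 % default perturbation, evaluated by convention on the
  plasma concentration at the final study time. Exact for power laws;
  < 1e-4 error on smooth closed forms.
* **Fitting** of under-determined coefficients (`F`, `k_ac`, …) maximizes
  a Gaussian log-likelihood with the error variance profiled out, i.e.
  least squares — in log space under the default multiplicative-lognormal
  error model (constant CV, suited to data spanning decades), or in
  natural units under the additive option. Bounded trust-region least
  squares with seeded log-uniform multi-starts; deterministic per seed.
* **Fixtures** stand in for concentration-time curves digitized from the
  source publications (not redistributable): the model curve sampled on a
  study-like grid (default: the 0.5–24 h human sampling schedule) with
  multiplicative lognormal noise `exp(σZ)`, `σ = sqrt(ln(1+cv²))`. They
  share the simulator's kinetics by construction, so parameter-recovery
  results demonstrate identifiability and optimizer correctness, not
  model adequacy for real data; they also carry no assay detection limit,
  no inter-subject variability and no sampling-time error.

## Numerical choices

LSODA (stiff-capable) with rtol 1e-8, atol 1e-10 µg and solver evaluation
exactly at the requested output times; all tolerances configurable. The
fitting objective integrates at rtol 1e-6/atol 1e-9 (the objective needs
less precision than reporting). Mass balance — the sum of all 20 state
slots versus the dose — holds to ~1e-15 relative in practice; the audited
bound is 1e-6. Dose proportionality (exact first-order linearity) holds to
solver precision and is tested across a 100-fold dose range. Test and
recovery problem sizes (24 h horizons, 8-point sampling grids, 20
replicates at CV 0.1) mirror the human single-dose study designs.

## Known limitations

Single oral bolus only; no saturable kinetics, transporter effects,
repeated dosing or toxicodynamics. Conjugated metabolites are lumped into
`CL_b`. The simulated human EGCg peak for the 600 mg PE scenario
(0.158 µg/mL) sits ~25 % below the published prediction (0.21), while the
other published scenario peaks are matched within rounding — under strict
dose proportionality those two published values cannot both hold, so the
discrepancy is inherent to reconstruction from the printed record.
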