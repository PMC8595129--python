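# Methods

## Whole-body model

The model is a 14-tissue perfusion-limited (well-stirred) whole-body PBPK
structure. Systemic tissues sit in parallel between the arterial and venous
pools; the lung sits in series and carries total cardiac output. Each tissue
is one homogeneous pool whose venous outflow leaves in instantaneous
equilibrium with the tissue (outflow blood concentration C_t·R_bp/Kp_t).
IV boluses are delivered into the venous pool as instantaneous amounts;
infusions as zero-order input into the venous pool.

Elimination is a single linear systemic clearance acting on the venous
*plasma* concentration. No hepatic/renal split is modelled: the drug class
shows no measurable urinary or fecal excretion of parent drug, clearance is
dominated by tissue uptake and intracellular nuclease metabolism, and the
in-vivo clearance fed to the model is itself an NCA-derived whole-body
value. A direct consequence is the exact identity AUC₀₋∞ = Dose/CL on the
venous plasma curve, which the tests exploit as an oracle.

### Numerics

* Stiff-capable integrator (LSODA), rtol 1e-8 / atol 1e-10, dense reporting
  grid of 0.01 h (a short final step closes the grid exactly at t_end).
  Dose-event times are integration breakpoints.
* The plasma AUC is integrated by the solver itself as an auxiliary state.
  The initial venous mixing transient has a time constant of a few
  thousandths of an hour, so quadrature on the reporting grid would lose
  several tenths of a percent; the solver integral keeps the Dose/CL
  identity to integrator tolerance. Grid-based linear-up/log-down trapezoid
  is the fallback for externally supplied curves.
* Mass balance (Σ compartments + eliminated − dose administered) is checked
  in tests to < 1e-6 relative on random models.
* Terminal extrapolation for AUC₀₋∞ fits a log-linear slope over the final
  decade of decline; a curve already decayed to the integrator floor
  contributes nothing and AUC₀₋∞ = AUC_last.

## Physiology

The underlying study software's physiology database is proprietary and its
values unpublished, so the package bundles its own reference tables (CSV,
one per species) compiled from standard compendia of organ weights and
regional blood flows (Brown et al. 1997; Davies & Morris 1993), lumped to
the 14-tissue topology: monkey 6 kg, rat 0.25 kg, and a 60 kg Chinese adult
male. `rest_of_body` is defined as the remainder after the named tissues so
that volumes close to ≤ body weight (unit density) and systemic flows sum
exactly to cardiac output. Validation enforces: positive volumes,
non-negative flows, lung flow = cardiac output, systemic flow balance within
1%, total volume ≤ 1.05×BW. Any entry can be overridden per species in the
pipeline config. Because elimination is referenced to venous plasma,
predicted AUC is insensitive to the physiological details; they shape only
the curve (Cmax, half-lives, tissue kinetics).

## Partition coefficients

Kp values come from the Rodgers–Single tissue-composition equations,
implemented from the literature:

* **Albumin branch** (neutrals, acids, zwitterions):
  Kpu = f_EW + (X/Y)·f_IW + [P·f_NL + (0.3P+0.7)·f_NP]/Y + Ka_PR·RA_t:p,
  with P = 10^logP, X and Y the 1 + ionized:neutral ratios at intracellular
  (pH 7.0) and plasma (pH 7.4) pH, and Ka_PR back-calculated from fup and
  the plasma lipid fractions (f_NL,p = 0.0023, f_NP,p = 0.0013).
* **Acidic-phospholipid branch** (monoprotic bases, pKa ≥ 7): the
  electrostatic association constant is back-calculated from the
  blood:plasma ratio via the red-blood-cell composition.
* **Polyanion limit**: the drug here is a fully ionized 20-mer
  oligonucleotide; the acid branch is evaluated in its fully ionized limit
  (lipid partitioning suppressed, X/Y → 10^(pH_IW − pH_p)), leaving water
  spaces plus the protein-binding term. With fup = 0.02–0.04 the binding
  term dominates and Kp ≈ (1−fup)·RA_t:p, i.e. 0.05–0.3 — consistent with a
  drug largely confined to extracellular space and protein.

Kp = fup·Kpu, clipped at zero. Plasma is treated as aqueous (no plasma-water
correction). The bundled composition table follows the published rat values,
reused across species as is conventional; the adipose neutral-lipid fraction
is trimmed from 0.853 to 0.846 so water+lipid fractions sum ≤ 1 (the
published row mixes w/w and v/v conventions and sums to 1.007).
Any Kp can be overridden in config, bypassing prediction — the reported
human Vss of 7.89 L is not recomputable from published inputs, though the
default polyanion prediction lands close (7.15–7.4 L).

The class-dependent dispatch (`kp_lukacova`) and the direct branches
(`kp_rodgers_single`) coincide for every class in this implementation; both
names are kept so a configuration can state explicitly which family it uses.

## NCA conventions

* λz: log-linear OLS over all terminal windows of ≥ 3 positive post-Tmax
  points (Tmax excluded); best adjusted r² wins, ties within 1e-4 go to the
  longer window. Non-declining profiles are "not estimable": AUC_last is
  still reported, extrapolated quantities are NaN.
* AUC/AUMC: linear-up/log-down trapezoid; AUC₀₋∞ adds C_last(observed)/λz,
  AUMC₀₋∞ adds C_last·t_last/λz + C_last/λz².
* IV bolus C(0): back-extrapolated log-linearly through the first two
  positive samples (carried flat if not declining). With the first sample at
  0.08 h and a steeply declining distribution phase, the unobserved initial
  area is ~10% of AUC; back-extrapolation reduces the CL recovery error on
  noise-free simulated data to < 1% (tested at 2%).
* BLQ: pre-dose BLQ → 0; embedded BLQ dropped as missing; trailing BLQ
  dropped. The LLOQ (0.18 µg/ml) applies at the assay level in the
  generator.
* Units follow the dosing convention: per-kg doses (µg/kg) give CL in
  ml·kg⁻¹·h⁻¹ and Vss in ml/kg; absolute doses (mg) give L/h and L.

The identities t½ = ln2/λz, CL = Dose/AUC₀₋∞ and Vss = CL·MRT hold exactly
by construction for every result (group *means* of such quantities need not
satisfy them, which is why summary tables can look internally inconsistent
at the second decimal).

## Dose proportionality

Power model ln(value) = α + β·ln(dose), OLS. CI from the t distribution at
the fit's residual df (α = 0.10, i.e. 90% two-sided). Rdnm = r^(β−1) with
r = highest/lowest dose; CI endpoints map through the same transform.
Classification against bounds (0.80, 1.25): CI ⊆ bounds → proportional,
disjoint → nonproportional, else inconclusive. When only mean±SD group
summaries exist, each is converted to a geometric mean under lognormality
(GM = mean/√(1+CV²)) and the fit uses one point per dose — point estimates
are then meaningful but the CI reflects only 1 residual df, so
classification from summaries should rely on an externally reported CI.
Calibration is verified by simulation: 500 seeded replicates of a 3-dose ×
3-subject proportional study with 25% lognormal noise give a mean slope
within 1 ± 0.05 and 86–94% CI coverage.

## Translation

* Allometric clearance: CL_h = CL_m·(BW_h/BW_m)^0.8; the fixed 0.8 exponent
  is the standard choice for macromolecules. Default monkey input is the
  mean of the per-dose NCA clearances.
* HED: dose × Km_animal/Km_human (12/37 for monkey→human), × 60 kg, ÷ safety
  factor 10; reported rounded to the nearest 10 mg, raw value retained.
* Ultrafiltration: fu% = 100·C_buffer/C_plasma and bound% = 100 − fu%, both
  reported explicitly (assay write-ups often label the bound fraction with
  the unbound formula; computing both avoids the ambiguity). A buffer
  concentration above the plasma chamber is flagged as nonphysical but not
  discarded.

## Synthetic data

The generator emulates the study designs, not any particular dataset:
between-subject variability is lognormal on clearance and on a common Kp
scale (default CV 15%), residual error proportional lognormal (default CV
10%) — standard PK variability structure chosen once, since no
variance components were ever published for these studies. Default seed
20211103. What passing tests show is that the *pipeline* recovers known
truth under this structure; they cannot show that real data follow it
(no assay drift, no absorption/injection-duration effects, no
dose-dependent clearance — the generated kinetics are strictly linear even
though the real compound's were judged nonlinear).

Rat tissue truth Kps are config values chosen so the finite-window
(0.17–6 h) tissue AUCs reproduce the observed exposure ranking
(plasma < muscle < heart < lung < stomach < jejunum < fat < liver < spleen
< kidney) under perfusion-limited kinetics; they are deliberately not
partition-coefficient estimates. Low-flow/high-Kp organs (fat, liver)
equilibrate slowly, so ranking survives only with wide gaps between
successive Kps — the defaults (1.5 … 500) encode that. The rat gut
compartment is split 60/40 into jejunum and stomach for this study, and the
homogenate dilution (×11) is applied before the LLOQ check and inverted in
reporting, as in the assay. Rat plasma clearance (100 ml·kg⁻¹·h⁻¹) is a
config default; no rat plasma PK was ever tabulated.

## Problem sizes

Default test and acceptance runs use the study-sized problems directly
(9 monkey subjects, 4 rat kill times, 500 doseprop replicates, ODE systems
of 17 states on grids of ~10³–10⁴ points); the whole suite runs in a few
seconds.

## Known limitations

* Perfusion-limited, linear kinetics only: no target-mediated disposition,
  saturable uptake, lysosomal trapping or carrier-release kinetics for the
  liposome — the model treats the encapsulated drug as one species.
* No oral absorption; IV bolus/infusion only.
* No PBPK parameter estimation: the model predicts from supplied inputs;
  fitting to observed curves is out of scope.
* Physiology tables are single reference individuals; no age/sex scaling.
* Predicted Cmax immediately after a bolus depends on the venous-pool
  mixing convention and the first output time; it is reported but should
  not be over-interpreted (observed early concentrations reflect finite
  injection and sampling times).
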