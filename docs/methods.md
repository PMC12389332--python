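# Methods

This note documents the models behind `esrd_pbpk`: their structure,
assumptions, parameter provenance, numerical choices, and what the synthetic
data do and do not establish about real patients.

## 1. Virtual populations

Two population specifications ship with the package.

**ESRD (Chinese, dialysis-dependent).**  Demographics follow sex-specific
registry models: body height BH(age) is quadratic (males
176.18 − 0.2623·age + 0.0016·age², females 161.15 − 0.1405·age +
0.0005·age²) and body weight is log-linear in height (males
exp(1.9619 + 0.01314·BH), females exp(2.442 + 0.0100·BH)).  Serum
creatinine comes from sex × age strata — males under 50: mean 800 µmol/L
(CV 38.4%), 50+: 674.74 (42.45%); females under 30: 800 (27.85%), 30–60:
666.80 (33.44%), 60+: 533.32 (34.01%).  The published female strata
("greater than 30", "greater than 60") overlap; they are normalised to
disjoint bands with the most specific band winning.  eGFR is computed by the
CKD-EPI 2009 creatinine equation (creatinine divided by 88.4 to mg/dL; the
race coefficient is omitted for a Chinese population).  Blood chemistry
(haematocrit ~33%, HSA ~35 g/L, AGP ~1.05 g/L, with the published CVs),
kidney-size coefficients (baseline 5.7 mL, 1.04 mL/kg, 29.8 mL/m, CV 23.4%,
density 1050 g/L) and prolonged GI residence times (gastric fasted 0.80 h,
colonic drug mean residence 36.72 h male / 50.14 h female) complete the
specification.

**HV comparator.**  Mirrors a built-in Chinese healthy-volunteer population.
Values that are not public (healthy creatinine, blood chemistry, HV GI
times) are physiologically plausible placeholders, marked as such in the
source; the ESRD gastric and colonic times are 2× the HV values, consistent
with the renal-impairment prolongation ratio.

Sampling rules: every "(mean, CV%)" parameter is lognormal with matching
arithmetic mean and CV (positivity; the convention of commercial PBPK
population simulators).  Age is uniform over 20–70 y, 50% female.  Height
and weight get lognormal inter-individual variability of CV 3% and 15%
(placeholders — the source prints none).  The kidney-volume functional form
(baseline + coefficients × BW, BH) is a documented placeholder; kidney
volume is inert in the reduced model.  Each subject consumes a fixed-length
deviate sequence, so two populations sampled with the same seed are
quantile-matched ("common random numbers") — the back-calculation relies on
this to be noise-free.

**OAT3.**  Renal OAT-mediated secretory function scales with eGFR as
OAT% = (1 − e^−(eGFR/43.9)^0.9) × 100%.  At the registry mean eGFR of
10.81 mL/min/1.73 m² the equation evaluates to 24.67% (the analysis it
derives from prints 24.6% — rounded inconsistently with its own equation;
the package reports the equation's value).  ESRD subjects carry the
per-subject eGFR-derived fraction; the population-level DMET profile stores
0.246, which is the same equation at the mean eGFR — the simulator uses the
per-subject value when an individual is supplied, never both (that would
square the reduction).

## 2. DMET profiles

A profile stores, per (target, tissue), the abundance (absolute, or relative
for ileal BCRP) and phenotype activity scores (EM/PM/IM/UM), for HV and for
the final calibrated ESRD configuration.  The effective pathway multiplier
is (abundance × activity)_population / (abundance × activity)_HV, giving the
headline ESRD changes: hepatic OATP1B1/1B3 × 0.25 (locked pair — the probes
cannot separate them, so both change with identical folds), jejunal P-gp
× 0.66, ileal BCRP × 2.0 (0.78 → 1.56 relative abundance), renal OAT3
× 0.246, CYP3A4 unchanged.  Calibration overrides are multiplicative on top
of the stored entries; overriding either OATP1B entry sets both.

## 3. Reduced PBPK model

States are amounts (mg): stomach → jejunum → ileum → colon lumen; jejunal
and ileal enterocytes; liver extracellular and intracellular; a central
compartment (Vss) with a perfusion-limited muscle sub-compartment; and
cumulative elimination per pathway (feces, gut metabolism, hepatic
metabolism, biliary, renal filtration, renal secretion, other).

Flows and assumptions:

* Gastric emptying rate = 1/(gastric residence); each small-intestinal
  segment has a fixed 1.75 h transit; colonic exit = 1/(colonic drug MRT,
  sex-specific).  Lumen → enterocyte absorption is first-order (drug ka);
  colonic absorption is a per-drug fraction of ka (0.02 default; 0 for the
  BCS-III-like rosuvastatin and dabigatran fixtures).
* Enterocytes lose drug apically (efflux back to the lumen) and
  basolaterally (fixed 10 h⁻¹ escape, or the lumped prodrug-conversion rate
  when configured).  Gut CYP3A4 splits 70/30 between jejunum and ileum.
  Both efflux pumps span the small intestine: the P-gp multiplier (an
  "intestinal" change) carries into the ileum at half weight, while jejunal
  BCRP stays at the HV baseline (quarter weight of the ileal clearance)
  because the ESRD BCRP change is ileum-specific.  Without cross-segment
  efflux and restricted colonic uptake, drug effluxed in one segment is
  simply recaptured downstream and the exposure ratio becomes insensitive
  to the efflux multipliers — the inversion would be unidentifiable.
* Liver: extracellular ↔ intracellular exchange with passive permeability
  PS (both directions) plus OATP1B uptake (inward, on unbound extracellular
  drug); intracellular CYP3A4 metabolism, a generic intracellular clearance
  for non-profiled routes, and biliary efflux (P-gp/BCRP), which is terminal
  (no enterohepatic recirculation).  Hepatic plasma-equivalent flow is
  90 L/h × B:P.
* Blood:plasma ratio is individualised from haematocrit: the fixture B:P at
  the 0.45 reference haematocrit fixes the red-cell partition coefficient.
  The unbound fraction is the population value (HV fu, or HV fu × the
  measured ESRD/HV ratio) individualised around the population-mean binding
  protein (HSA or AGP) through a 1:1 binding model — population shifts come
  only from the measured fu ratio, within-population variability from the
  subject's protein level; the two do not double count.
* Renal elimination: unbound filtration fu × GFR with GFR = 7.2 L/h ×
  eGFR/120, plus unbound OAT3 secretion (× the subject's eGFR-derived OAT3
  fraction) and tubular BCRP efflux.
* Muscle is perfusion-limited (50 L/h × B:P, volume 0.4 L/kg, partition
  Kp_muscle); muscle AUC is proportional to plasma AUC through Kp.
* Inhibition: competitive 1/(1 + I_u/Ki) per target; mechanism-based
  inactivation as the steady-state enzyme-amount ratio
  kdeg/(kdeg + kinact·I_u/(KI + I_u)) with kdeg = 0.03 h⁻¹.  Perpetrators
  are static unbound concentrations; simulated perpetrator profiles are out
  of scope.
* A drug with no hepatic interaction at all (no PS, no hepatic clearances)
  bypasses the liver spaces entirely, so degenerate configurations reduce
  exactly to one- or two-compartment systems with closed-form solutions —
  the basis of the solver-verification tests.

Integration: LSODA with rtol 10⁻⁸ and dose-scaled atol, output grid 0.05 h;
multiple doses are integrated piecewise with state re-initialisation.  Mass
balance (compartments + cumulative eliminations = administered dose) holds
to ≤ 10⁻⁶ relative at every output time and is asserted in tests.

**Parameter provenance.**  The five fixture drug models are archetypes of
the microdose-cocktail probes.  Printed anchors are used where available:
atorvastatin ileal BCRP CLint,T 6 µL/min; rosuvastatin renal OAT3 and BCRP
CLint,T 150 µL/min per 10⁶ cells; dabigatran unbound fraction unchanged in
ESRD; rosuvastatin's renal share ≈ 25–28% of absorbed dose in HVs.  Every
other value (fu, B:P, ka, Vss, Kp_muscle, PS, remaining intrinsic
clearances, organ scaling factors, inhibitor constants and exposures) is a
documented, physiologically plausible placeholder.  Consequently the model
is expected to reproduce *pathway-ratio behaviour* (exposure ratios, DDI
directions, recovery of multipliers), not clinical AUCs.

## 4. Non-compartmental analysis

Linear-up/log-down trapezoids: logarithmic rule (c₀−c₁)/ln(c₀/c₁)·Δt on
strictly declining intervals with positive endpoints, linear otherwise
(standard PK convention; the log form is undefined at zero or equal
concentrations).  λ_z is a log-linear regression over post-Cmax suffixes
(≥ 3 points, Cmax excluded) maximising adjusted R²; when no declining
terminal set exists the result is flagged and CL/F falls back to
dose/AUC₀₋t.  CL/F defaults to dose/AUC₀₋∞; the observation window is 72 h.

## 5. Back-calculation

For one probe, the estimator solves f(m) = AUCR_sim(m)/AUCR_obs − 1 = 0 for
the free multiplier m by bisection on ln m over [0.01, 10], with matched
cohorts (common random numbers) making f deterministic and smooth.
Convergence: |pred/obs − 1| ≤ 10⁻³ or log-bracket < 10⁻⁴; no sign change
over the bounds raises a bracket error reporting f at both ends.  The
population AUCR is the ratio of geometric-mean AUC₀₋₇₂ over n = 10 matched
subjects per arm (the clinical cohort size).  The sequential protocol
freezes each estimate before the next step; the final probe only validates
(window 0.8–1.25, inclusive — "falling within" reads inclusive; 0.5–2.0 is
the looser model-validation window).  Protocol order matters and is tested:
estimating ileal BCRP before fixing OATP1B misattributes the uptake signal.

On noise-free synthetic observations the protocol recovers (75.0%, 34.0%,
100.8%) for the (OATP1B, P-gp, BCRP) changes — within one percentage point
of the configured (75, 34, 100); the residual fractions of a point come from
the 10⁻³ early-exit tolerance against each probe's AUCR sensitivity.

## 6. Scenarios

DDI scenarios reuse one sampled cohort for both arms (with/without
perpetrator) and report geometric-mean AUC and Cmax ratios.  A 240 h window
is used in the shipped analyses so the prolonged ESRD terminal phase is not
truncated.  In this reduced model the ESRD-amplified DDI direction holds
when the perpetrator inhibits a pathway whose burden *grows* in ESRD (e.g.
the CYP3A4 probe with itraconazole); inhibiting the pathway that ESRD
itself reduces (statin + OATP1B inhibitor) yields a *smaller* ratio than in
HVs here — a documented divergence in scenario detail from the clinical
analysis, which reported amplification for its specific victim/perpetrator
set.

Muscle exposure is the muscle AUC over 0–72 h (single dose) or the final
interval of a 7-dose daily regimen (≈ steady state); the ESRD/HV ratio
exceeds 1 for all statin fixtures and grows under multiple dosing for the
accumulation-prone ones.

Morris screening uses standard trajectories (4 levels, Δ = 2/3, default
r = 20) on unit-scaled ranges; μ* equals the absolute coefficient for
additive-linear models (asserted).  Of the physiological inputs screened,
serum albumin dominates the CYP3A4 probe's exposure (through binding);
cardiac output, liver density and kidney density are deliberately inert in
the reduced model and screen at μ* = 0, and haematocrit is near-inert for
oral exposure (well-stirred oral AUC is flow-independent).

## 7. Individual-factor selection

The per-subject ratio CL/F_PBPK / CL/F_reference is screened against each
covariate by Spearman correlation (robust at n = 10; Pearson selectable),
retaining p < 0.05.  Survivors enter a LASSO on internally standardised
covariates with λ_min chosen by cross-validation (leave-one-out for n ≤ 12,
else 10-fold), and the non-zero set is refit by ordinary least squares in
the original units — the printed correction equations look unshrunken, so
the refit is the natural interpretation.  Corrected CL/F divides by the
predicted ratio (ratio > 1 means the PBPK model over-predicts clearance).
Duplicated covariate columns are dropped keeping the first; non-positive
predicted ratios are flagged and left uncorrected.

**Synthetic covariate model.**  Genus relative abundances are marginally
lognormal on the percent scale; the two effect-carrying genera co-occur
(shared latent factor, log-scale correlation ≈ 0.9) — without
co-occurrence, a two-covariate signal splits its marginal correlations and
the p < 0.05 screen at n = 10 is underpowered by construction.  The planted
slopes are the published equation's (0.152, 0.0558) on a 1.11 intercept;
ratio noise defaults to 2% of the intercept.  Measured operating
characteristics over 100 seeded replicates: with a noise-free planted ratio
the screen + LASSO stage selects exactly the planted pair in 96% of
replicates (extras vanish because the response lies exactly in the planted
span); at the default 2% noise, exact support drops to ~82% because λ_min
is known to overselect, while the planted pair is retained in ≳ 95% and the
refit slopes stay unbiased within ~2%.  Applying the fitted equation
strictly improves the training-cohort agreement (R²) between corrected and
reference clearance.

## 8. What the synthetic experiments do and do not show

All pipeline-level results here are *self-consistency* demonstrations: the
observations are generated by the same reduced model that the estimators
invert, with no structural mismatch, no residual error in the calibration
inputs, and planted covariate effects.  Passing them establishes that the
machinery is correct (mass balance, closed-form agreement, deterministic
invertibility, selection behaviour), not that the reduced model predicts
clinical exposure in ESRD patients — that would require the proprietary
full-platform drug models and the clinical cohort data, which are out of
scope.  Problem sizes (10 matched subjects per calibration arm, 10-trial ×
10-subject scenario designs, 100-replicate selection studies) are the
package's defaults and match the emulated study design.

## 9. Known limitations

* No saturable (Michaelis–Menten) transport or metabolism — microdose
  linearity is assumed; intestinal P-gp saturation at therapeutic doses is
  explicitly out of scope.
* No enterohepatic recirculation, dissolution/precipitation, metabolite
  cascade beyond one lumped conversion, or dialysis-session kinetics.
* Perpetrators are static unbound concentrations; interaction constants are
  placeholders, so DDI checks are directional only.
* The HV comparator and parts of the drug fixtures are placeholders where
  sources print no value; they are labelled in the code.
* Phenotype frequencies default to all-extensive (activity 1); the
  machinery accepts arbitrary frequencies but no population genetics is
  claimed.
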