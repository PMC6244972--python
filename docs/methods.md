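# Methods

`pkpdkit` implements a translational pharmacokinetic-pharmacodynamic
modelling chain for a bispecific HER2xHER3 antibody: antibody disposition in
cynomolgus monkey, allometric projection to human and mouse, a xenograft
tumor-growth-inhibition model driven by the projected mouse exposure, and
the dose-selection calculus (safety margins against the monkey NOAEL
exposure, receptor occupancy, exposure-matched cross-species dosing) used to
propose first-in-human doses.

## Structural PK model

Drug amounts in a central (`A1`, volume `V1`) and peripheral (`A2`, volume
`V2`) compartment exchange via intercompartmental clearance `Q`.
Elimination from the central compartment is the sum of a linear pathway
(clearance `CL`, lysosomal degradation of IgG) and a saturable
Michaelis-Menten pathway (`Vmax`, `Km`) approximating target-mediated drug
disposition:

    dA1/dt = -(CL/V1) A1 - Vmax C1/(Km + C1) - (Q/V1) A1 + (Q/V2) A2
    dA2/dt =  (Q/V1) A1 - (Q/V2) A2,   C1 = A1/V1

Typical values at a 70 kg anchor: CL 0.0125 L/h, V1 3.17 L, Q 0.0313 L/h,
V2 3.51 L, Vmax 0.500 mg/h, Km 0.219 mg/L.  Units are fixed internally at
mg, L, h, kg.

Doses are instantaneous boluses into the central compartment.  Human i.v.
administration is modelled as a bolus because the reported Cmax-based
occupancies are consistent with Cmax = dose/V1 exactly; mouse i.p.
administration is a bolus with bioavailability 1.0 (no absorption data
exist; the fraction is a parameter of `simulate`).  Integration uses LSODA
with relative tolerance 1e-8 and absolute tolerance 1e-10 mg by default;
every dose time is a hard restart so the state discontinuity never crosses
a solver step.  States more negative than 100x the absolute tolerance are
an error; smaller excursions are clipped to zero.

### Allometric scaling

Flows (CL, Q, Vmax) scale with body weight as `(W/W_ref)^0.75`, volumes
(V1, V2) linearly.  Km is a property of the drug-target interaction and is
carried across species unchanged (the binding epitopes are conserved);
`AllometricRule(scale_km=True)` exposes the alternative.  Scaling the 70 kg
anchor to 0.02 kg reproduces the published mouse set (CL 2.75e-5 L/h, V1
9.06e-4 L, Q 6.88e-5 L/h, V2 1.00e-3 L, Vmax 1.10e-3 mg/h).  Monkey body
weights were not reported; the synthetic monkey studies draw weights
uniformly from 2.5-3.5 kg, a typical adult cynomolgus range (configurable).

## Exposure metrics and dose selection

For a candidate flat dose given once every three weeks (cycle 504 h), a
typical-subject (no variability) single-bolus simulation yields
Cmax = dose/V1, Ctrough = C(504 h), and Cave = AUC_0-inf/504 h.  Receptor
occupancy is `%RO = 100 C/(Km + C)`; the safety margin divides the NOAEL
reference exposure (mean AUC_0-inf 193 g.h/L at 100 mg/kg in the monkey
single-dose study) by the predicted human AUC_0-inf.

Two AUC_0-inf conventions are implemented:

- `method="model"` — the exact model integral: numeric integration until
  C < 1e-6 mg/L, then the analytic linear tail `(A1+A2)/(CL + Vmax/Km)`
  (below Km the system is linear with that total clearance).
- `method="nca"` — a non-compartmental-style estimate from the first-cycle
  profile: the exact area over [0, 504 h] plus `C(504)/lambda_z` with the
  terminal slope taken as the instantaneous log-slope at cycle end.  When
  elimination is still partially saturated at 504 h this apparent slope is
  shallower than the true terminal slope, so the estimate exceeds the model
  integral (by up to ~7% at 1200 mg).

The dose table uses the NCA convention, which is how exposures of simulated
profiles are conventionally summarized and which reproduces every published
table row at 80 mg and above to within 0.3% on AUC and 0.13 percentage
points on occupancy.  Single-cycle exposure only; no accumulation.  Display
rounding follows the published table: AUC to three significant figures,
occupancy to one decimal, margin to the nearest integer.

The Km sensitivity sweep (`km_sensitivity`) recomputes occupancies for Km
values spanning 0.0219-2.19 mg/L with the exposure held at the structural
parameter set — Km enters the occupancy formula only, since Cmax is
unaffected by clearance and the sweep asks how robust the occupancy claim
is to target-affinity uncertainty.  The occupancy criterion (which
concentration metric must clear which occupancy) is a required argument,
because the published threshold statements imply different criteria at the
two quoted Km extremes.  The criterion is evaluated at dose-table display
precision.  One knife edge is documented: at Km 0.219 mg/L the Cave
occupancy at 360 mg computes to 98.95%, fractionally below a literal 99%
cut although it tabulates as 99.0 at the published precision; the resolved
threshold is therefore 360 or 480 mg depending on sub-0.1-point rounding
that the reported precision cannot decide.

## Tumor-growth-inhibition model

Tumor volume `T` (mm^3) grows by a zero-order rate `K_G` (mm^3/h) inflated
linearly over time by a progression factor `lam` (week^-1, converted by
1/168 to h^-1; an exponential form is available behind
`progression="exponential"`), and dies by a first-order rate `K_D` (1/h).
Drug concentration from the mouse-scaled PK model acts twice:

- on growth, indirectly: an effect state `I` with turnover `K_io` is
  produced at a rate inhibited by an Emax term (`EC50` 2.60 mg/L, Emax
  fixed to 1) and multiplies the entire growth flux (`K_G (1 + lam t) I`);
- on death, directly: a stimulatory Emax term with `EC50_KD` 1.02e-5 mg/L
  (stored in mg/L; five orders of magnitude below EC50, so the kill switch
  is effectively binary in the presence of drug).

    dI/dt = K_io (1 - C/(EC50 + C)) - K_io I,          I(0) = 1
    dT/dt = K_G (1 + lam t) I - K_D C/(EC50_KD + C) T,  T(0) = Base

The kill term vanishes without drug, so the untreated tumor follows the
closed form `Base + K_G (t + lam t^2/2)`.  This form is forced by the
published values themselves: a drug-independent first-order death of
0.004/h against a 177 mm^3 baseline would shrink untreated tumors
(0.338 - 0.004*177 < 0), contradicting the observed vehicle growth; the
near-zero EC50_KD is best read as natural attrition that reveals itself
once growth is suppressed.  Two unit labels in the published parameter
table (K_G printed as h^-1, K_D as mm^3/h) are treated as transposed, since
growth is stated to be zero-order and death first-order.  Time zero for the
progression term is treatment start.

`stasis_metric` evaluates T(day 21)/T(0): at most 1 classifies as
"stasis or regression", above 1 as "progression".

### Exposure-matched dose translation

`auc_matched_mouse_dose` finds, by bisection, the weekly mouse dose whose
total AUC_0-inf over n weekly administrations (three by default) equals the
human single-dose AUC_0-inf of a target flat dose.  The matching convention
is a parameter because published cross-species translations rarely state
one.  With the full saturable-clearance model on both sides (default), the
proposed human doses 360/750/900 mg map to 9.7/21.5/26.3 mg/kg — close to
the published 9.5/20/24 mg/kg translations; a linear-clearance-only
convention (closed form `AUC * CL_mouse / n / weight`) gives roughly half
those values, so the published translation evidently included the nonlinear
pathway.  The residual few-percent gap is documented rather than tuned
away: the exact exposure window and convention behind the published numbers
are not recoverable.

## Statistical model

Individual parameters are lognormal: `P_i = P_pop exp(eta_i)`,
`eta ~ N(0, omega^2)` with `omega^2 = ln(1 + (CV/100)^2)` — reported
variabilities are treated as lognormal CVs (PK: CL 13.2%, V1 14.6%; tumor:
Base 20.6%, K_G 55.1%, K_D 35.5%).  Residual error is proportional plus
additive for concentrations (SD 0.108, 0.039 mg/L fixed) and proportional
only for tumor volumes (CV 25.6%); draws are independent across
observations.  Below the 0.078 mg/L quantification limit, the first
observation per subject is imputed at LLOQ/2 = 0.039 mg/L (with the fixed
additive SD of 0.039 mg/L folded into its variance in quadrature) and later
ones are excluded.

## Estimation

The hierarchical marginal likelihood over per-subject random effects is
approximated by the Laplace method: the per-subject joint exponent is
minimized over eta (BFGS) and the curvature at the mode supplies the
Gaussian correction.  This is an approximation in the same family as the
conditional-estimation methods of dedicated pharmacometric software; it is
validated against 32-node Gauss-Hermite quadrature on small problems
(agreement within 0.1 on -2LL).  A naive-pooled mode (eta = 0, no prior)
is the fast default and the vehicle for the simulation-based recovery
checks; with between-subject CVs of 13-15% on the PK side it recovers
population medians with negligible bias.

Optimization works on log-parameters (positivity by construction) inside a
+-12 log-unit box around the initial values.  The default algorithm is
iteratively reweighted least squares: each outer round freezes the
observation weights at the current predictions and solves the weighted
problem with a trust-region Gauss-Newton method (`scipy.optimize.least_squares`).
Freezing the weights matters — weights that move with the predictions
reward inflating them, which produced a 3-9% upward bias on the tumor
baseline in early recovery experiments; the frozen-weight scheme removed
it.  An optional quasi-Newton polish on the exact -2 log-likelihood
(`polish=True`) and jittered multi-start (`n_starts`) are available; the
defaults (no polish, single start from the published initial values) were
chosen because the recovery simulations converge reliably from them and
the exact-likelihood polish changes estimates by less than the replicate
spread at several times the cost.  The residual SD is profiled after the
structural fit; the reported objective is the exact -2LL at the final
estimates.  Standard errors use a sandwich estimator (finite-difference
Hessian and per-subject scores); a seeded bootstrap is deliberately not
the default for cost reasons.

For the PK model, estimation is anchored at 70 kg: each animal's structural
parameters are the anchor scaled allometrically to its body weight, so the
fitted quantities are directly the human-anchored values.  Nested models
are compared by the objective drop against the chi-square quantile at
p < 0.01 (6.63 for one degree of freedom).

In the tumor fit the mouse PK is fixed (the efficacy study had no PK
sampling).  K_io (turnover half-life ~5 h against twice-weekly caliper
measurements) and EC50_KD (saturated at any measurable concentration) are
practically unidentifiable from the study design and are held at their
published values in the default recovery subset (Base, K_G, K_D, EC50,
lam); both can be freed via `estimate`.

## Synthetic studies

The monkey generators emulate the two toxicity-study designs: a single-dose
arm (10/30/100 mg/kg i.v., two animals each, 14 samples over 0.5-1007 h)
and the first week of a repeat-dose arm (n = 6/6/10, ten samples over
0.5-168 h).  Exact sampling times within the reported windows were not
published; the defaults are standard rich-sampling grids and are
configurable.  Sex is recorded but has no effect, mirroring the covariate
model.

The xenograft generator produces three arms of ten mice (vehicle, 2.5,
25 mg/kg weekly i.p. for four weeks), baselines drawn lognormally around
the published 177 mm^3 and truncated by rejection to the reported
108-172 mm^3 range, caliper measurements on a twice-weekly day 0/3/7/10/...
grid, and informative dropout: records stop after the first measurement at
or above 800 mm^3 or at day 68 post-implantation (day 60 after treatment
start).  Caliper volume is `width^2 * length / 2`.

What the generators do not emulate: anti-drug-antibody responses (the
reason only week-1 repeat-dose data were analysed), assay drift,
correlated residuals, or any covariate structure.  Passing recovery tests
therefore demonstrates estimator correctness under the stated statistical
model, not robustness to the violations real preclinical data exhibit.

Note one deliberate inconsistency inherited from the source analysis: the
published baseline estimate (177 mm^3) lies above the reported baseline
range (108-172 mm^3).  Recovery studies therefore disable the truncation
(`XenograftRules(baseline_range=None)`) — with truncation active the
fitted baseline is bounded by 172 mm^3 and a median within 5% of 177 is
unattainable by construction.

## Problem sizes and numerical settings

Recovery studies use 100 replicates per design with seeds spawned from a
single root seed; fits in the recovery loop use the fast LSODA path
(relative tolerance 1e-6) and skip standard errors.  Oracle comparisons
(closed forms, quadrature) run at tolerances 1e-8 to 1e-12.  The pipeline
funnels all randomness through one seeded generator per run and writes
deterministic outputs: re-running a configuration reproduces every report
byte for byte.

## Known limitations

- No mechanistic target binding (full TMDD) or FcRn model; the
  Michaelis-Menten approximation inherits its known low-concentration bias.
- The mouse exposure entering the tumor model is a cross-species
  extrapolation; humanized antibodies bind rodent FcRn more tightly than
  primate FcRn, so true mouse exposure was likely higher and the fitted
  EC50s correspondingly underestimated.  The package reproduces the
  analysis; it cannot repair this structural uncertainty.
- Immune-effector (ADCC) contributions are absent by design — the
  xenograft host is immunodeficient.
- The pooled estimator underestimates parameter uncertainty relative to the
  mixed-effects analysis; RSEs from the sandwich estimator describe the
  pooled fit, not the published hierarchical one.
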