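# Methods

## Structural and statistical model

The package models steady-state efavirenz pharmacokinetics with a
one-compartment, first-order-absorption model under repeated oral dosing
(dose D mg every τ = 24 h). The closed-form superposition solution

C(t) = D·ka / (V·(ka − ke)) · [ e^(−ke·t)/(1 − e^(−ke·τ)) − e^(−ka·t)/(1 − e^(−ka·τ)) ],  ke = CL/V,

is the only structural primitive; when |ka − ke| < 10⁻⁷·max(ka, ke) the
analytic limit C(t) = D·k/V · e^(−kt)·[t(1−E) + τE]/(1−E)², E = e^(−kτ),
replaces it (flip-flop kinetics), and the two branches are tested for
continuity. V/F = 150 L and ka = 0.18 h⁻¹ are fixed population constants;
only apparent clearance CL/F is subject-specific. Bioavailability is
absorbed into the apparent parameters and never modelled separately.

Clearance follows a multiplicative covariate model: a CYP2B6\*18
genotype-specific base (TT/TC/CC, reference TT) scaled by fractional
effects (1 + θ) for CYP2B6\*6 (reference GT), female sex, and centred body
weight (per kg); additional candidates (age, CYP2A6\*9, \*17, ABCB1
1236C/T, ART-only vs ART+anti-TB regimen, CNS-toxicity status) enter the
same way when selected. Categorical covariates contribute one parameter
per genotype level *observed* in the dataset (so a locus observed with only
two levels contributes df = 1). Between-subject variability is a single
log-normal random effect on CL, CLᵢ = CL·exp(ηᵢ), η ~ N(0, ω²), reported
as %CV = 100·√ω²; the residual model is proportional, y = C·(1 + ε),
ε ~ N(0, σ²). σ² is interpreted on the variance scale (a
`prop_err_is_variance` switch records the convention). Inter-occasion
variability is not modelled: the reference design has one occasion and no
IOV estimate exists to emulate.

## Estimation

The marginal likelihood is approximated by FOCE with interaction, in
Laplace form. For each subject the scalar penalised deviance

g(η) = Σⱼ [(yⱼ − fⱼ(η))²/(σ²fⱼ(η)²) + log(σ²fⱼ(η)²)] + η²/ω²

is minimised over η ∈ [−8, 8]; the residual variance uses the individual
prediction f(η) (the "interaction"). The objective is
OFV = Σᵢ [gᵢ(η̂ᵢ) + log ω² + log gᵢ''(η̂ᵢ)], dropping n·log 2π and a log 2
per subject consistently, so only ΔOFV between nested models is
interpreted. The test suite verifies OFV (constants restored) against
64-point adaptive Gauss–Hermite quadrature to within 1% on small
instances, and the closed-form concentrations against a repeated-dose ODE
oracle to 10⁻⁶ relative.

Because the random effect is scalar, all inner problems are solved
simultaneously: a damped Newton iteration vectorised across subjects, with
derivatives by central differences (h = 10⁻⁴), step clipping, bisection-
style backtracking, and a stagnation stop at the finite-difference noise
floor (|Δη| < 10⁻¹⁰). Empirical-Bayes estimates are the converged modes;
their curvatures feed the Laplace term. The outer problem is solved by
L-BFGS-B with numerical gradients on a transformed scale: log for the base
clearances and both variances, log(1 + θ) for categorical fractional
effects, raw scale with a smooth positivity penalty for the continuous
effects (the clearance multiplier is clipped at 10⁻³ with a quadratic
penalty, keeping the objective finite and differentiable near the
boundary). Convergence tolerance is 10⁻⁸ relative OFV change, at most 500
iterations, with up to 3 seeded random restarts on reported failure;
non-convergence is flagged on the result, and a fit is never returned that
is worse than its starting point. Relative standard errors come from the
inverse of a central-finite-difference Hessian of OFV/2 on the natural
scale (relative step 10⁻³); a non-positive-definite or singular Hessian is
reported as a flag with NaN entries, never masked.

Initial values, when not supplied, are moment-based: base clearance from
D/(τ·median concentration) per \*18 stratum, fractional effects 0,
ω² = 0.3, σ² = 0.1.

## Covariate selection

Forward inclusion adds, per round, the candidate with the largest ΔOFV
exceeding the χ²(df) 95th percentile (3.84 for 1 df, 5.99 for 2 df), ties
broken by larger ΔOFV then lexicographic name; backward elimination then
removes, among the forward-added covariates, any whose removal costs no
more than the 99th percentile (6.63 / 9.21), least-damaging first. At the
exact boundary a covariate is removed: retention requires strictly
exceeding the critical value. Candidate fits are warm-started from the
current model's parameters; a candidate whose fit fails is skipped with a
warning, never fatal. Each accepted step records
100·(ω²_before − ω²_after)/ω²_base as the share of between-subject
variance explained. A separate clinical-significance screen flags any
retained covariate whose maximal fractional effect over the observed
covariate range (levels for categorical, range extremes for continuous)
is below 20%. Weight enters linearly per kg; an allometric alternative was
deliberately left out of the selection path to match the reference
parameterisation.

## Synthetic cohort

The generator emulates the reference cohort's structure: n = 185 with
125/185 female; weight from sex-specific normals (61.52 ± 10.06 kg male,
57.92 ± 11.29 kg female) truncated to [35, 120] kg via inverse-CDF
sampling; age likewise (40.2 ± 9.1 / 38.3 ± 8.1 y, truncated 18–75);
genotypes drawn independently per locus from the cohort's empirical
proportions (CYP2B6\*6 57:84:39, \*18 132:47:6, CYP2A6\*9 110:0:24,
\*17 120:15:1, ABCB1 115:16:6); regimen ART+TB with probability 90/185 and
CNS-toxicity status 79/185. Hardy–Weinberg frequencies are available as an
alternative parameterisation. Observations are drawn at Uniform(12, 15) h
post dose (the study design) or at fixed times; concentrations get
per-subject η and per-sample ε, with draws at or below the lower limit of
quantitation (default 0) resampled rather than truncated, which keeps
concentrations positive without biasing the mean at σ² = 0.12 (P(ε ≤ −1)
≈ 0.2%). All randomness flows from one seed through spawned streams;
identical configuration and seed give identical datasets.

What the generator does **not** emulate: linkage between CYP2B6\*6 and
\*18 (no haplotype data exist to calibrate it), adherence, auto-induction
or time-varying clearance, rifampicin induction dynamics, the
8-hydroxy metabolite, and CNS adverse-event dynamics. Passing recovery
tests therefore demonstrate that the estimation machinery is correct under
the stated model, not that the model is correct for real patients.

### Replicate designs and problem sizes

Two designs are packaged. The *study design* (one sample per subject,
12–15 h window) reproduces the reference observation scheme but cannot
separately identify ω² and σ²; it is used for the selection
operating-characteristics experiment (20 replicates, n = 185). The
*recovery design* (3 samples at 2, 13.5, 24 h) identifies both variance
components and is used for the 10-replicate, n = 200 parameter-recovery
experiment. These sizes keep each experiment in the minutes range on one
CPU while leaving Monte-Carlo error well inside the recovery tolerances
for the well-identified parameters; the sex effect is the exception (its
per-replicate SE is ≈ 0.085 by the fitted Hessian, ≈ 82% relative — in
line with the large uncertainty reported for that effect in the reference
analysis), so its recovered median is intrinsically the noisiest quantity
the package reports.

A known operating characteristic follows from the same arithmetic: under
the single-sample study design the sex effect (+22% against ≈ 78% total
log-scale SD) has only ≈ 35% forward-selection power at the 5% threshold,
and weight ≈ 75%, so stepwise selection recovers the exact four-covariate
generating set in a minority of replicates. This is a property of the
design and effect sizes, not of the selection code — the null candidates'
false-inclusion rate sits at the nominal ≈ 5% — and the corresponding
acceptance check is left failing rather than re-tuned.

## Dose simulation

For each of 36 strata (CYP2B6\*18 × \*6 × sex × weight class split at
58 kg) the simulator draws 1000 individuals — weight from the sex-specific
truncated normal conditioned on the class, η, sampling time
Uniform(12, 15) h, and a resampled proportional residual (the 1–4 μg/ml
window refers to measured concentrations, so assay error is included by
default; a switch simulates "true" concentrations instead). Because
concentration is linear in dose, one set of draws serves all candidate
doses (200–800 mg), making the attainment curves exactly monotone in dose;
the recommended dose minimises the proportion outside 1–4 μg/ml, ties
going to the lowest dose (least toxicity exposure; the choice is a package
convention). Strata are simulated on independent spawned streams by
default, with a common-random-numbers mode for monotonicity checks.
Covariates are drawn fresh per stratum rather than resampled from a fixed
185-subject panel.

The computed table reproduces the 200 mg floor for every CYP2B6\*6 TT
stratum robustly across seeds. Outside those rows it can differ from the
previously proposed table (e.g. \*18 TT/\*6 GG strata optimise at
600–800 mg rather than 400 mg under this model); the package ships the
proposed table as reference data and reports cell-by-cell agreement
(`compare_with_reference`) instead of forcing it. Several reference cells
(e.g. 600 mg for \*18 CC/\*6 GG males next to 400 mg for the corresponding
females) are hard to rationalise under any monotone exposure model, which
is why disagreement is reported rather than treated as an error.

## Numerical and degenerate-case conventions

- Observation times must lie in (0, τ]; t = τ is legal (trough).
- Concentrations of exactly 0 are legal data; predictions are strictly
  positive, so the proportional-error deviance stays finite.
- ω² and σ² are bounded below at e⁻¹² during optimisation; noiseless data
  drive the estimates to the bound rather than −∞.
- A categorical covariate constant in a dataset contributes no parameter
  (df 0) and is skipped by selection with a warning.
- An observation equal to the population prediction does *not* give
  η̂ = 0 exactly under interaction: the log-variance term displaces the
  mode by ≈ ω²·∂log f/∂η; the displacement vanishes linearly in ω².
- Omitting a subject-level covariate inflates ω̂², not the individually
  weighted residuals (the EBEs absorb the misfit); diagnostics for that
  misspecification are ΔOFV and ω̂², with IWRES sensitive only when the
  residual model is held fixed.

## Known limitations

Single random effect on CL only (no Ω blocks, no IOV); no SAEM or
importance-sampling estimation; linear weight effect only in the selection
path; no time-varying clearance; the dose table optimises a concentration
window, not a clinical outcome model.
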