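# Methods

## Structural model

Amounts in three compartments — central (plasma, volume `V1`), CSF (`V2`,
fixed at 0.13 L) and peripheral (`V3`) — evolve linearly.  Transfers are
parameterised as clearances: `CL1` (central elimination), `Q2`
(central↔peripheral), and an asymmetric central↔CSF pair in which the
blood→CSF flux uses `Q1·PC` while the CSF→blood flux uses `Q1`.  `PC < 1`
encodes restricted penetration across the blood–CSF barrier.  The asymmetry
is part of the model, not an error: what leaves the central compartment at
rate `(Q1·PC/V1)·A1` arrives in CSF in full, so mass is conserved; only the
two directions have different conductances.

CSF drainage through an external catheter removes CSF (and drug dissolved
in it) at a set daily volume.  We convert the drained volume to a clearance,
`CL2 = drainage (L/day)/24` in L/h, acting on the CSF concentration, so the
elimination rate constant is `k20 = CL2/V2`.  A second reading — taking
`drainage/24` itself as a first-order rate constant in 1/h — is dimensionally
looser but defensible from the way such models are sometimes written down;
it is implemented behind `PKParameters.drainage_as_rate_constant` so the
sensitivity of any conclusion to this choice can be quantified.  At the
evaluated scenarios both readings give the same pass/fail verdicts for all
headline PTA quantities (the literal reading is uniformly more optimistic
about CSF exposure because, with `V2 = 0.13 L`, `CL2/V2` is ~7.7× larger
than `drainage/24`); the acceptance script reports both.

With `CL1 > 0` the rate matrix is strictly stable, so a periodic steady
state exists for any repeated regimen.

## Numerics

Within an infusion-on or infusion-off segment the system is linear with
constant input, so propagation is exact: `x(t) = e^{At}(x0 − xp) + xp` with
`xp = −A⁻¹b`, evaluated by eigendecomposition.  If `A` is singular (the
zero-clearance closed system used in conservation tests) or the eigenbasis
is ill-conditioned (condition number above 1e10), an augmented 4×4 matrix
exponential is used instead.  The steady state solves
`(I − Φ(τ)) x* = g(τ)` where `Φ` is the one-interval propagator and `g` the
interval input response; repeated-dose simulation is retained purely as a
test oracle and for simulating the trial's "sample after the fourth dose"
design, which is simulated literally from a drug-free start rather than
assumed at steady state.  Concentration grids use 1000 evenly spaced points
per interval (`[0, τ)`, the interval being periodic), which resolves fT>MIC
to 0.1% of the interval; no root refinement is done and "above MIC" is a
strict inequality (immaterial for continuous concentrations, fixed for
determinism).  Eigen-solver round-off can produce concentrations of order
−1e-16 at troughs; profiles are clipped at zero.

Continuous infusion of a regimen "D q τh" means the regimen's total daily
dose given at constant rate (2 g q8h → 250 mg/h), matching clinical
convention; it is represented as `infusion_h == interval_h`.

## Virtual populations and targets

Individual parameters are log-normal around the typical values with
`ω² = ln(1 + (CV/100)²)` — exact for a log-normal, so the typical value is
the median and the sampled CV matches the reported CV.  No correlations
between random effects are modelled (none were reported), parameters
without a reported CV (V3, Q2) are fixed, and the CV reported for the fixed
V2 is sampled (the value is listed with the others; a zero-BSV alternative
is a one-line change to `bsv_cv_pct`).  Drainage is a *scenario*, not a
biological trait: PTA evaluations override every virtual patient's drainage
with the scenario value (0/50/150/250 ml/day), and trial simulation draws it
from the observed distribution, a normal (mean 126, SD 81 ml/day) truncated
to [0, 350].

PK/PD targets: 40% fT>MIC in plasma with free fraction 0.98 (2% protein
binding); 50% and 100% fT>MIC in CSF, where drug is taken fully unbound.
PTA is computed on true (noise-free) individual profiles — residual error
is a property of the assay, not of the patient — over a two-fold MIC series
0.03125–64 mg/L, with one shared virtual cohort across the whole grid so
comparisons along any axis are paired.  The default cohort size is 1000, as
in the simulation study the defaults emulate.

A caveat worth knowing: "longer infusion ⇒ higher PTA, continuous infusion
highest" holds for finite infusion durations and for the slow CSF
compartment, but *not* for plasma near the all-or-nothing MIC.  A continuous
infusion has no peak, so a patient whose steady-state free concentration
sits just below the MIC attains 0% fT>MIC where an intermittent infusion of
the same daily dose would still clear the MIC around its peak (at MIC
8 mg/L, 2 g q8h: PTA ≈ 0.92 for continuous infusion versus 1.0 for the 4-h
infusion).  Tests assert the monotonicity only where it is a theorem-like
property.

## Synthetic trial generator

The generator reproduces the design that makes estimation testable without
any private data: 82 patients allocated 42/19/21 to 1 g q8h, 1 g q6h and
2 g q8h (infusion rate fixed at 1 g/h), paired plasma and CSF samples after
the fourth dose at two sparse nominal-time schedules (40/42 split):
mid-infusion, +10 min, +2 h, +4 h after the end of infusion (group 1); end
of infusion, +1 h, +3 h, pre-next-dose (group 2).  "During infusion" is
sampled at the infusion midpoint — the paper-level description does not fix
the time, and the midpoint is the unbiased choice.  Demographics come from
truncated normals with the published moments (age 43.4 ± 13.1 y in [19, 77],
weight 65.2 ± 11.6 kg in [41.5, 100], 50 M/32 F); serum creatinine is
back-solved through Cockcroft–Gault from a creatinine-clearance distribution
(142.6 ± 52.8, [57.3, 355.7] ml/min), so the covariate table is internally
consistent.  Optional switches add sampling-time jitter (SD 5 min is a
realistic clinic value; off by default) and random observation loss (off by
default — the generator emits the full 328+328 observations; the original
trial retained slightly fewer, with no stated mechanism).  Proportional
residual error `y = c(1+ε)`, `ε ~ N(0, 0.349²)`, truncated at zero, is
applied to observations only.

What the generator does **not** emulate: dropouts and regimen switches,
assay quantification limits, correlated random effects, model
misspecification (data are generated from the same structural model that is
fitted).  Passing recovery tests therefore demonstrates estimator
correctness and identifiability at this design — not robustness to
real-world model misfit.

## Estimation

A mixed-effects engine is out of scope; two simpler estimators are provided
with different contracts.

**Naive-pooled ML** (`fit_pooled`): minimises the exact −2 log-likelihood of
a proportional Gaussian error model over the six structural parameters and
σ jointly, on the log scale, with `V2` fixed.  Warm start by
relative-residual least squares; Nelder–Mead polish; multi-start at
0.5×/1×/2× the initial values; the best-so-far objective history, numeric
gradient norm at the optimum and per-start objectives are reported, and
non-convergence is an explicit flag.  On variability-free data it recovers
the generating values to well under 0.1%.  On data with between-subject
variability it is *structurally biased*: pooling a log-normal mixture
flattens the concentration curves, inflates σ to the combined
BSV-plus-residual magnitude (≈ 55–65% here), and biases V1/Q1 upward.  This
is a property of naive pooling, documented rather than patched.

**Iterated two-stage** (`fit_two_stage`): targets the typical (median)
values.  Stage 1 is a pooled log-scale least-squares fit.  Each iteration
then refits per subject the parameters the design identifies individually —
V1 and CL1 from that subject's four plasma points, Q1 from its four CSF
points — and refits V3, Q2 and PC globally.  All fits run on log
concentrations with an analytic offset for `E[ln(1+ε)] ≈ −σ²/2`, σ being
estimated from the within-subject plasma residual spread (within a subject,
plasma residuals contain only measurement noise, because V1 and CL1 absorb
that subject's random effects); the offset-to-variance map is computed by
Gauss–Hermite quadrature with the same quantification floor that is applied
to the data (1e-3 mg/L).  Typical V1, CL1, Q1 are medians of the
per-subject estimates.  The iteration count is fixed at 2: Q1 (per-subject,
dynamics) and PC (global, amplitude) are only jointly weakly identified from
four sparse CSF points per subject, and longer alternation drifts along
that ridge.  At the trial design this estimator's median bias over replicate
studies is a few percent for V1/CL1 and below ±30% for Q1/PC, with the full
bias table printed by the recovery test; its residual CV estimate sits near
the generating 34.9%.

**Bootstrap** (`bootstrap_ci`): subjects resampled with replacement, each
replicate refitted from the point estimate with the same estimator settings
(reduced optimizer budgets — the refits start at the optimum of a nearly
identical dataset); failed refits are dropped and counted; percentile
2.5/50/97.5 intervals.  **VPC** (`vpc`): replicate studies are simulated
under the dataset's own design — same regimens, sampling groups and drainage
covariates, fresh random effects and residual noise — and the observed
5th/50th/95th percentiles per nominal-time bin are compared with the
simulation-based 95% CI of each percentile.  Note that at trough times the
CSF concentration exceeds the decayed plasma concentration (CSF is the slow
compartment); CSF exposure is below plasma exposure on average, not
pointwise.

## Reporting defaults and problem sizes

`run_simulate_pta` evaluates the full factorial {1 g q8h, 1 g q6h, 2 g q8h}
× {0.5, 1, 2, 3, 4 h, continuous} × {0, 50, 150, 250 ml/day} × three
targets × twelve MICs, writes the tidy grid, breakpoint tables at PTA
floors 0.90 and 0.80, and a machine-readable recommendation: among
finite-infusion scenarios with drainage ≤ 150 ml/day, the scenario
maximising (lexicographically) the CSF 50%, CSF 100% and plasma breakpoints,
with longer infusions winning ties.  Every artifact embeds the package
version, a configuration hash and the seeds, and nothing is overwritten
without `force`.  The end-to-end demo runs the whole pipeline at reduced
sizes (200 PTA patients, 50 bootstrap replicates, 200 VPC simulations by
default) and is byte-reproducible for a fixed seed; the test suite runs it
smaller still (100/5/50).  Production-scale choices are 1000 virtual
patients per PTA point and 1000 bootstrap/VPC replicates.

## Known limitations

- No covariate models on parameters (none were retained in the source
  analysis) and no renal-function scaling of CL1; the Cockcroft–Gault
  covariate exists only to make the synthetic cohort internally consistent.
- Linear elimination only; no saturable transport at the barrier, no
  protein-binding kinetics (binding is a fixed 2% free-fraction correction).
- The estimators quantify typical values, not inter-individual variance
  components; ω estimates and shrinkage diagnostics would require the
  mixed-effects machinery that is explicitly out of scope.
- The Q1–PC pair is weakly identified from four CSF samples per subject;
  their recovery bounds (±30%) are honest, not tight.
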