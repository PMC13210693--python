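# Methods

## Scientific problem

In NONMEM-style population PK modelling the residual-error block defines
two distinct objects: the observation equation `Y`, whose EPS/SIGMA
structure fixes the residual variance entering the likelihood, and a
user-chosen scaling factor `W` that only enters the individual weighted
residual, `IWRES = (DV - IPRED) / W`.  Codings that share `Y` share the
likelihood — and therefore parameter estimates, OFV, WRES and CWRESI —
even when their `W` differ, in which case IWRES is merely rescaled.
`ruvdiag` implements this whole pipeline (simulation, FOCE-I estimation,
residual computation, pairwise run comparison) so that the algebra of the
`W`/`Y` distinction can be verified numerically rather than argued.

## Structural model

One-compartment, first-order oral absorption, single dose:

    C(t) = D·ka / (V·(ka − ke)) · (e^(−ke·t) − e^(−ka·t)),   ke = CL/V,

with the flip-flop limit `D·ka·t·e^(−ka·t)/V` substituted when
`|ka − ke| < 1e−8·ka` to avoid catastrophic cancellation (unreachable at
the study parameters, where ke = 0.1/h and ka = 1/h).  Between-subject
variability is log-normal on CL and V: `CL_i = TVCL·exp(η_CL)`,
`V_i = TVV·exp(η_V)`, η ~ N(0, ω²).  Sensitivities to η are analytic;
the identity `∂C/∂η_V = −C − ∂C/∂η_CL` (a consequence of the 1/V
prefactor and ke = CL/V) keeps them cheap and exact.

## Synthetic data

The generator reproduces the study conditions: 500 subjects, one 100 mg
dose, samples at 0.25, 0.5, 1, 1.5, 2, 4, 6, 8, 10, 12, 18, 24 h,
ω² = 0.09 (≈30% CV) on CL and V, and three residual structures —
additive (σ_add = 0.5 mg/L), proportional (CV = 20%), combined
(σ_prop = 0.15, σ_add = 0.5 mg/L, two independent noise terms:
`DV = IPRED·(1 + σ_prop·ε1) + σ_add·ε2`).  Simulated concentrations
below 0.001 mg/L are truncated to that floor; estimation then treats all
records as exact observations (no censoring model).  A single
`numpy.random.default_rng(seed)` stream with a fixed draw order (η
matrix, then the noise matrices) makes a protocol bitwise reproducible.

**What the generator does not emulate:** covariates, dropout, sparse or
unbalanced sampling, multiple dosing, and below-quantification censoring
mechanisms of real assays.  Passing tests therefore demonstrate the
algebraic and estimation properties of residual coding, not robustness
to real-data complications.

**A consequence of the truncation rule worth knowing.**  Under the study
design the population curve spans only ≈0.2–1.5 mg/L, comparable to
σ_add = 0.5, so the floor truncates the lower noise tail of roughly 10%
of additive-dataset observations.  Fitting the correctly specified
additive model to such data attenuates the estimated residual SD to
≈0.46 mg/L and the typical clearance to ≈4.7 L/h — a reproducible bias
of the protocol, not an estimator defect (the proportional dataset,
where the floor never bites, recovers its truths cleanly).  In the
combined model the same mechanism, compounded by the soft trade-off
between the proportional and additive variance components over this
narrow concentration range, inflates the estimated proportional CV to
≈30% against a generating value of 15%.  The recovery tests document
where this bias exceeds three standard errors.

## FOCE-I estimation

Inner problem (empirical Bayes): per subject, minimize

    Σ_j [ log v_j(η) + (y_j − f_j(η))² / v_j(η) ] + ηᵀΩ⁻¹η

with `v_j` evaluated at the conditional prediction (the interaction).
All subjects advance simultaneously via damped Newton steps using the
expected-information Hessian `Σ_j (2/v_j + (v'_j/v_j)²)·J_j J_jᵀ + 2Ω⁻¹`
(symmetric positive definite) and Armijo backtracking on the exact
objective, with a round-off slack of `1e−12·(1+|obj|)` so that progress
at machine precision is not rejected; subjects whose line search hits
that floor are frozen.  Convergence: per-subject gradient norm < 1e−9,
cold start at η = 0, warm starts across outer iterations, and a final
cold-started pass at the optimum so reported η̂ are path-independent.

Outer problem: the linearized marginal −2 log-likelihood

    OFV = Σ_i [ log|V_i| + r_iᵀ V_i⁻¹ r_i ],
    V_i = J_i Ω J_iᵀ + diag(v_ij),   r_i = y_i − f_i(η̂_i) + J_i η̂_i,

excluding the constant `n·log 2π` (reported separately), minimized over
log-transformed parameters (TVCL, TVV, ω²_CL, ω²_V, and the coding's
residual parameters; KA fixed at 1/h) by L-BFGS-B with finite-difference
gradients (relative step 1e−5, chosen above the OFV's numerical noise
floor) followed by a Nelder-Mead polish (fatol 1e−7, xatol 1e−6).  This
two-stage scheme reproduces the reparameterization identity between the
two-EPS and one-EPS variance-style combined codings to ~1e−10 in OFV.
Standard errors come from the central finite-difference Hessian of OFV/2
on the log scale (step 1e−3), inverted and delta-method transformed.

The engine handles balanced designs — every subject on one sampling
grid, possibly with individual doses — which covers the study design;
unbalanced data are rejected explicitly.  Initial estimates for study
runs are the generating values inflated by 20% on the SD scale.

## Residual diagnostics

* `IPRED = f(η̂)`, `IRES = DV − IPRED`, `IWRES = IRES / W(IPRED)`.
* `PRED = f(0)`, `RES = DV − PRED`, and WRES whitens `y − PRED` by the
  lower Cholesky factor of `V₀ = J(0) Ω J(0)ᵀ + diag(v(PRED))`.
* CWRESI whitens `y − (f(η̂) − J(η̂)η̂)` by the Cholesky factor of
  `J(η̂) Ω J(η̂)ᵀ + diag(v(f(η̂)))` — variance at the conditional
  prediction, per the interaction convention.

Lower-triangular Cholesky (forward substitution) is the decorrelation
convention; per-observation values depend on it, summary statistics do
not, and no claim is made that individual values match NONMEM's
(undocumented) internal factorization.  ε-shrinkage is `1 − SD(IWRES)`
with the n−1 denominator.  The SD-style combined coding's W is never
clipped at low IPRED: its divergence there is the phenomenon under
study.

## Comparison study

Nine runs (three codings per dataset), eight pairwise summaries: the six
within-group comparisons against the normalized references (ADD.1,
PROP.1, COMB_VAR1), the COMB_SD-vs-COMB_VAR3 pair, and the cross-dataset
ADD.2-vs-PROP.1 overlay illustrating the hazard of comparing IWRES
across runs with inconsistent W.  Ratio summaries exclude denominators
below 1e−12 (counted); extreme observations are those with |IWRES ratio|
> 5.  Figures are exported as long-format CSV series (run id, IPRED,
residual) rather than rendered images.

## Problem sizes and tolerances in the test suite

Unit and property tests use 20–100 subjects; the whitening oracle uses
1500 subjects simulated from the linearized marginal model (on data from
the full nonlinear model the linearization itself biases per-time WRES
variances — visible as the proportional model's WRES SD ≈ 1.1 — so
identity covariance is only the exact expectation under the linear
model).  The recovery suite fits 200-subject datasets; the combined
coding-concordance suite uses the protocol's 500 subjects.  Exact
identities are asserted at 1e−12 relative or machine equality;
reparameterization identities at 1e−4; stochastic recovery at three
estimated standard errors.

## Known limitations

* Balanced designs only; single dose; no lag time, infusion or
  multi-compartment structure.
* No BQL/M3 censored-likelihood handling — the floor rule is applied to
  the simulated values only, and its estimation bias is documented above
  rather than corrected.
* WRES/CWRESI per-observation values are convention-dependent
  (Cholesky); cross-software comparison should use summary statistics.
* OFV differences across non-nested parameterizations (variance-style
  versus SD-style combined codings) are not a model-selection criterion;
  the study runner reports them but draws no such comparison.
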