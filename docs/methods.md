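# Methods

## Model and estimands

We assume a log-linear structural model for a binary outcome: setting the
exposure to `x` multiplies outcome risk by `exp(beta1 * x)`, so `beta1` is
the log causal risk ratio (CRR). Causal interpretation rests on the three IV
assumptions (instrument associated with exposure; independent of
confounders; no direct path to the outcome) — these are assumptions of the
analysis, not testable properties, and nothing in the software can certify
them.

Two just-identified moment-condition systems are implemented.

**MGMM (multiplicative error).** Moments
`E[y e^{-b1 x} - b0] = 0` and `E[g (y e^{-b1 x} - b0)] = 0`. The first is
linear in the nuisance intercept `b0` (the outcome probability at x = 0), so
`b0` is profiled out exactly, leaving the single SMM g-estimating equation

    f_M(b1) = sum_i y_i exp(-b1 x_i) (g_i - gbar).

The profiling is an algebraic identity, verified in the test suite against a
two-dimensional brute-force solution of the original system (bisection in
`b0` along condition 1, sign changes of condition 2 along that curve).

**LGMM (additive error).** Moments `E[y - e^{b0' + b1 x}] = 0` and
`E[g (y - e^{b0' + b1 x})] = 0`; the first gives
`e^{b0'} = sum(y) / sum(e^{b1 x})`, and substitution yields the profiled
function `f_L` shown in the README. Both systems estimate the same CRR when
the model is correct and confounding is absent, but their finite-sample
root sets differ.

## Numerical evaluation

`f_M` contains `exp(-b1 x_i)` with `|b1|` up to 50: double precision
overflows at exponent ~709, so all sums are carried as (sign, log
magnitude). Positive- and negative-weight terms are reduced separately by
log-sum-exp and combined by log-difference; when the two parts agree to
within an absolute log-difference of 1e-14 (the double-precision limit) the
result is declared exactly zero, which makes sign counting deterministic.
`f_L`'s only unstable piece is the exposure-weighted mean of `g`, which is
shift-invariant and bounded by max|g|, so it is computed with a common
exponential shift and the rest in ordinary arithmetic.

## Identification diagnostic

The scan grid defaults to `[-50, 50]` in steps of 0.1 (1001 points; the
reference design used intervals between 0.1 and 1, and our refinement
experiments show step choice in that range almost never changes the count).
Sign changes are counted after discarding exact zeros; a zero run flanked by
opposite signs therefore counts as one crossing (a grid point landing on a
root is one root, not two or none), while a zero run flanked by equal signs
is recorded as a touching root without a sign change. Classification:
0 changes → NO_SOLUTION, 1 → UNIQUE, ≥2 → MULTIPLE. Each crossing is refined
by bisection to 1e-8 — bisection rather than secant/Brent because bracket
maintenance is the only property that matters on functions this flat.

A dataset with no events (`y ≡ 0`) makes both estimating functions
identically zero. We flag this as *degenerate* and report NO_SOLUTION with
zero informative sign changes rather than "a root everywhere"; the flag is
carried on the scan result so downstream consumers can distinguish it. At
the study's prevalence (5%) and sample sizes this never occurs.

## Point estimation and uncertainty

With roots, the tabulated `beta1` is the smallest-magnitude root (ties
toward the smaller value) — purely a tabulation convention, always
accompanied by the multiplicity flag, which is the primary output; with
multiple roots no point estimate should be trusted. With no root, the
squared scaled moment `(f/n)^2` is minimised (grid argmin plus bounded local
polish of the log magnitude), mirroring what automated GMM software does,
and the positive objective minimum is reported as evidence that no solution
exists.

Standard errors use the standard just-identified GMM sandwich on the
two-moment system, evaluated at the selected root with the profiled
intercept plugged in. When the derivative ("bread") matrix is numerically
singular (condition number > 1e12) or the moment values are not finite, the
SE and CI are reported as absent rather than fabricated — the situation in
which applied software prints an estimate without a confidence interval.

The two-stage comparator fits OLS of `x` on `g`, then a log-link binomial
GLM of `y` on the fitted values. The log-link fit is Fisher scoring with
step-halving: a step is halved until the linear predictor stays below zero
(fitted probabilities < 1) and the deviance does not increase, with a
deviance-change tolerance of 1e-10 and at most 100 iterations; a fit whose
probabilities are driven to the boundary (e.g. separation) raises a
convergence error instead of returning boundary artefacts. Second-stage SEs
condition on the first-stage fitted values (first-stage uncertainty is not
propagated), so the CI is approximate — the common default for this
comparator. The ratio (Wald) estimator divides the log-link slope of `y` on
`g` by the OLS slope of `x` on `g`; its delta-method variance treats the two
stages as independent. For a binary instrument the two-stage and ratio
estimates coincide exactly (verified to 1e-8); for continuous instruments
they agree closely but not identically, and we test near-equality rather
than assert more than the algebra gives.

## Synthetic data generator

The generator emulates a Mendelian-randomization-style design: a continuous
instrument (interpretable as a weighted allele score) explaining a fraction
`rho2` of unit exposure variance, no confounding, and a rare (5%) outcome
generated from the truncated log-linear risk `min{exp(-3 + 0.2 x), 1}`. The
truncation is applied exactly as the model writes it rather than by
rejection sampling; at the
defaults it needs `x >= 15` under a unit-variance normal and never fires in
practice (asserted in tests). What the generator does **not** emulate —
and hence what passing tests cannot show — includes confounding of the
exposure-outcome relation, discrete genotype (0/1/2) instruments, covariate
structure, model misspecification of the log-linear risk, and pleiotropy.
Identification-failure rates on real data may differ for all those reasons;
the diagnostic itself does not depend on the generator.

Seeding: a replicate is reproducible in isolation via
`replicate_seed(master_seed, condition_index, replicate_index)` — the first
32-bit word of `numpy.random.SeedSequence(entropy=master_seed,
spawn_key=(condition_index, replicate_index))`. Results are invariant to
execution order, and identical configurations give bit-identical datasets.

## Study engine and problem sizes

The default lattice follows the reference design (`rho2` in {0.001, 0.002,
0.005, 0.01, 0.02, 0.03, 0.05, 0.1}; `n` in {5,000, 10,000, 20,000,
50,000}) with 1,000 replicates per condition — a desk-scale default for
which a 50% proportion carries a Monte-Carlo SE of about 1.6 percentage
points (the reference used 10,000 replicates, SE ≤ 0.5). Percentages per row
sum to 100; the reported `mc_se` is the binomial SE at the row's modal
category; mean F is unconditional on identification status. The
acceptance-style checks in the test suite use 1,000 replicates for the
tabulated percentages and mean-F cells, 500 for the poor-identification
bound at `rho2 = 0.02, n = 50,000`, and 200 with a 0.5 grid step (within the
reference's stated interval range) for the lattice-wide LGMM-vs-MGMM
ordering; tolerances are three Monte-Carlo standard errors of the
difference between the two estimated percentages (our replication count
plus the reference's 10,000). The `n = 1,000,000` scenario is supported through configuration
but not exercised by default.

## Known limitations

* Single instrument, no covariates, log link only: overidentified moment
  stacks, covariate-adjusted SMMs and logistic-link variants are out of
  scope.
* GMM sandwich SEs (and all CIs) are asymptotic; exactly in the
  weak-instrument regimes this package diagnoses, they can be badly
  anti-conservative. The multiplicity flag, not the CI, is the output to
  act on.
* The sign-change count is grid-based; roots closer together than the grid
  step can be missed. The refinement-stability tests bound how often this
  happens at the default step (≈1% of weak-instrument datasets), and the
  scan is cheap to rerun at finer resolution.
* The ratio-estimator delta CI ignores the covariance between numerator and
  denominator (they are fitted on the same data).
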