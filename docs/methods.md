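# Methods

This note records the modeling conventions, numerical choices, and
limitations behind `bsemfit`. It is the place where design decisions
that the code cannot explain by itself are written down.

## Population models

All generating models are equicorrelated independent-cluster CFA models
built from the 5-item primary-loading block (.70, .70, .75, .80, .80);
10-item factors repeat the block twice, preserving the marginal loading
distribution. Families: A (3 factors × 5 items, correlation manipulated
at .35/.85), B (as A with correlation fixed at .5 plus one cross-loading
per factor at items 5, 9, 15, each loading on the next factor
cyclically), C1–C3 (3 or 6 factors × 5 or 10 items, no cross-loadings),
and D1–D3 (3 or 6 factors × 5 or 10 items with one or two cross-loadings
per factor, placed on the last — highest-loading — items of each block,
targets cycling to the next factor).

**Residual variances.** `ψ_j = 1 − Σ_k λ_jk²` (primary and cross
loadings both subtracted, the factor-covariance cross-term not). Items
without cross-loadings therefore have unit variance, and a cross-loading
item has total variance `1 + 2 λ_p λ_c φ`. Subtracting the full
communality instead would be infeasible for a 0.8 primary with a 0.5
cross-loading. This convention was frozen after verifying that it — and
none of the alternatives — reproduces the published population fit
values for the cross-loading models to three decimals. The D families
additionally keep their residuals at the design cross-loading magnitude
0.5 even when a different magnitude is requested, again because that is
the convention the published population values encode.

**Misspecification.** Dimensionality misspecification reassigns items
to fewer factors. The 3→2 and 3→1 (and 6→2) variants merge intact
factors, order-preserving ({1}, {2,3} for 3→2; {1,2,3}, {4,5,6} for
6→2). The intermediate large-model variants instead split items
contiguously and near-evenly across analysis factors (C1 3→2:
15/15; C2 6→4: 12/6/6/6; C3 6→4: 15/15/15/15) — these assignments were
calibrated against the published population fit values, which intact
merges cannot reproduce. Cross-loading misspecification drops paths
from the head of a round-robin-ordered placement list (first
cross-loading of each factor, then the second of each), so partial
misspecification is spread across factors; the grouped-by-factor
alternative was tested and rejected by the same calibration.
Identification everywhere: latent variances fixed to 1, all loadings
and factor correlations free, no anchor loadings.

## Gibbs sampler

A sweep updates (1) factor scores from their multivariate normal
conditional, (2) per item the intercept and free loadings jointly from
the conjugate normal regression conditional (flat intercept prior), (3)
residual variances from `IG(n/2 − 1, SSR/2)` (the limiting `IG(−1, 0)`
prior, flat in the variance), and (4) the factor correlation matrix by
marginal parameter expansion: an unconstrained latent covariance is
drawn from its inverse-Wishart conditional under a flat prior (degrees
of freedom `n − q − 1`, scale `ξ'ξ`), split into scales and a
correlation matrix, and the scales are pushed into the loadings and
factor scores. This keeps conjugacy with unit latent variances; a
random-walk alternative on Fisher-z correlations was considered and not
needed. The improper residual/covariance priors are the limiting
noninformative forms; software that assigns a proper density to those
hyperparameters can behave differently when variances approach zero.

Chain `c` starts loadings at the prior mean plus an alternating offset
(±0.25, ±0.5, …) so the Gelman–Rubin diagnostic is meaningful; other
blocks start at neutral values (residuals 1, correlations 0, intercepts
at the sample means). Sign indeterminacy under the Diffuse prior is
resolved per draw: any factor whose free loadings average negative is
reflected together with its correlations. PSR is computed on the second
half of each chain for every free parameter and floored at 1 (values
below 1 are Monte Carlo noise); sampling stops when all PSR < 1.10, or
continues on a geometric schedule (+10% of the current length per
check) up to the iteration cap. Defaults match the full study design: 3
chains, 10,000–500,000 iterations, first half burn-in; the desk-scale
runs in the tests and the acceptance script use 3 × 2,000, which the
convergence checks show is ample for these models.

## Discrepancy and indices

The chi-square discrepancy is `N` times the ML fit function with the
divisor-`N` sample covariance. Because the intercepts are saturated
(their posterior is centered on the sample means and carries no
structural information), the index series uses the
covariance-structure-only form, so that `p* = p(p+1)/2` counts exactly
the modeled moments, `q` counts free loadings + factor correlations +
residual variances, and `pD ≈ q` under diffuse priors (≈ 33 for the
correct three-factor model, ≈ p for the independence baseline). The
mean-inclusive form (which equals −2 log LR against the saturated model
and is verified against an observation-wise likelihood oracle) is
available in `chi_square_discrepancy`; building the indices on it would
inflate `pD` by ≈ p without a matching `p*` and push the DevM BRMSEA
away from its frequentist population counterpart — the
covariance-only convention is the one under which the large-n,
diffuse-prior indices converge to the population RMSEA/CFI/TLI, which
the tests assert.

Replicated discrepancies re-simulate a full dataset of size `N` per
draw. The independence baseline has a conjugate posterior
(variance-wise inverse gamma, means normal) and is sampled directly
with the same number of draws; hypothesized and null series are aligned
index-wise from independent runs, which adds Monte Carlo noise to
draw-wise BCFI/BTLI but not to their posterior means. BCFI summaries
are clamped to [0, 1]; BTLI is left unclamped. Credible intervals are
equal-tailed 5%/95% quantiles with linear interpolation. Draws where an
incremental index's denominator vanishes are flagged invalid and
excluded from summaries.

## Frequentist population fits

Population RMSEA/CFI/TLI come from minimizing the ML fit function
against the analytic implied covariance of the generating model, with
`N = 1,000,000` plugged into the index formulas (`χ² = (N−1) F_min`,
`df = p* − q`, null model diagonal with `df₀ = p* − p`). Fitting the
analytic matrix rather than a simulated 1e6-row dataset removes
sampling noise; the published values were produced the other way and
occasionally differ by ~0.001 in the third decimal, which is why the
large-model checks allow ±0.002. Merged-factor models have genuine
local minima (the population-pattern start for the 3→2 model at
correlation .35 converges to a visibly worse optimum), so `fit_ml`
always runs a deterministic 8-point multi-start (anchor start plus
seeded random starts) and keeps the best; optimizer is L-BFGS-B with
the analytic gradient, gradient tolerance 1e-9, correlations bounded in
(−0.999, 0.999) with an eigenvalue guard, residual variances bounded
below at 1e-6 (Heywood protection). Just-identified toys (df = 0) are
reported as perfect fit.

## Harness

Replication `r` of condition `c` draws everything (data, chain seeds,
replicated datasets) from a counter-based stream keyed by
`(base_seed, c, r)`, so results are reproducible in isolation and
independent of execution order or worker count. Non-converged
replications are recorded and replaced by advancing the replication
counter until the requested number of converged solutions is reached
(abort after 5× the target). Rejection rates are proportions over
converged replications; replication SDs use divisor n−1. The ANOVA
effect sizes subsample unbalanced cells to the minimum count with a
fixed seed and decompose type-I sums of squares (equivalent to type III
on the balanced table), flagging η² at 0.0588 and 0.1379. The full 240-
and 72-condition grids are constructed exactly; the 500-replication
production run is supported by the same code path but the shipped tests
and acceptance script run 2–20 replications per condition with 3 × 300
to 3 × 2,000 iteration chains, sizes at which every check here is
stable.

## What the generator does and does not emulate

Data are exactly multivariate normal with zero means, drawn from the
population implied covariance. Passing tests therefore demonstrate the
behavior of the indices under the idealized conditions of the study
design — continuous indicators, no missing data, no excess kurtosis, no
correlated residuals, exact equicorrelation — and say nothing about
robustness to ordinal items, non-normality, or structural features
outside the grids. Sample sizes below ~2q + 3 are rejected because the
latent-covariance update needs a proper inverse-Wishart conditional.

## Known limitations

- The parameter-expanded correlation update is the standard approximate
  marginal-augmentation move, not an exact joint conditional; posterior
  means and the fit indices are insensitive to this at the sample sizes
  studied, but extreme-tail functionals of Φ may not be.
- PPp at large n flags even trivial misfit (by design of the statistic);
  the package reports it alongside the approximate-fit indices rather
  than reconciling them.
- The independence baseline with informative loadings priors is
  conceptually awkward (the null model ignores the prior); BCFI/BTLI
  under strongly informative priors inherit that awkwardness.
- `eta_squared` requires at least one observation per crossed cell and
  silently discards data when balancing; heavily unbalanced designs
  should be summarized with care.
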