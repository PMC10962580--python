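# Methods

This note records the statistical models implemented in `baskex`, the
numerical choices behind them, and what the simulation machinery does and
does not emulate.

## Setting

A single-arm basket trial with K baskets and a binary endpoint:
`Y_k ~ Binomial(n_k, p_k)` independently across baskets.  Hypotheses
`H0: p_k <= q0` vs `Ha: p_k > q0` per basket, with a target rate q1 used
for design.  Efficacy in basket k is declared when
`P(p_k > q0 | D) > Δα`.  All hierarchical modelling happens on the
log-odds scale `θ_k = logit(p_k)`, which avoids boundary problems at
observed rates of 0 or 1 and puts every model on a common footing.

## Analysis models and priors

Default priors (overridable through `ModelConfig`):

| model       | structure | priors |
|-------------|-----------|--------|
| independent | `θ_k ~ N(logit(q0), ν_μ)` per basket | ν_μ = 100 |
| bhm         | `θ_k ~ N(μ, σ²)` | `μ ~ N(logit(q0), 100)`, `σ ~ Half-Cauchy(0, 25)` |
| cbhm        | as bhm, σ² fixed | `σ² = exp{a + b log T}`, default (a, b) = (−7.25, 5.86) |
| exnex       | `θ_k = δ_k M1_k + (1−δ_k) M2_k`, `δ_k ~ Bern(π_k)` | `M1_k ~ N(μ, σ²)`, `σ ~ Half-N(0, 1)`, `M2_k ~ N(−0.62, 4.42)`, π_k = 0.5 |
| mexnex      | as exnex | `σ² ~ Half-N(0, 1)`; π_k from the two-step construction below |
| bma         | pooled subsets, closed form | pooled rate `~ Beta(0.45, 0.55)`, model prior `∝ P_j²` |

The NEX location −0.62 is the log-odds of a plausible response rate of
0.35, and 4.42 is read as a *variance* — the unit-information variance
`1/(0.35 × 0.65)` at that rate.  The literature this prior descends from
is ambiguous about variance vs SD; the variance reading reproduces the
published re-analysis of the motivating trial to within 0.01 on every
posterior mean, which is why it is the default.  `nex_scale_is_sd=True`
switches the reading.  Half-normal scales are standard deviations of the
underlying normal.

### Independent model: exact quadrature

The stratified posterior is one-dimensional, so it is integrated
adaptively on θ over ±12 prior SDs (`scipy.integrate.quad`, split at the
decision threshold and the posterior mode; absolute error far below
1e−8).  Posterior mean, SD and `P(p > q0 | D)` are therefore exact, and
results are cached by `(Y, n, prior, q0)`.  Two consequences: the
independent model never touches MCMC, and any simulation involving only
it is fully deterministic given the seed.

Boundary behaviour worth noting: as the prior variance tends to 0 with
the prior centred at `logit(q0)`, the posterior pins θ at the threshold
itself, so `P(p > q0 | D) → 1/2` (not 0): half of the vanishing mass
sits on either side.

### Homogeneity statistic and the CBHM

`T = Σ_k (O1_k − E1_k)²/E1_k + Σ_k (O0_k − E0_k)²/E0_k` with pooled-rate
expectations `E1_k = n_k p̄`, `p̄ = ΣY/Σn` — the standard Pearson
chi-squared statistic for a 2×K table.  The pooled construction is the
one under which the simulation calibration at the equal planned sample
size reproduces the published coefficients (a, b) = (−7.25, 5.86) to two
decimals, which is how the (undocumented) expected-count convention was
fixed.  Degenerate cases: `p̄ ∈ {0, 1}` gives T = 0; a CBHM fit at T = 0
evaluates σ² at a floor of `log T = log 1e−10`, i.e. essentially complete
pooling, and flags this in the diagnostics.

σ² is plugged into the hierarchical model as a constant, not
re-estimated, and no cap is applied at σ² = 80.

Calibration solves `exp{a + b log H_B} = 1` and
`exp{a + b log H_B̄} = 80`, where H_B is the median T under the
all-sensitive truth and H_B̄ the minimum over heterogeneous
configurations of the median T.  With equal sample sizes the first-j
configurations (j = 1..K−1) exhaust the distinct cases; with unequal
sizes ordering matters and `mode="permutations"` scans all 2^K − 2 mixed
assignments.  For analysis at realized unequal sizes the recommended
default (implemented as `mode="auto"`) calibrates at the rounded mean
size replicated K times: the permutation calibration at realized sizes
produces far larger |a|, |b| and hence near-degenerate thresholds.

### Two-step exchangeability weights (mexnex)

Step 1 excludes basket k when `min_{k'} |p̂_k − p̂_k'| > c`.  The
comparison is done in integer arithmetic
(`|Y_k n_k' − Y_k' n_k| · den(c)` vs `num(c) · n_k n_k'`), with float
cut-offs snapped to the nearest rational with denominator ≤ 10⁶, so grid
values like 1/13 compare exactly and a basket at distance exactly c is
*retained* (strict inequality).  Step 2 builds `Beta(Y_k+1, n_k−Y_k+1)`
posteriors for the retained set S and sets
`π_k = mean_{k'∈S, k'≠k} (1 − h_{k,k'})`, with the Hellinger distance in
closed form through log-beta functions:
`h² = 1 − B((a+a')/2, (b+b')/2) / sqrt(B(a,b) B(a',b'))`.

Edge cases: |S| ≤ 1 leaves no borrowing partner, so every π_k = 0 and
the fit degrades to an all-NEX (independent) analysis.  Excluded baskets
stay inside the joint MCMC with π_k = 0 — the model remains one joint
mixture, whose EX mean and SD are informed only by EX-eligible baskets —
and their posterior indicator probabilities are exactly 0.

The cut-off is chosen pre-trial by `select_cutoff_c`: for each candidate
the decision threshold is re-calibrated, operating characteristics are
simulated over the first-j-sensitive scenario set, and
`x · Power + (1 − x)(1 − Error)` is maximized; exact ties break toward
the smaller (more conservative) c.

### Bayesian model averaging

With one exchangeability component, a model is an EX subset of size ≥ 2
(pooled under a single `Beta(0.45, 0.55)` rate) plus singleton NEX
baskets; subsets of size 0 and 1 both describe the all-independent
model, and the space deduplicates them into a single member, giving
`1 + 2^K − K − 1` models (27 for K = 5).  The deduplicated convention is
the one that reproduces the published model-averaged posterior of the
motivating trial to printed precision; keeping all 2^K allocations does
not.  Marginal likelihoods are conjugate beta functions computed in log
space (binomial coefficients are constant across models and omitted);
weights are normalized by log-sum-exp; per-basket posteriors are finite
beta mixtures whose mean, SD and tail probabilities are evaluated in
closed form.

## The sampler

MCMC models share one Metropolis-within-Gibbs kernel over the EX/NEX
mixture family (the hierarchical models are the π = 1 special case).
Per iteration: (1) random-walk Metropolis on each θ_k under its active
mixture component, step sizes adapted toward 44% acceptance during
burn-in; (2) exact Gibbs draw of each indicator δ_k given θ_k; (3)
conjugate Gibbs draw of μ; (4) random-walk Metropolis on log σ; and (5)
a joint rescaling move `σ' = cσ, θ'_k = μ + c(θ_k − μ)` applied to the
EX-assigned baskets.  The rescaling move is the non-centred update that
carries the chain through the funnel between σ and the θs; without it,
tail probabilities of small baskets under the half-Cauchy prior mix an
order of magnitude more slowly (verified against a near-exact 2-D
quadrature oracle during development).  Indicator weights of exactly 0
or 1 short-circuit, so posterior exchangeability probabilities are
exactly 0/1 at those boundaries.  Posterior exchangeability is reported
as the posterior mean of δ_k.

Default settings: 4 chains × 30 000 iterations, 5 000 burn-in, no
thinning.  On the packaged trial data every per-basket rate passes
split-R̂ < 1.05 and bulk ESS > 400 (typically ESS of several thousand);
breaches raise a warning attached to the diagnostics, never silently.
A fixed seed yields bit-identical draws.

The sampler carries a batch axis: the simulation engine fits thousands
of replicated trials in one vectorized pass with streaming summaries
(posterior mean, SD, exceedance probability, indicator means) instead of
stored draws.  Batched fits default to 2 chains × 5 000 iterations
(2 500 burn-in), leaving ≈ 5 000 retained draws per replicate — Monte
Carlo error on `P(p_k > q0 | D)` of about 0.01, the same order as a
routine single-trial JAGS analysis, which is the regime the decision
thresholds are calibrated in.

## Decision-threshold calibration

`calibrate_delta_alpha` simulates the all-null scenario, fits the
method, and sets Δα from the pooled per-basket posterior probabilities
(basket-wise control) or the per-trial maxima (FWER control).

Discreteness demands care.  Under the exact quadrature the independent
model's posterior probability takes one of n+1 values, so no strict
threshold achieves the nominal level: at n = 13, q0 = 0.15, α = 0.10 the
strict rule rejects either 3.4% or 16.5%.  The rule therefore carries a
tie-break probability γ — trials landing exactly on the threshold atom
reject with probability γ — the classical randomized-test construction,
with (Δα, γ) chosen so the calibration-scenario rejection rate is
exactly α.  For MCMC-based methods the posterior probabilities are
continuous and the tie branch is inert.  Under FWER control γ is solved
by bisection on the empirical per-trial tie counts.  Rules are bound to
the method they were calibrated for and refuse cross-method application.

## Simulation engine

`run_operating_characteristics` reports, per scenario and method:
per-basket rejection % (type I error where `p_k <= q0`, power
otherwise — a marginally effective basket at 0.35 counts as sensitive),
% of trials with correct conclusions in every basket, FWER (defined when
at least one basket is null), and the mean/SD of posterior point
estimates.  `random_truth_study` draws each basket's truth per replicate
uniformly from [0, 0.15] or [0.35, 0.5] with equal probability, and
pools type I error over null basket-draws and power over the rest.

Reproducibility: data generation, fitting and tie-break decisions use
three substreams spawned from the master seed; identical seed ⇒
identical results regardless of batch size, with replicates vectorized
through the sampler's batch axis rather than farmed to worker processes.

## Problem sizes

Defaults chosen for single-CPU work: threshold calibration at 10 000
replicates (seconds for the closed-form methods, minutes for MCMC
methods at the batched settings), CBHM coefficient calibration at
10 000, operating characteristics at 1 000 replicates per scenario for
MCMC methods and 10 000 for closed-form ones.  The test suite verifies
the MCMC-method operating characteristics at several hundred replicates
against three-standard-error bands; full 10 000-replicate tables across
all 16 scenarios and 7 methods are a batch job (hours, embarrassingly
parallel across scenario × method cells).

## What the generator does and does not emulate

Simulated trials are exactly the design's sampling model: independent
binomial counts at fixed n per basket.  Real basket trials depart from
this in ways the engine deliberately ignores: staggered accrual and
interim looks (no adaptive stopping is modelled anywhere), over-running
or under-running realized sample sizes (handled only as fixed unequal
n), patient-level covariates, and non-binary or delayed endpoints.
Passing operating-characteristic tests therefore validate the *decision
procedure under the stated sampling model*, not robustness to protocol
deviations.

## Known limitations

- A single exchangeability component: the mixture cannot represent two
  separate borrowing clusters (its weights sink toward independence
  instead).  The model-space enumeration in `bma` has the same
  single-subset restriction.
- The published re-analysis this package reproduces reports a CBHM
  shrinkage variance (≈ 383) that is consistent with coefficients
  calibrated for the realized unequal sample sizes, while its posterior
  summary table is consistent with the equal-size coefficients
  (σ² ≈ 47); both conventions are implemented (`mode="permutations"` vs
  the equal-size default coefficients), and the two fits are numerically almost
  indistinguishable because both variances already imply near-zero
  borrowing.
- Decision thresholds for the quadrature-exact independent model depend
  on the tie-break construction; different (equally defensible) quantile
  conventions move its operating characteristics by a few tenths of a
  percentage point at n = 13.
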