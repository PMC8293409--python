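# Methods

This note records the models, priors, numerical choices and known
limitations of the package, in the order data flow through the pipeline.

## Viewing geometry

Eyes are modelled as two nodal points at lateral offsets ±i/2 (default
interpupillary distance i = 6.3 cm, chosen because it reproduces the
apparatus' quoted 1.4 °/s mean vergence rate for the 50→25 cm sweep;
the nodal-point/rotation-centre distinction is deliberately ignored).
Coordinates are cyclopean (origin midway between the eyes, x lateral,
z toward the screen); lengths in cm, angles in degrees.  The vergence
angle for symmetric fixation at distance d is 2·arctan(i/2d); the
dichoptic target separation that places the crossed intersection of the
lines of sight at d on a screen at D is i·(D−d)/d.  The fixation
trajectory within a trial is taken to be linear in metric distance
(the apparatus description states distances and duration only); nothing
downstream depends on the interpolation law because only endpoint
vergence angles enter the analysis.

## Observer model

The four-parameter logistic
P("bigger" | x) = γ + (1 − γ − λ)·σ(β(x − α)), with bias α (% size
change; positive x = physical growth, so vergence micropsia predicts
α > 0), linear slope β (> 0, reported on the log₁₀ scale), floor γ and
ceiling lapse λ.  "Detection threshold" means the lapse-free 76 %-point:
β = ln(0.76/0.24)/threshold; the criterion is configurable.  Constancy
predictions use the small-angle power law: a mechanism of strength
g ∈ [0, 1] rescales perceived angular size by ratio^(−g) for a
distance ratio, so the nulling physical change is (ratio^g − 1)·100 %
(+100 % at g = 1 for a halving; equivalently −50 % perceived change for a
fixed retinal size).  The power-law interpolation between the no- and
full-constancy endpoints is this package's construction; only its
endpoints are constrained by the experimental logic.

## QUEST+ engine

Joint gridded posterior over (α, log₁₀β, γ, λ).  Default lattice:
α ∈ [−20, 20] in 0.5 % steps, log₁₀β ∈ [−1.3, 0.3] in 25 steps,
γ, λ ∈ {0, 0.01, …, 0.1}; stimulus domain ±{1, 1.5, …, 20} % (zero is
never presented).  Each trial presents the stimulus minimising expected
posterior entropy over the two outcomes; ties (within 1e−12 bits) break
to the smallest |x|, positive first, making selection deterministic.
Expected entropies are computed with four precomputed likelihood tables
(L, L·log L and complements) so selection is a handful of matrix-vector
products; a likelihood floor of 1e−12 prevents lapse-free grid cells
from being annihilated by a single surprising response.  The engine is
serialisable to JSON for session resumption, and `run_batch` runs many
sessions in lock-step against shared tables (one matrix product per
trial serves all sessions) for simulation studies.  A reduced lattice
(α ∈ [−10, 10] × 17 slopes × 6×6 lapses) is used inside the design
simulation; spot checks showed stimulus placement and bias recovery
close to the full lattice at a fraction of the cost.

## Synthetic experiments

The generator's defaults are the study's conditions: 11 subjects × 200
trials (10 blocks of 20), stimuli from the QUEST+ engine, Bernoulli
responses from the logistic observer.  The design-analysis observer is
bias 0, detection threshold 5 %, lapse rate 2 %.  Between-subject spread
(normal bias, positive-truncated-normal threshold) is available for
recovery studies but is off by default, matching the fixed-parameter
simulation conditions.  Per-subject RNG streams derive from
`default_rng([seed, subject_index])`, so enlarging an experiment never
reshuffles existing subjects.  What the generator does *not* emulate:
fixation instability, retinal slip, diplopia, drop-out, learning or
fatigue — passing tests therefore certify the statistical machinery,
not robustness to those behavioural artifacts.

## Bayesian fits

Individual posteriors: Bernoulli likelihood with α, log₁₀β ~
Normal(0, 100²) and γ, λ ~ Beta(1, 10) truncated to [0, 0.1] (the
package's default lapse bound; configurable via `lapse_max`).
Hierarchical model: αₛ ~ Normal(μ_α, σ_α), log₁₀βₛ ~ Normal(μ_β, σ_β),
subject-level lapses; hyperpriors μ ~ Normal(0, 100²), σ ~
half-Normal(10).  Subject effects are sampled non-centred (z-scores),
which behaves well when σ is near zero — exactly the regime of the
design simulation.

Sampling uses emcee's affine-invariant ensemble (DE + snooker moves,
vectorised log-probability).  Walkers start jittered around a
mode: L-BFGS-B on the individual posterior, or, for the hierarchy,
around a start point assembled from per-subject individual MAPs (the
marginal MAP of the non-centred parameterisation itself is degenerate —
it inflates σ — so the start is built bottom-up instead).  Defaults
retain ≥15,000 draws (matching the study's posterior sample size):
individual fits 32 walkers × (800 warm-up + 2×470) steps with thinning 2;
hierarchical fits 2·ndim+4 walkers × (2000 warm-up + 10×draw-steps)
with thinning 10.  The design simulation uses a reduced schedule
(6,000 draws, 600 warm-up, thinning 14); at these settings the
Monte-Carlo error on a 95 % posterior quantile is well below 0.1 % size
change, the scale that matters against a 1.5 % margin.

Diagnostics: ensemble walkers are individually far shorter than their
autocorrelation time, so per-walker split-R-hat mostly measures
within-walker autocorrelation.  R-hat and ESS are therefore computed
over four walker-group super-chains.  Individual fits are flagged (and
warned about) above R-hat 1.01; hierarchical fits above 1.02, the
package's operating point for desk-scale ensemble runs whose estimates
are stable under reseeding.  Non-convergence is always flagged on the
fitted object, never silent.

Intervals are central quantile intervals with linear (type-7)
interpolation; the one-sided bound at level ℓ is defined as the
directional end of the central (2ℓ−1) interval, so the 95 % directional
bound equals the upper end of the central 90 % interval — the
construction the inferiority test uses.

## Inference

JZS Bayes factor: one-sample default-prior Bayes factor with a
Cauchy(0, √2/2) prior on the standardised effect, computed by adaptive
quadrature of the non-central-t marginal likelihood; BF01 > 1 favours
the null.  Its input is the per-subject posterior-mean biases (point
estimates, the standard usage).  The quadrature error is propagated and
reported.  Inferiority test: pass iff the 95 % directional bound of the
population-bias posterior, in the micropsia-predicted (positive)
direction, falls below the smallest effect size of interest
(default margin 1.43 %).

## Design simulation

For each replicate: n unbiased observers × 200 QUEST+ trials (reduced
lattice), hierarchical fit (reduced draw schedule), record the
population-bias posterior mean and the magnitude of its 95 % directional
bound.  "The design rules out effects greater than m" is operationalised
as: the directional bound falls below m in ≥95 % of replicates; the
reported rule-out margin is the empirical 95th percentile (inverted-CDF
rule) of the bound magnitudes.  The desk-scale default is 100 replicates
— the summary JSON quotes the Monte-Carlo standard error of the mean
bias estimate so that the 100-replicate resolution is explicit.
Replicate r at size n uses `default_rng([seed, n, r])`, making each
(n, replicate) cell reproducible in isolation; fit failures are recorded
per replicate rather than aborting the study.

Two summaries of the same replicates answer different questions and, at
small n, disagree.  (1) *Estimate accuracy*: the spread of the
population-bias posterior means across replicated 5-observer experiments
is small (SD ≈ 0.3–0.5 % size change at the default conditions), so the
experiment's headline estimate essentially never spuriously indicates a
constancy effect approaching 1.5 %.  (2) *Per-replicate inferiority
bounds*: the 95th percentile of the directional bound magnitudes at
n = 5 comes out near 1.8–1.9 %, not below 1.5 % — a minority of
replicates draw one or two subjects whose individual 200-trial bias
estimates land 1.5–2 % from zero, which inflates the σ_α posterior
under the diffuse half-Normal(10) hyperprior and widens the
population-bias interval.  Refitting those tail replicates with a
4×-longer MCMC schedule moves their bounds by only a few hundredths of
a percent, so the tail reflects the conditions, not sampler noise.  The
package computes and reports both summaries; `rule_out_margin` is
defined on the bounds, the stricter reading.

## Degenerate inputs and edge cases

Zero-trial fits return the prior (used as a prior-predictive check);
all-one-response data push the bias posterior outside the tested
stimulus range with a wide interval rather than failing; zero-variance
inputs to the Bayes factor take the analytic limit (BF01 → ∞-favouring
values at t = 0, 0 for a nonzero mean with zero spread); duplicated
subjects in the hierarchy degrade gracefully.  Trial CSVs are validated
row by row (stimulus nonzero, |x| ≤ 20, binary response) with the
offending line number in the error.

## Known limitations

* The hierarchical hyperpriors are this package's documented defaults;
  toolboxes differ here, so third-party population estimates may differ
  in the second decimal even on identical data.
* The ensemble sampler trades per-draw independence for wall-clock
  speed; R-hat at desk-scale settings sits near, not far below, its
  threshold, and the thresholds above reflect that.
* Only the logistic link is implemented (no Weibull/Gumbel variants),
  and the QUEST+ engine is the plain joint-entropy variant (no
  nuisance-parameter marginalisation).
* An importer for externally deposited raw data is limited to the
  package's own CSV schema.
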