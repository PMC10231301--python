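# Methods

## Task design

The stimulus design fully crosses actors × 6 expressions × 3 occlusion
conditions ("masks": lower half covered, upper half covered, none) and
distributes the crossing over six blocks so that, within a block, every
actor contributes exactly one expression shown under all three masks and
every expression is contributed by `n_actors / 6` actors. The construction
is a balanced Latin square over actor groups: actors are dealt round-robin
into six groups (shuffled within gender, and ethnicity when provided, so
blocks stay balanced on actor attributes), and group *g* contributes
expression `(g + b + phase) mod 6` in block *b*, with the emotion order and
phase randomized by seed. When an attribute stratum is not divisible by six
the deal degrades gracefully to within-one-actor balance and logs a
warning; real stimulus sets are rarely perfectly factorial.

Participants complete six rounds, rating one emotion per round ("does this
face express X?") while viewing one block; the emotion-to-round and
block-to-round assignments are permuted jointly and independently per
participant, and the yes/no key mapping is drawn once per participant.
Whether block order should be randomized independently of rating order is
not determined by the design goals; we randomize them jointly per
participant, which preserves every counterbalancing invariant the analyses
rely on.

A trial is *congruent* when the viewed expression matches the rated
emotion; the 6×6 crossing yields 6 congruent pairings (where an incorrect
"no" is a false-negative error) and 30 incongruent pairings (where an
incorrect "yes" is a false positive).

## Synthetic data

The generator stands in for the study's raw behavioural data. Each trial is
a Wiener diffusion with unit diffusion coefficient (the common alternative
scale 0.1 only rescales parameters) between absorbing boundaries 0 and
*a*, starting at *a·z*, with accuracy coding: the upper boundary is the
correct response ("yes" on congruent trials, "no" on incongruent ones).
Drift toward correct is the (emotion × mask) cell value plus a participant
intercept drawn Normal(0, σᵤ²); across-trial variabilities follow the full
DDM convention (drift Normal(v, sv²), start Uniform(z ± sz/2), non-decision
Uniform(t ± st/2)).

Defaults emulate the study conditions: drift 1.5 for unoccluded faces,
reduced under occlusion (study-1 profile: lower 1.05, upper 1.1; study-2
profile: lower 0.8, upper 1.1 — the replication's lower-mask deficit was
roughly twice as large), boundary separation 1.8, unbiased start, 350 ms
non-decision time, sv 0.3, sz 0.05, st 0.1, intercept SD 0.3. These
magnitudes are typical of diffusion fits to fast binary emotion judgments
and place accuracy in the mid-80% range with median RTs near 900 ms.
Attention-check failure rates default to the two studies' observed rates
(72/300 and 26/290); fast-guess contaminants replace a trial with a uniform
RT below 100 ms at rate 0.005.

Paths are simulated by Euler–Maruyama with dt = 1e-4 s by default.
Absorption is tested against continuity-corrected barriers (shifted inward
by 0.5826·σ·√dt, the standard correction for discretely monitored
barriers), which removes the O(√dt) late-passage bias; with the correction,
simulated choice fractions match the closed-form absorption probability and
the first-passage histograms match the series density to within Monte-Carlo
noise at 10⁶ paths. Gaussian increments come from a seeded generator in
large buffers consumed sequentially, so results are independent of buffer
size and exactly reproducible by seed. Paths exceeding a 20 s cap are
resampled and counted.

What the generator does *not* emulate: perceptual properties of real faces,
emotion-specific confusion structure (incongruent drift is a single value
by default), response-key effects, fatigue or learning across rounds.
Passing recovery tests therefore demonstrate that the inference machinery
recovers known generative structure at realistic sizes — not that the
substantive findings would replicate on human data.

## Exclusions

Three pre-registered rules, applied in a fixed order: (1) drop participants
who failed the attention check; (2) drop trials with RT < 100 ms; (3) drop
trials with RT strictly above the top-0.5% empirical quantile
(linear-interpolation definition; ties at the threshold retained), computed
once per dataset over all remaining trials. Whether the original ordering
computed the quantile before or after the fast-RT rule is not documented;
we compute it after, and record the threshold in the exclusion report. The
quantile rule is deliberately not idempotent (re-applying recomputes the
threshold on the trimmed sample); the report's conservation identity
(`out = in − fast − slow`) is checked programmatically. RTs are modelled on
the natural-log scale; the sign-flipped value exists only for plotting.

## Likelihood

The WFPT density at the lower boundary factorizes into a drift-free part
and `exp(−v·a·w − v²t/2)`; the drift-free part is evaluated by the
two-regime series (small-time image-charge sum, large-time eigenfunction
sum), switching to whichever needs fewer terms at the requested relative
tolerance (default 1e-6, capped at 1e-3). The upper boundary uses the
reflection v → −v, z → 1 − z. Drift variability sv integrates in closed
form through that factorization; sz and st are marginalized by
Gauss–Legendre quadrature with node doubling until the result is stable to
the requested tolerance (error if 128 nodes per axis do not suffice).
Decision times at or below zero have density zero by contract. Times are
seconds internally; the I/O layer converts from milliseconds once.

## Hierarchical inference

The default model estimates one drift coefficient per mask condition
(cell-means coding, so pairwise contrasts are computed on draws),
participant intercepts on drift, and shared *a*, *z*, *t*, *sv* across
conditions. sz and st are fixed at zero in the likelihood: outliers are
removed by the pre-registered trims rather than absorbed by uniform tails,
and those ranges are weakly identified at per-cell trial counts of ~18.
A boundary-variant model indexes *a* by mask while keeping drift-by-mask as
covariate, mirroring the follow-up analysis that asks whether mask effects
on responding reflect evidence thresholds rather than accumulation rates.
An "sa" (across-trial boundary variability) parameter is sometimes listed
in this literature's parameter inventories but is nonstandard in the full
DDM; we do not model it.

Priors are weakly informative and config-exposed: Normal(0, 2²) on drift
coefficients; HalfNormal(1) on the intercept SD; Normal(1.5, 1²) truncated
positive on *a*; Normal(0.5, 0.25²) truncated to (0,1) on *z*;
Normal(0.3, 0.25²) truncated non-negative on *t*; HalfNormal(2) on *sv*.

Sampling is Metropolis-within-Gibbs with scalar random walks in blocks
(drift coefficients | intercepts | SD | shared), log- or logit-scale walks
with Jacobians for positive/bounded parameters. Proposal scales adapt by
Robbins–Monro toward ~30% acceptance during a 300-sweep tuning phase plus
the 200 recorded burn-in sweeps, then freeze, so the 4800 retained draws
come from a fixed kernel. Initialization uses closed-form method-of-moments
(EZ-style) estimates from accuracy and correct-RT moments, which puts the
chain near the posterior mode and makes the short burn-in adequate. A
single chain of 5000 with 200 burn-in is the recording protocol;
split-chain R-hat and effective sample size are attached to every fit.
Posterior hypothesis tests use strict inequalities with exact ties counting
one half, so identical columns give probability 0.5. Cross-study
comparisons pair draws by index (independent fits), resampling to a common
length when draw counts differ.

Parameter recovery at the suite's scale (40 participants × 18 trials per
mask cell, the smaller study's congruent-set size) recovers the generating
drift order and detects a 0.7-unit lower-mask deficit with
P(lower > none) < 0.05 in ≥90% of replicates; posterior means carry mean
absolute bias well under 0.15 evidence units/s despite the deliberate
sz/st misspecification.

## Behavioural regressions

Ratings: random-intercept binomial logistic regression, the intercept
integrated out by Gauss–Hermite quadrature (15 nodes by default) and the
marginal likelihood maximized with an analytic gradient; σᵤ is bounded at
zero, where the model collapses exactly to ordinary logistic regression —
on a 2×2 table without clustering the mask coefficient equals the
closed-form log odds ratio, and on clustered data the fit matches
lme4::glmer (nAGQ = 15) to three decimals. Complete separation is detected
and raised, not silently absorbed. Response times: statsmodels MixedLM on
log-RT with mask × accuracy interaction; the simple effects of mask within
correct and incorrect responses are fit on the accuracy subsets, matching
how RT tables in this literature are reported. Confidence intervals:
cluster bootstrap resampling participants (the random-effect unit) with
replacement, 1,000 refits by default, percentile 95% intervals; more than
5% failed refits is an error. Chance tests fit an intercept-only mixed
logistic on correctness per condition (intercept = 0 is chance). The
false-positive cascade runs ratings for all 30 incongruent pairings, RTs
only where a mask coefficient is significant (two-tailed p < 0.05,
uncorrected, matching the reporting convention; Benjamini–Hochberg gating
is available but off by default), and drift fits only where an RT effect is
significant.

## Pipeline

One YAML config and one integer seed drive the full run; stage seeds are
fanned out through SHA-256, so reruns are byte-identical. Study profiles
fix the actor and participant counts (36/300, 18/290) and a `demo` profile
(6 actors, 8 participants) exercises every stage in seconds. Each run
directory contains the design and manifest, schedule, raw and cleaned
trial tables, ground truth, exclusion report, rating and RT regression
tables with bootstrap CIs, posterior draws with manifests (seed, protocol,
acceptance rates, R-hat, ESS), drift summaries with 95% credible intervals,
hypothesis-test listings, a recovery report against ground truth, and a
structured log. `validate_tables` re-checks conservation invariants
(exclusion counts, 6/30 pairing counts, retained draw counts) against the
emitted files. At demo scale some per-emotion cells are too small for
stable bootstrap refits or full interaction designs; those scopes degrade
to point fits or mask-only models with a logged warning rather than
aborting the run.

## Problem sizes in the test suite

The suites use scaled-down but structurally faithful sizes: 20 synthetic
replicates (plus 12 equal-drift nulls) for drift recovery at 40
participants × 54 congruent trials; 10⁶ Euler–Maruyama paths per parameter
set for density validation; 200 replicates at 150 participants × 5 trials
per cell with 149 bootstrap refits for CI calibration (many clusters with
sparse per-cluster data, the regime where cluster-bootstrap asymptotics
apply). The acceptance script reports the same quantities at further
reduced replicate counts. Empirical proportions over finite replicate
suites are judged with their binomial sampling tolerance.

## Known limitations

- The sampler is random-walk Metropolis, adequate at these model sizes but
  not competitive with gradient-based samplers for much larger designs.
- sz and st are simulated but not estimated by default; the resulting drift
  bias at the default magnitudes is small (covered by the recovery suite)
  but grows if the generator's ranges are increased substantially.
- The rejection-based exact first-passage sampler is not implemented; the
  continuity-corrected Euler–Maruyama scheme is the only path generator.
- Incongruent trials share a single drift value by default, so the
  synthetic false-positive cascade exercises machinery, not emotion-specific
  confusion structure.
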