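# Methods

This note documents the models implemented in `fastdisc`, the defaults
and numerical choices behind them, what the synthetic-data generator does
and does not emulate, and the known limitations.

## Choice model and priors

A session is a sequence of binary choices between a smaller immediate
amount A (delay 0) and a larger delayed amount B at delay D_B (days).
Subjective value follows the hyperbolic discount function
V = R/(1 + kD); three robustness families (exponential,
Myerson–Green hyperboloid V = R/(1+kD)^s, modified-Rachlin hyperboloid
V = R/(1+(kD)^s)) are provided in `discounting` for sensitivity analyses
on the model-agnostic normalized area-under-the-curve index. The internal
time unit is days (1 h = 1/24 day), so k has units days⁻¹ and the
half-life of value under the hyperbolic form is 1/k days.

The response rule is a lapse-contaminated probit,
P = ε + (1−2ε)·Φ((V_B − V_A)/α). The acuity α carries commodity units
and absorbs the scale of the value difference — value differences are
deliberately not normalized, so P is invariant under a joint rescaling
of amounts and α. The lapse ε bounds P inside [ε, 1−ε], capturing
value-independent responding. ε and α here are unrelated to the
identically named group-level hypothesis parameters; the two namespaces
are kept separate throughout the code.

Priors: α ~ Exponential(rate 0.1), ε ~ Beta(1.1, 10.9),
log k ~ Normal(log(1/50), 2.5). The log k prior centers on a 50-day
half-life with a very wide (±2.5 on the log scale) spread. The Beta
prior technically supports ε up to 1, but ε ≥ 0.5 makes the rule
non-monotone in value; posterior draws there (prior mass < 0.4%) are
truncated out of the stored posterior and flagged when they exceed 1% of
draws.

## Posterior estimation

Each participant × condition × commodity session is fitted separately
and independently by MCMC using the affine-invariant ensemble sampler
(emcee) with differential-evolution moves, which mix much better than
the plain stretch move on this correlated (log k, α) posterior.
Defaults: 16 walkers, 500 warmup steps, 250 retained steps (4,000
post-warmup draws), initialized in a small ball around a coarse-grid MAP
to keep warmup short. For diagnostics the 16 walkers are grouped into 4
pseudo-chains and split-chain R̂ and effective sample size are computed
with arviz; R̂ > 1.05 on any parameter marks the session non-converged
in the output (flagged, never dropped). All sampler settings are exposed
as configuration. The point estimate of the discount rate is the
posterior median of log k, matching the use of median half-lives in
reporting.

Fit quality is summarized by the area under the ROC curve of the
posterior-mean trial probabilities against the observed choices
(Mann–Whitney construction, ties at 0.5, via scikit-learn); 1 is perfect
prediction, 0.5 chance. Sessions whose responses are all one class have
no defined AUC and report NaN.

## Adaptive design

The measurement protocol fixes B per commodity — 20 for money and music,
10 for food, on the exchange scale 20 money units = 20 song downloads =
10 chocolate bars — and restricts D_B to 19 delays. The published
protocol describes the delays as approximately log-spaced between 1 hour
and 1 year without printing them; we adopt exact geometric spacing
between 1/24 and 365 days. The immediate-amount candidates are the 99
values {B/100, …, 99B/100}; percent granularity is a free design choice.

Each trial maximizes the myopic expected Shannon information gain (the
mutual information between the next response and the parameters under
the current posterior): EIG(d) = H(Σᵢwᵢpᵢ) − ΣᵢwᵢH(pᵢ) over candidate
designs d, posterior draws i, and binary entropy H. This is our own
design-selection criterion — the exact criterion of the adaptive toolbox
used in the original protocol is documented elsewhere and not
reproduced here; both target the same goal of concentrating trials near
the posterior's indifference region. Ties in the gain break to the first
candidate (lowest A, shortest delay).

During a simulated session the interim posterior is a 500-particle
importance-reweighted prior sample with systematic resampling and a
Liu–West shrinkage jitter (a = 0.98) triggered when the effective sample
size falls below half the particle count. The particle filter only
steers design selection; the reported fit always comes from the full
MCMC run on the completed session. In paired-seed simulations adaptive
sessions beat uniform-random designs in both posterior precision and
point-estimate accuracy.

## Group-level hypothesis comparison

The unit of analysis is Δ_{p,c}, the change in log k from control to
fasted for participant p and commodity c ∈ (food, money, music).
Participant scatter around the group-level change locations is Cauchy
with a common scale, making the group fit robust to the extreme Δ values
binary choice data can produce. The six models and their per-commodity
locations are listed in the README; parameter counts (1, 2, 2, 3, 3, 2)
include the scale parameter.

Maximum likelihood uses box-constrained L-BFGS-B with lower bound 0 on
all location parameters (scale bounded below at 1e-6 to avoid the
likelihood singularity on degenerate tables), with 8 starts: one
moment-matched (median / MAD of the table) and 7 random with locations
in [0, 3] and scale in [0.05, 2]; best log likelihood wins, ties to the
smaller parameter norm. Bounds rather than a log transform implement
positivity because the nested-model structure lives on the boundary: on
data with positive out-of-domain mean change, the negative-spillover
fit drives its decrease parameter to exactly 0 and collapses onto the
in-domain fit — a log transform's vanishing gradient stalls short of the
boundary and breaks that equality. The spillover constraint ε > ζ is
enforced by fitting (ζ, gap) with ε = ζ + gap, gap ≥ 0; without it the
model would be exchangeable with a relabeled variant.

AIC = 2n − 2LL and BIC = n·ln(N) − 2LL with N the number of
participants (not the number of Δ cells): recomputing the reference
comparison table's ΔBIC column from its printed LL and n values
reproduces it with ln(50) and not with ln(150), which fixes the
convention. Weights are w_m = exp(−½Δ_m)/Σ exp(−½Δ_i) on either
criterion. Descriptive statistics: percentile bootstrap CIs for the mean
change per commodity, paired Cohen's d (mean of differences over their
SD, ddof 1), and the spillover ratio — 100 × mean out-of-domain Δ over
mean food Δ.

## Synthetic-data generator

`simulate.PopulationConfig` defaults encode the emulated study: 50
participants, 2 conditions × 3 commodities, 35 adaptive trials per
session, baseline log k ~ Normal(log(1/50), 1) per participant ×
commodity with cross-commodity correlation 0.5 (discount rates correlate
across commodities empirically; the exact value is a free, realistic
default), Δ ~ Cauchy(model locations, scale 0.5), session-level α = 0.5
and ε = 0.01. The default generative model is spillover with in-domain
change 2.0 and out-of-domain change 0.5 (ratio 0.25). Generated Δ with
|Δ| > 10 — a factor of e¹⁰ ≈ 22,000 in k — is resampled; this truncation
is a generator-side sanity bound only, and is also what makes the sample
mean of the Cauchy-scattered Δ table well-behaved. The analysis modules
never truncate.

What the generator does *not* emulate: session-order and practice
effects, within-participant correlation of α and ε across sessions,
hunger-questionnaire scores and blood glucose, non-stationary responding
within a session, and any model misspecification (responders are exactly
probit-with-lapse hyperbolic discounters). Passing recovery tests
therefore show the estimation and comparison machinery is correct and
well calibrated under the assumed model, not that the model captures
real behavior.

## Problem sizes and tolerances

The test suite and acceptance script run recovery at sizes chosen to
exercise the claims while staying lightweight: 50 single sessions for
parameter recovery in the tests (30 in the acceptance script), 100
replicate change tables per generating model in the tests (25 in the
script), 20 replicates for the spillover-ratio band, and P = 5 tables
for the optimizer-vs-grid-oracle equivalence at 1e-4 log-likelihood
units. Optimizer boundary equalities are asserted at 1e-6; weight
normalization at 1e-12.

## Known limitations

- No hierarchical pooling across participants; sessions are fitted
  independently by design, so participants with uninformative data fall
  back toward the prior rather than toward the group.
- The hyperboloid curvature s is never fitted; those families exist for
  value-curve summaries only.
- Interim particle posteriors can degenerate for extreme true parameters
  (very fast or very slow discounters at the grid edges); the design
  then stops improving, but the final MCMC fit remains valid.
- Model comparison assumes the Cauchy scatter scale is shared across
  commodities within a model, as in the comparison it reimplements.
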