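# Methods

## Experimental designs being modeled

Two silent-gesture designs over the same two-order space (prenominal vs
postnominal placement of a modifier gesture relative to the noun gesture):

1. **Preference task.** Each participant sees one meaning (descriptive or
   possessive, between subjects), makes one forced choice between the two
   order videos, then rates preference strength on a 0–100 slider anchored
   to the two videos. The *predicted* order is the typologically natural
   one: postnominal for descriptive, prenominal for possessive meanings.
2. **Regularization-learning task.** Four conditions cross meaning type
   with the *naturalness* of the majority order. Training shows two
   meanings eight times each, six times (75%) in the condition's majority
   order and twice in the minority order; the 16 (meaning, order) tokens
   are interleaved by a seeded uniform shuffle (the concrete randomization
   is a design choice here; the entropy and MI statistics depend only on
   counts, so any interleaving yields identical metrics). Testing elicits
   16 binary choices, eight per meaning. Default per-condition sample
   sizes are 47/50/50/53 (natural/unnatural descriptive,
   natural/unnatural possessive).

Meanings are abstract tokens `m1`, `m2`; concrete items never enter any
statistic.

## Regularization statistics

For two variants with counts (a, b), `H = −p log₂ p − (1−p) log₂(1−p)` with
`0·log₂ 0 := 0`, so `H ∈ [0, 1]` bits. Per participant:

* `ΔH = H(pooled test choices) − H(pooled training input)`. The default
  6:2-per-meaning input pools to 12:4, so input entropy is
  `H(0.75) = 0.8113` bits. Negative ΔH is regularization; positive ΔH means
  the output is more variable than the input.
* `MI = H(pooled) − Σ_m p(m) H(V | m)`, the mutual information between
  chosen order and meaning; `ΔMI` subtracts the input MI, which is 0 under
  the default design because both meanings share the same 6:2 split (the
  subtraction is kept explicit so non-default designs with asymmetric
  inputs work unchanged). MI is 1 bit when each meaning is assigned one
  order categorically.

Test-phase rows alone define the output counts; training rows enter only
through the input counts. An empty meaning or an empty table raises rather
than silently returning 0, since a zero-trial conditional entropy is
undefined.

## Monte-Carlo experiment null and z-scores

The null asks what ΔH and ΔMI look like if participants merely
probability-match: each simulated participant draws 8 Bernoulli(0.75)
majority-order choices per meaning. Each of 10,000 runs simulates a full
cohort at the observed per-condition sizes and records the within-run mean
of the statistic (pooled, and per condition). Because both statistics
depend only on the per-meaning majority counts (k₁, k₂), the simulation is
vectorized through a (9, 9) lookup table; 10,000 runs of 200 participants
take about a second.

The z-score of an observed cohort mean is
`(observed − mean of run means) / SD of run means`, with the SD taken at
the relevant sample size (pooled or per condition). The run-level SD is the
natural denominator because the simulation is defined at the level of
whole experiment runs; this choice determines z magnitudes and is the
package's documented convention. Both expectations are cross-checked
against exact enumeration over Binomial(8, 0.75)²:
`E[ΔH] = −0.04787` and `E[ΔMI] = +0.05557` bits. The positive null ΔMI is
pure finite-sample bias — empirical MI of a 16-trial table is nonnegative
even under independence — which is exactly why the null, not 0, is the
reference for observed MI gains.

A note on the input-entropy constant: with a 75/25 input the input entropy
is `H(0.75) = 0.8113` bits, and the enumeration above confirms that the
null mean ΔH of ≈ −0.048 is only consistent with this value.

## Bootstrap confidence intervals

Condition means and between-condition differences get 95% CIs from 10,000
participant-level resamples (independent within each group for
differences). The default interval is percentile; BCa is available via
`method="bca"` (delegated to scipy). Percentile resampling is implemented
as one vectorized numpy indexing operation, making the 10,000 × n case
cheap and exactly reproducible from an integer seed.

## Regression layer

* **Chance tests** on one-choice-per-participant data use the closed-form
  intercept-only logistic model: `β = logit(k/n)`,
  `SE = 1/√(n p̂ (1−p̂))`, two-sided normal p. With a single observation
  per participant a random effect is unidentifiable, so the plain model is
  the mixed model here. `k = 0` or `k = n` raises a separation error
  instead of returning an infinite estimate.
* **Ordinary logistic and OLS** (condition effects, instruction-order
  checks, slider ratings) use statsmodels GLM/OLS behind the package's
  model surface. Slider values are first folded onto the 50–100
  preference-strength scale (x → 100 − x below 50).
* **The learning/naturalness mixed model** is a binomial GLMM with a
  Gaussian random intercept per participant and deviation-coded (±0.5)
  fixed effects for majority-naturalness and meaning type plus their
  interaction. All fixed effects are between-participant, so a random
  slope is not identifiable and the random effect is an intercept. The
  marginal likelihood integrates the random effect by *adaptive*
  Gauss–Hermite quadrature: an inner Newton iteration finds each group's
  posterior mode and curvature, and the quadrature grid is recentered and
  rescaled there (10 nodes by default; 1 node = Laplace). The outer
  optimizer is L-BFGS-B over (β, σ) with σ ≥ 0; at the σ = 0 boundary the
  quadrature is exact and the fit coincides with pooled logistic
  regression. Wald SEs come from a central-difference Hessian of the
  negative marginal log-likelihood (one-sided step for σ near the
  boundary). Model comparison uses likelihood-ratio tests on the marginal
  deviances: each main effect against the intercept-only model, the
  interaction against the two-main-effects model.

Numerical settings: inner Newton tolerance 1e-10 (max 50 steps), outer
gradient tolerance 1e-8 (max 200 iterations), quadrature-refinement check
in the tests requires 10- vs 30-node estimates to agree within 1e-3.

## Synthetic-participant generator

The generator exists so that every analysis has a ground truth; it is a
first-class, tested module, not a fixture.

**Preference task.** Choice of the predicted order is
Bernoulli(θ_condition) with defaults θ_descriptive = 0.625 and
θ_possessive = 0.6375 — the inverse logits of intercepts 0.51 and 0.56,
the effect sizes this paradigm typically produces. The slider value is a
truncated normal (location 80, SD 12) on the chosen video's side, flipped
to the wrong side with probability `p_mismatch = 0.1`; response time is
Normal(12500, 2200) ms, placing ≈10% of participants under the 9678 ms
exclusion threshold (the combined duration of both videos) so the
exclusion path is always exercised. Exclusions remove fast responders and
choice/slider mismatches and log counts per reason plus their overlap. Any
distribution on [0, 100] would serve for the slider; only the folding
transform and the OLS downstream are fixed by the analysis contract.

**Learning task.** Each participant samples one strategy from a mixture:

* *matcher* (w = 0.4): chooses the majority order with probability
  inv-logit(logit(0.75) + u);
* *regularizer* (w = 0.4): inv-logit(λ·logit(0.75) + b·s + u) with λ ≥ 1
  (λ = 2.5 default) and naturalness bias b (default 0; s = ±1 for
  natural/unnatural majority);
* *conditioner* (w = 0.2): assigns one order per meaning (majority order
  to a uniformly chosen one) and follows the assignment with probability
  1 − ε (ε = 0.1).

u ~ Normal(0, σ_u), σ_u = 0.5 by default, is a shared per-participant
log-odds offset. This is the minimal generative model producing the three
behaviors the pipeline must detect — learning above chance, entropy
reduction, MI increase — and the pure-matcher setting with σ_u = 0 *is*
the Monte-Carlo null model, which the tests exploit. Note that σ_u > 0
alone already depresses expected output entropy (heterogeneous p is more
extreme on average), so only the σ_u = 0 matcher is null-typical.

One global seed expands into per-participant substreams via numpy
`SeedSequence` spawning: cohorts are byte-reproducible and participants
independent.

**What the generator does not emulate:** human exclusion rates from real
crowdsourcing (fatigue, satisficing), sequential order effects within the
test phase, item-specific preferences, response-time/choice coupling, and
any influence of participants' native language. Passing tests therefore
demonstrate that the *pipeline* recovers known generative structure at the
published sample sizes, not that any particular human population behaves
like the mixture model.

## Problem sizes

Default analysis settings are 10,000 null runs and 10,000 bootstrap
resamples, matching the reference analyses. The test suite uses 2,000–3,000
resamples/runs where the check is qualitative, 1,000 replications for
error-rate calibrations (LRT type-I in [0.03, 0.07], bootstrap coverage in
[0.93, 0.97]), and 20–40 replicate cohorts for recovery checks; these sizes
make the Monte-Carlo error small relative to each test's tolerance.

## Known limitations

* The GLMM supports a single grouping factor and a random intercept only —
  exactly the identifiable structure of this design; crossed or nested
  random effects are out of scope.
* Entropy/MI formulas generalize to more variants or meanings, but the
  validated design space is 2 × 2; the enumeration oracle requires two
  meanings and ≤ 32 trials.
* BCa intervals can be undefined for degenerate (constant) samples; the
  percentile method is the default for that reason.
* The typology constants are point-in-time counts from a spoken-language
  survey; they carry no phylogenetic or areal controls, and the
  experiment-vs-typology comparison is descriptive, not inferential.
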