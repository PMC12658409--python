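# gesturebias

Simulation and analysis pipeline for silent-gesture experiments on
noun-phrase word-order biases.

## The scientific problem

In spoken-language typology, adjectives tend to follow the noun and
genitives tend to precede it, breaking the otherwise strong tendency toward
harmonic (same-side) ordering of noun-phrase dependents. Silent-gesture
experiments probe whether category-specific ordering biases — postnominal
for *descriptive* meanings, prenominal for *possessive* meanings — operate
in individual minds: once when people improvise an order with no linguistic
system in place (a one-shot forced choice plus a preference slider), and
once when they learn a miniature gesture language whose order is variable
(75% majority / 25% minority training input followed by 16 binary test
choices).

This package implements the complete analysis stack for both designs,
together with a synthetic-participant generator so that every stage is
testable without human data:

* **Regularization statistics.** Variant entropy
  `H(V) = −Σ p(v) log₂ p(v)` over the two orders (in bits, 0–1 for two
  variants); per-participant entropy change
  `ΔH = H(output) − H(input)`, where the 6:2-per-meaning training input has
  `H(0.75) = 0.811` bits; and lexical conditioning as mutual information
  `MI = H(V) − H(V | meaning)`, which is 1 bit when the two meanings get
  the two orders categorically.
* **Monte-Carlo experiment null.** 10,000 simulated experiments in which
  participants probability-match the 75/25 input (8 Bernoulli(0.75) draws
  per meaning), giving the null mean and SD of run-level mean ΔH and ΔMI
  and hence z-scores for observed cohort means — plus an
  exact-enumeration oracle for the null expectations
  (E[ΔH] = −0.0479, E[ΔMI] = 0.0555 bits).
* **Bootstrap CIs** (percentile or BCa, 10,000 resamples) for condition
  means and between-condition differences.
* **Regression layer.** Closed-form intercept-only logistic chance tests
  (β = logit(k/n), Wald SE = 1/√(n p̂ (1−p̂))), ordinary logistic and OLS
  models via statsmodels, and a random-intercept logistic mixed model with
  deviation-coded (±0.5) fixed effects fit by adaptive Gauss–Hermite
  quadrature, compared by likelihood-ratio tests.
* **Typology tables.** Packaged spoken-language counts of
  adjective/genitive order and their harmony cross-table, with the
  postnominal proportions used to compare experimental choices against
  typology.

## Worked example

Simulate a default learning-experiment cohort (200 participants at the
per-condition sizes 47/50/50/53; a mixture of probability matchers,
regularizers and lexical conditioners) and run the full analysis:

```python
import gesturebias as gb
from gesturebias.pipeline import analyze_exp2, render_report

trials = gb.simulate_exp2_experiment(seed=42)
report, metrics = analyze_exp2(trials, n_runs=10_000, n_boot=10_000, seed=42)
print(render_report(report))
```

prints (abridged):

```
== Change in entropy ==
simulated null: mean -0.0477, sd 0.0132 (10000 runs)
overall: mean -0.2211 [-0.2699, -0.1720], z = -13.13
...
== Change in MI ==
simulated null: mean 0.0556, sd 0.0052 (10000 runs)
overall: mean 0.1531 [0.1202, 0.1888], z = 18.81
...
== Learning model (majority order) ==
intercept: beta = 1.606, SE = 0.099, z = 16.19, p = 6.42e-59
...
no reliable naturalness preference (intercept CI covers 0)
```

Read: the cohort's mean entropy change (−0.221 bits) sits 13 run-SDs below
the probability-matching null (−0.048), so the simulated learners
regularize far beyond what reproducing the 75/25 input would produce; mean
MI rises well above the null's finite-sample bias (0.056), showing lexical
conditioning; the learning model's positive intercept (log-odds of choosing
the majority order) confirms learning above chance; and because the
generator has no naturalness bias by default, the naturalness intercept's
CI covers 0.

The same pipeline is scriptable from the shell:

```bash
gesturebias simulate-exp2 --out out --seed 42
gesturebias analyze-exp2 out/exp2_trials.csv --out out --seed 42
gesturebias report out/exp2_report.json
```

Every command writes a `manifest.json` with seeds, config and file digests
so runs are exactly reproducible.

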