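"""Uncertainty machinery: bootstrap CIs, the Monte-Carlo experiment null,
an exact-enumeration oracle for its expectations, and z-scores.

The null model asks what entropy change and mutual-information change look
like when participants merely probability-match their 75/25 training input:
each simulated participant draws 8 Bernoulli(0.75) majority-order choices
per meaning (16 total), the statistic is computed against the 12:4 input,
averaged within each simulated experiment run, and the distribution of run
means provides the reference mean, SD and z-score for an observed cohort
mean. Because each statistic depends only on the two per-meaning majority
counts (k1, k2), runs are vectorized through a (9, 9) lookup table and the
exact expectation is available by enumerating Binomial(n, p)^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import DesignConfig, EXP2_SAMPLE_SIZES

__all__ = [
    "BootstrapResult",
    "NullDistribution",
    "bootstrap_mean_ci",
    "bootstrap_diff_ci",
    "simulate_null",
    "exact_null_expectation",
    "z_score",
]


@dataclass(frozen=True)
class BootstrapResult:
    point_estimate: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    method: str

    @property
    def covers_zero(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


def _check_method(method: str) -> str:
    if method not in ("percentile", "bca"):
        raise ValueError("method must be 'percentile' or 'bca'")
    return method


def bootstrap_mean_ci(
    values,
    n_boot: int = 10_000,
    seed: int = 0,
    method: str = "percentile",
    conf_level: float = 0.95,
) -> BootstrapResult:
    """95% bootstrap CI around a sample mean, resampling participants with
    replacement."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d sample of length >= 2")
    _check_method(method)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - conf_level) / 2.0
    if method == "percentile":
        idx = rng.integers(0, x.size, size=(n_boot, x.size))
        means = x[idx].mean(axis=1)
        lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    else:
        res = stats.bootstrap(
            (x,), np.mean, n_resamples=n_boot, confidence_level=conf_level,
            method="BCa", rng=rng,
        )
        lo, hi = res.confidence_interval.low, res.confidence_interval.high
    return BootstrapResult(float(x.mean()), float(lo), float(hi), n_boot, seed, method)


def bootstrap_diff_ci(
    group_a,
    group_b,
    n_boot: int = 10_000,
    seed: int = 0,
    method: str = "percentile",
    conf_level: float = 0.95,
) -> BootstrapResult:
    """95% bootstrap CI for mean(a) - mean(b), resampling each group
    independently."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need length >= 2")
    _check_method(method)
    rng = np.random.default_rng(seed)
    alpha = (1.0 - conf_level) / 2.0
    if method == "percentile":
        means_a = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
        means_b = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
        diffs = means_a - means_b
        lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    else:
        res = stats.bootstrap(
            (a, b),
            lambda u, v, axis=-1: np.mean(u, axis=axis) - np.mean(v, axis=axis),
            n_resamples=n_boot, confidence_level=conf_level, method="BCa",
            rng=rng, paired=False,
        )
        lo, hi = res.confidence_interval.low, res.confidence_interval.high
    return BootstrapResult(
        float(a.mean() - b.mean()), float(lo), float(hi), n_boot, seed, method
    )


def _entropy_of_p(p: np.ndarray) -> np.ndarray:
    """Binary entropy in bits, vectorized, with 0 log 0 := 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    m = (p > 0) & (p < 1)
    pm = p[m]
    out[m] = -(pm * np.log2(pm) + (1 - pm) * np.log2(1 - pm))
    return out


def _statistic_table(config: DesignConfig, statistic: str) -> np.ndarray:
    """Value of the statistic for every (k1, k2) majority-count pair.

    k1, k2 are the numbers of majority-order choices among the
    n_test_per_meaning test trials of each meaning.
    """
    n = config.n_test_per_meaning
    k = np.arange(n + 1)
    k1, k2 = np.meshgrid(k, k, indexing="ij")
    h_pooled = _entropy_of_p((k1 + k2) / (2 * n))
    if statistic == "delta_h":
        h_input = _entropy_of_p(np.array([config.majority_proportion]))[0]
        return h_pooled - h_input
    if statistic == "delta_mi":
        h_cond = 0.5 * (_entropy_of_p(k1 / n) + _entropy_of_p(k2 / n))
        return h_pooled - h_cond  # input MI is 0: identical per-meaning splits
    raise ValueError("statistic must be 'delta_h' or 'delta_mi'")


@dataclass(frozen=True)
class NullDistribution:
    """Run-level means of a statistic under the probability-matching null."""

    run_means: np.ndarray
    statistic: str
    sample_sizes: dict[str, int]
    p_majority: float
    seed: int
    condition_run_means: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_runs(self) -> int:
        return int(self.run_means.size)

    @property
    def sim_mean(self) -> float:
        return float(self.run_means.mean())

    @property
    def sim_sd(self) -> float:
        return float(self.run_means.std(ddof=1))

    def summary(self) -> dict:
        return {
            "statistic": self.statistic,
            "n_runs": self.n_runs,
            "sim_mean": self.sim_mean,
            "sim_sd": self.sim_sd,
            "p_majority": self.p_majority,
            "sample_sizes": dict(self.sample_sizes),
            "seed": self.seed,
            "condition_sim_means": {
                c: float(v.mean()) for c, v in self.condition_run_means.items()
            },
            "condition_sim_sds": {
                c: float(v.std(ddof=1)) for c, v in self.condition_run_means.items()
            },
        }


def simulate_null(
    config: DesignConfig | None = None,
    sample_sizes: dict[str, int] | None = None,
    statistic: str = "delta_h",
    n_runs: int = 10_000,
    seed: int = 0,
) -> NullDistribution:
    """Monte-Carlo experiment null for entropy or MI change.

    Each run simulates one experiment: for every participant, draw
    n_test_per_meaning Bernoulli(p_majority) majority-order choices per
    meaning, evaluate the statistic against the training input, and average
    over participants (pooled and per condition).
    """
    config = config or DesignConfig()
    sample_sizes = sample_sizes if sample_sizes is not None else dict(EXP2_SAMPLE_SIZES)
    if any(n <= 0 for n in sample_sizes.values()) or not sample_sizes:
        raise ValueError("sample sizes must be positive")
    table = _statistic_table(config, statistic)
    n = config.n_test_per_meaning
    p = config.majority_proportion
    rng = np.random.default_rng(seed)
    cond_means: dict[str, np.ndarray] = {}
    weighted = np.zeros(n_runs)
    total = sum(sample_sizes.values())
    for label, n_part in sample_sizes.items():
        k1 = rng.binomial(n, p, size=(n_runs, n_part))
        k2 = rng.binomial(n, p, size=(n_runs, n_part))
        vals = table[k1, k2].mean(axis=1)
        cond_means[label] = vals
        weighted += vals * (n_part / total)
    return NullDistribution(
        run_means=weighted,
        statistic=statistic,
        sample_sizes=dict(sample_sizes),
        p_majority=p,
        seed=seed,
        condition_run_means=cond_means,
    )


def exact_null_expectation(
    config: DesignConfig | None = None, statistic: str = "delta_h"
) -> float:
    """Exact per-participant expectation of the null statistic by full
    enumeration over the Binomial(n, p)^2 outcome space."""
    config = config or DesignConfig()
    if config.n_meanings != 2:
        raise ValueError("enumeration oracle assumes two meanings")
    n = config.n_test_per_meaning
    if 2 * n > 32:
        raise ValueError("design too large to enumerate")
    table = _statistic_table(config, statistic)
    w = stats.binom.pmf(np.arange(n + 1), n, config.majority_proportion)
    return float(np.outer(w, w).ravel() @ table.ravel())


def z_score(observed_mean: float, null: NullDistribution) -> float:
    """Standardize an observed cohort mean against the null's run means."""
    sd = null.sim_sd
    if sd == 0:
        raise ZeroDivisionError("null distribution has zero SD; z undefined")
    return (float(observed_mean) - null.sim_mean) / sd
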