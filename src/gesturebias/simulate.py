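"""Synthetic participants for both experiments.

Experiment 1 is a single forced choice between the two gesture orders plus a
0-100 slider rating; the generator draws the choice from a per-condition
Bernoulli and places the slider on the chosen video's side (with a
configurable probability of contradicting the choice, which downstream
exclusion rules must catch).

Experiment 2 participants are simulated by a mixture of three learner
strategies over the 16 test trials that follow the 75/25 training schedule:

* ``matcher`` — probability-matches the training input: chooses the majority
  order with probability inv-logit(logit(0.75) + u).
* ``regularizer`` — boosts the majority order on the log-odds scale:
  inv-logit(lambda * logit(0.75) + b_natural * s + u), with s = +1 when the
  majority order is the natural one and -1 otherwise; lambda = 1 reduces to
  matching, lambda -> inf to categorical use of the majority order.
* ``conditioner`` — assigns one order per meaning (the majority order to a
  uniformly chosen one of the two) and follows the assignment on each trial
  with probability 1 - epsilon.

u ~ Normal(0, sigma_u) is a per-participant log-odds offset shared across
trials. The mixture is the minimal generative model exhibiting the three
behaviors the analysis pipeline must detect: learning above chance, entropy
reduction, and an MI increase.

Seeding: one global seed is expanded into independent per-participant
substreams via numpy SeedSequence spawning, so cohorts are reproducible and
participants statistically independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import (
    Condition,
    DesignConfig,
    EXP1_CONDITIONS,
    EXP2_CONDITIONS,
    EXP2_SAMPLE_SIZES,
    MeaningType,
    Order,
    build_training_schedule,
    majority_order,
    natural_order,
)

#: Minimum combined video-watching time; faster forced-choice responses mean
#: the participant cannot have watched both videos.
RT_THRESHOLD_MS = 9678.0

TRIAL_COLUMNS = [
    "participant_id",
    "experiment",
    "condition",
    "phase",
    "trial_index",
    "meaning_id",
    "meaning_type",
    "order",
    "is_majority",
    "is_natural",
    "rt_ms",
    "slider_raw",
    "instruction_order",
]


@dataclass(frozen=True)
class Exp1Params:
    """Generative settings for the preference experiment.

    theta_* are the probabilities of choosing the predicted order
    (postnominal for descriptive, prenominal for possessive); defaults are
    the inverse logits of intercepts of 0.51 and 0.56 on the log-odds scale.
    rt_* parameterize a normal response-time draw whose defaults place ~10%
    of participants under the fast-response threshold.
    """

    n_per_condition: int = 160
    theta_descriptive: float = 0.625
    theta_possessive: float = 0.6375
    slider_location: float = 80.0
    slider_spread: float = 12.0
    p_mismatch: float = 0.1
    rt_mean_ms: float = 12500.0
    rt_sd_ms: float = 2200.0

    def __post_init__(self) -> None:
        for name in ("theta_descriptive", "theta_possessive", "p_mismatch"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_per_condition < 0:
            raise ValueError("n_per_condition must be nonnegative")

    def theta(self, meaning_type: MeaningType) -> float:
        if meaning_type is MeaningType.DESCRIPTIVE:
            return self.theta_descriptive
        return self.theta_possessive


@dataclass(frozen=True)
class LearnerParams:
    """Mixture-of-strategies learner model for the learning experiment."""

    w_matcher: float = 0.4
    w_regularizer: float = 0.4
    w_conditioner: float = 0.2
    lam: float = 2.5
    b_natural: float = 0.0
    epsilon: float = 0.1
    sigma_u: float = 0.5

    def __post_init__(self) -> None:
        w = (self.w_matcher, self.w_regularizer, self.w_conditioner)
        if any(x < 0 for x in w) or not np.isclose(sum(w), 1.0):
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        if self.lam < 1:
            raise ValueError("lam (regularization exponent) must be >= 1")
        if not 0.0 <= self.epsilon <= 0.5:
            raise ValueError("epsilon must be in [0, 0.5]")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be nonnegative")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_matcher, self.w_regularizer, self.w_conditioner)


def matcher(**kw) -> LearnerParams:
    """Pure probability-matching learner (the Monte-Carlo null model)."""
    return LearnerParams(w_matcher=1.0, w_regularizer=0.0, w_conditioner=0.0, **kw)


def regularizer(lam: float = 2.5, **kw) -> LearnerParams:
    return LearnerParams(w_matcher=0.0, w_regularizer=1.0, w_conditioner=0.0, lam=lam, **kw)


def conditioner(epsilon: float = 0.1, **kw) -> LearnerParams:
    return LearnerParams(
        w_matcher=0.0, w_regularizer=0.0, w_conditioner=1.0, epsilon=epsilon, **kw
    )


def transform_rating(slider_raw: float) -> float:
    """Fold a raw 0-100 slider value onto the 50-100 preference-strength
    scale: values under 50 map to their mirror above 50 (2 -> 98)."""
    x = float(slider_raw)
    if not 0.0 <= x <= 100.0:
        raise ValueError(f"slider value {x} outside [0, 100]")
    return x if x >= 50.0 else 100.0 - x


def _row(pid: str, experiment: int, condition: Condition, phase: str, idx: int,
         meaning_id: str, meaning_type: MeaningType, order: Order, *,
         rt_ms: float | None = None, slider_raw: float | None = None,
         instruction_order: str | None = None) -> dict:
    is_nat = order is natural_order(meaning_type)
    try:
        is_maj = order is majority_order(condition)
    except Exception:
        is_maj = None
    return {
        "participant_id": pid,
        "experiment": experiment,
        "condition": condition.label,
        "phase": phase,
        "trial_index": idx,
        "meaning_id": meaning_id,
        "meaning_type": meaning_type.value,
        "order": order.value,
        "is_majority": is_maj,
        "is_natural": is_nat,
        "rt_ms": rt_ms,
        "slider_raw": slider_raw,
        "instruction_order": instruction_order,
    }


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_exp1(params: Exp1Params | None = None, seed: int = 0) -> pd.DataFrame:
    """Simulate the preference experiment: one forced-choice row (phase
    'test') and one slider row (phase 'slider') per participant."""
    params = params or Exp1Params()
    rows: list[dict] = []
    rngs = _spawn_rngs(seed, 2 * params.n_per_condition)
    i_rng = 0
    for cond in EXP1_CONDITIONS:
        predicted = natural_order(cond.meaning_type)
        theta = params.theta(cond.meaning_type)
        for i in range(params.n_per_condition):
            rng = rngs[i_rng]
            i_rng += 1
            pid = f"e1-{cond.meaning_type.value[:4]}-{i:04d}"
            chose_predicted = rng.random() < theta
            order = predicted if chose_predicted else predicted.complement
            rt = float(max(rng.normal(params.rt_mean_ms, params.rt_sd_ms), 500.0))
            instr = "item-first" if rng.random() < 0.5 else "modifier-first"
            # slider drawn on the chosen side (postnominal side is >50),
            # flipped to the opposite side with probability p_mismatch
            strength = np.clip(rng.normal(params.slider_location, params.slider_spread), 50.5, 100.0)
            side_order = order if rng.random() >= params.p_mismatch else order.complement
            slider = strength if side_order is Order.POSTNOMINAL else 100.0 - strength
            rows.append(_row(pid, 1, cond, "test", 0, "m1", cond.meaning_type, order,
                             rt_ms=rt, instruction_order=instr))
            rows.append(_row(pid, 1, cond, "slider", 1, "m1", cond.meaning_type, order,
                             slider_raw=float(slider), instruction_order=instr))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _simulate_test_choices(
    condition: Condition, params: LearnerParams, config: DesignConfig,
    rng: np.random.Generator
) -> list[tuple[str, Order]]:
    maj = majority_order(condition)
    strategy = rng.choice(3, p=params.weights)
    u = rng.normal(0.0, params.sigma_u) if params.sigma_u > 0 else 0.0
    base = logit(config.majority_proportion)
    meanings = config.meaning_ids
    choices: list[tuple[str, Order]] = []
    if strategy == 2:  # conditioner: one order per meaning
        maj_meaning = meanings[rng.integers(len(meanings))]
        assigned = {
            mid: (maj if mid == maj_meaning else maj.complement) for mid in meanings
        }
        for mid in meanings:
            for _ in range(config.n_test_per_meaning):
                follow = rng.random() >= params.epsilon
                order = assigned[mid] if follow else assigned[mid].complement
                choices.append((mid, order))
    else:
        if strategy == 0:  # matcher
            p_maj = expit(base + u)
        else:  # regularizer
            s = 1.0 if condition.majority_natural else -1.0
            p_maj = expit(params.lam * base + params.b_natural * s + u)
        for mid in meanings:
            for _ in range(config.n_test_per_meaning):
                order = maj if rng.random() < p_maj else maj.complement
                choices.append((mid, order))
    perm = rng.permutation(len(choices))
    return [choices[i] for i in perm]


def simulate_exp2_participant(
    condition: Condition,
    params: LearnerParams | None = None,
    config: DesignConfig | None = None,
    seed: int = 0,
    participant_id: str | None = None,
) -> pd.DataFrame:
    """One learning-experiment participant: training rows then test rows."""
    params = params or LearnerParams()
    config = config or DesignConfig()
    rng = np.random.default_rng(seed)
    pid = participant_id or f"e2-{seed:08d}"
    schedule_seed = int(rng.integers(2**31))
    schedule = build_training_schedule(condition, config, schedule_seed)
    rows = [
        _row(pid, 2, condition, "train", i, mid, condition.meaning_type, order)
        for i, (mid, order) in enumerate(schedule.trials)
    ]
    for i, (mid, order) in enumerate(_simulate_test_choices(condition, params, config, rng)):
        rows.append(_row(pid, 2, condition, "test", i, mid, condition.meaning_type, order))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_exp2_experiment(
    sample_sizes: dict[str, int] | None = None,
    params: LearnerParams | None = None,
    config: DesignConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a full learning-experiment cohort.

    ``sample_sizes`` maps condition label -> participant count; the default
    is the published per-condition breakdown (47/50/50/53).
    """
    sample_sizes = sample_sizes if sample_sizes is not None else dict(EXP2_SAMPLE_SIZES)
    params = params or LearnerParams()
    config = config or DesignConfig()
    total = sum(sample_sizes.values())
    seeds = np.random.SeedSequence(seed).spawn(total)
    frames: list[pd.DataFrame] = []
    i = 0
    for cond in EXP2_CONDITIONS:
        n = sample_sizes.get(cond.label, 0)
        for j in range(n):
            pid = f"e2-{cond.label.replace(' ', '-')}-{j:04d}"
            rng_seed = int(np.random.default_rng(seeds[i]).integers(2**31))
            frames.append(
                simulate_exp2_participant(cond, params, config, rng_seed, participant_id=pid)
            )
            i += 1
    if not frames:
        return pd.DataFrame(columns=TRIAL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


@dataclass
class ExclusionLog:
    """Counts of Experiment-1 participants removed per preregistered rule."""

    n_input: int = 0
    n_fast_rt: int = 0
    n_mismatch: int = 0
    n_both: int = 0
    excluded_ids: list[str] = field(default_factory=list)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)

    def to_dict(self) -> dict:
        return {
            "participants_in": self.n_input,
            "excluded_fast_rt_only": self.n_fast_rt,
            "excluded_mismatch_only": self.n_mismatch,
            "excluded_both": self.n_both,
            "excluded_total": self.n_excluded,
            "participants_retained": self.n_input - self.n_excluded,
        }


def apply_exclusions(
    trials: pd.DataFrame, rt_threshold_ms: float = RT_THRESHOLD_MS
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the preference-experiment exclusion rules.

    Removes participants whose forced-choice response time is below the
    threshold (they cannot have watched both videos) or whose slider
    response sits on the opposite side from their forced choice.
    """
    if "phase" not in trials.columns:
        raise ValueError("trial table lacks a 'phase' column")
    choice = trials[trials["phase"] == "test"].set_index("participant_id")
    slider = trials[trials["phase"] == "slider"].set_index("participant_id")
    if choice["rt_ms"].isna().any():
        raise ValueError("forced-choice rows with missing rt_ms")
    if slider["slider_raw"].isna().any():
        raise ValueError("slider rows with missing slider_raw")
    log = ExclusionLog(n_input=choice.shape[0])
    fast = set(choice.index[choice["rt_ms"] < rt_threshold_ms])
    slider_side_post = slider["slider_raw"] > 50.0
    chose_post = choice.loc[slider.index, "order"] == Order.POSTNOMINAL.value
    mismatch = set(slider.index[slider_side_post.values != chose_post.values])
    log.n_both = len(fast & mismatch)
    log.n_fast_rt = len(fast - mismatch)
    log.n_mismatch = len(mismatch - fast)
    log.excluded_ids = sorted(fast | mismatch)
    clean = trials[~trials["participant_id"].isin(log.excluded_ids)].reset_index(drop=True)
    return clean, log
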