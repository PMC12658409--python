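"""Experiment structure: orders, meaning types, conditions, training schedules.

Both experiments manipulate where a modifier gesture (a descriptive property
or a possessor) is placed relative to the gesture for the head noun. The
learning experiment trains each participant on a 75/25 mixture of the two
orders (6 of 8 training trials per meaning use the condition's majority
order) and then collects 16 binary test choices.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import yaml


class Order(str, enum.Enum):
    """Position of the modifier gesture relative to the noun gesture."""

    PRENOMINAL = "prenominal"
    POSTNOMINAL = "postnominal"

    @property
    def complement(self) -> "Order":
        return Order.POSTNOMINAL if self is Order.PRENOMINAL else Order.PRENOMINAL


class MeaningType(str, enum.Enum):
    DESCRIPTIVE = "descriptive"
    POSSESSIVE = "possessive"


class MissingMajorityError(ValueError):
    """Raised when a majority order is requested for a condition without one."""


@dataclass(frozen=True)
class Condition:
    """An experimental condition.

    ``majority_natural`` is only defined for the learning experiment
    (Experiment 2), where the 75% majority training order either matches
    (natural) or opposes (unnatural) the category-specific preferred order.
    Experiment 1 conditions carry ``majority_natural=None``.
    """

    meaning_type: MeaningType
    majority_natural: bool | None = None

    @property
    def label(self) -> str:
        if self.majority_natural is None:
            return self.meaning_type.value
        nat = "natural" if self.majority_natural else "unnatural"
        return f"{nat} {self.meaning_type.value}"

    @classmethod
    def from_label(cls, label: str) -> "Condition":
        parts = label.strip().lower().split()
        if len(parts) == 1:
            return cls(MeaningType(parts[0]))
        if len(parts) == 2 and parts[0] in ("natural", "unnatural"):
            return cls(MeaningType(parts[1]), parts[0] == "natural")
        raise ValueError(f"unrecognized condition label: {label!r}")


#: The four learning-experiment conditions, in canonical report order.
EXP2_CONDITIONS: tuple[Condition, ...] = (
    Condition(MeaningType.DESCRIPTIVE, True),
    Condition(MeaningType.DESCRIPTIVE, False),
    Condition(MeaningType.POSSESSIVE, True),
    Condition(MeaningType.POSSESSIVE, False),
)

#: Experiment-1 conditions (single forced choice, no training input).
EXP1_CONDITIONS: tuple[Condition, ...] = (
    Condition(MeaningType.DESCRIPTIVE),
    Condition(MeaningType.POSSESSIVE),
)

#: Per-condition analyzed sample sizes of the learning experiment.
EXP2_SAMPLE_SIZES: dict[str, int] = {
    "natural descriptive": 47,
    "unnatural descriptive": 50,
    "natural possessive": 50,
    "unnatural possessive": 53,
}


def natural_order(meaning_type: MeaningType) -> Order:
    """Category-specific preferred order for a meaning type.

    Descriptive meanings (typologically: adjectives) prefer postnominal
    order; possessive meanings (genitives) prefer prenominal order.
    """
    if meaning_type is MeaningType.DESCRIPTIVE:
        return Order.POSTNOMINAL
    return Order.PRENOMINAL


def majority_order(condition: Condition) -> Order:
    """The order shown on 75% of training trials in a learning condition."""
    if condition.majority_natural is None:
        raise MissingMajorityError(
            f"condition {condition.label!r} has no training input, "
            "so no majority order is defined"
        )
    nat = natural_order(condition.meaning_type)
    return nat if condition.majority_natural else nat.complement


@dataclass(frozen=True)
class DesignConfig:
    """Structural parameters of the learning experiment.

    Defaults encode the published design: two meanings, 8 training trials
    per meaning of which 6 use the majority order (75%), and 8 test trials
    per meaning.
    """

    majority_proportion: float = 0.75
    n_train_per_meaning: int = 8
    n_majority_per_meaning: int = 6
    n_test_per_meaning: int = 8
    n_meanings: int = 2

    def __post_init__(self) -> None:
        if not 0.5 < self.majority_proportion <= 1.0:
            raise ValueError("majority_proportion must be in (0.5, 1]")
        if self.n_majority_per_meaning > self.n_train_per_meaning:
            raise ValueError("n_majority_per_meaning exceeds n_train_per_meaning")
        if min(self.n_train_per_meaning, self.n_test_per_meaning, self.n_meanings) < 1:
            raise ValueError("trial counts and n_meanings must be positive")

    @property
    def n_train_total(self) -> int:
        return self.n_meanings * self.n_train_per_meaning

    @property
    def n_test_total(self) -> int:
        return self.n_meanings * self.n_test_per_meaning

    @property
    def meaning_ids(self) -> tuple[str, ...]:
        return tuple(f"m{i + 1}" for i in range(self.n_meanings))

    @classmethod
    def from_yaml(cls, path) -> "DesignConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown design config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class TrainingSchedule:
    """A seeded interleaving of the (meaning, order) training tokens."""

    trials: tuple[tuple[str, Order], ...]
    condition: Condition
    seed: int
    config: DesignConfig = field(default_factory=DesignConfig)

    def __len__(self) -> int:
        return len(self.trials)


def build_training_schedule(
    condition: Condition, config: DesignConfig | None = None, seed: int = 0
) -> TrainingSchedule:
    """Build one participant's training sequence.

    Per meaning, exactly ``n_majority_per_meaning`` trials use the
    condition's majority order and the remainder its complement; the 16
    tokens are interleaved by a single seeded uniform shuffle. The schedule
    construction requires the configured counts to realize the configured
    majority proportion exactly.
    """
    config = config or DesignConfig()
    maj = majority_order(condition)
    if config.n_majority_per_meaning / config.n_train_per_meaning != config.majority_proportion:
        raise ValueError(
            "n_majority_per_meaning / n_train_per_meaning must equal majority_proportion"
        )
    tokens: list[tuple[str, Order]] = []
    for mid in config.meaning_ids:
        n_min = config.n_train_per_meaning - config.n_majority_per_meaning
        tokens.extend([(mid, maj)] * config.n_majority_per_meaning)
        tokens.extend([(mid, maj.complement)] * n_min)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(tokens))
    return TrainingSchedule(
        trials=tuple(tokens[i] for i in order), condition=condition, seed=seed, config=config
    )


def input_distribution(schedule: TrainingSchedule):
    """Per-meaning and pooled order counts of a training schedule."""
    from .metrics import VariantCounts

    per_meaning: dict[str, dict[Order, int]] = {}
    for mid, order in schedule.trials:
        bucket = per_meaning.setdefault(mid, {Order.PRENOMINAL: 0, Order.POSTNOMINAL: 0})
        bucket[order] += 1
    return VariantCounts(
        {
            mid: (c[Order.PRENOMINAL], c[Order.POSTNOMINAL])
            for mid, c in sorted(per_meaning.items())
        }
    )
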