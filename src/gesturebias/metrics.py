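"""Regularization statistics: Shannon entropy, entropy change, and mutual
information between chosen order and meaning.

With two order variants, entropy lives in [0, 1] bits: 1 bit for an exact
50/50 split, 0 for categorical use of a single order. Regularization is a
drop in a participant's test-phase entropy relative to the entropy of their
75/25 training input (H(0.75) = 0.8113 bits under the default design).
Lexical conditioning — using different orders for different meanings — is
measured as mutual information: pooled entropy minus meaning-conditional
entropy, 1 bit when the two meanings receive the two orders categorically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy

from .design import DesignConfig, Order

__all__ = [
    "VariantCounts",
    "EntropySummary",
    "MISummary",
    "shannon_entropy",
    "entropy_change",
    "conditional_entropy",
    "mutual_information",
    "default_input_counts",
    "participant_metrics",
]


class UndefinedEntropyError(ValueError):
    """Entropy of an empty distribution is undefined."""


@dataclass(frozen=True)
class VariantCounts:
    """Counts of the two order variants, split by meaning.

    ``per_meaning`` maps meaning id -> (prenominal count, postnominal count).
    All downstream statistics depend only on these counts, never on trial
    order.
    """

    per_meaning: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for mid, (a, b) in self.per_meaning.items():
            if a < 0 or b < 0:
                raise ValueError(f"negative count for meaning {mid!r}")

    @property
    def pooled(self) -> tuple[int, int]:
        pre = sum(a for a, _ in self.per_meaning.values())
        post = sum(b for _, b in self.per_meaning.values())
        return pre, post

    @property
    def n_total(self) -> int:
        return sum(self.pooled)

    @classmethod
    def from_pairs(cls, *pairs: tuple[int, int]) -> "VariantCounts":
        return cls({f"m{i + 1}": tuple(p) for i, p in enumerate(pairs)})


@dataclass(frozen=True)
class EntropySummary:
    input_entropy: float
    output_entropy: float
    delta_h: float


@dataclass(frozen=True)
class MISummary:
    overall_entropy: float
    conditional_entropy: float
    mi: float
    delta_mi: float


def shannon_entropy(counts) -> float:
    """Shannon entropy in bits of a two-variant count vector.

    Uses the 0·log2(0) := 0 convention; raises UndefinedEntropyError on an
    all-zero vector.
    """
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or np.any(arr < 0):
        raise ValueError("counts must be a 1-d nonnegative vector")
    if arr.sum() == 0:
        raise UndefinedEntropyError("entropy of zero total count is undefined")
    return float(_scipy_entropy(arr, base=2))


def entropy_change(test_counts: VariantCounts, input_counts: VariantCounts) -> EntropySummary:
    """Participant's pooled test entropy minus their input entropy."""
    h_in = shannon_entropy(input_counts.pooled)
    h_out = shannon_entropy(test_counts.pooled)
    return EntropySummary(input_entropy=h_in, output_entropy=h_out, delta_h=h_out - h_in)


def conditional_entropy(counts: VariantCounts) -> float:
    """Entropy of order choice conditional on meaning, Σ_m p(m)·H(V|m)."""
    n = counts.n_total
    if n == 0:
        raise UndefinedEntropyError("conditional entropy of empty table is undefined")
    total = 0.0
    for mid, pair in counts.per_meaning.items():
        nm = sum(pair)
        if nm == 0:
            raise UndefinedEntropyError(f"meaning {mid!r} has zero trials")
        total += (nm / n) * shannon_entropy(pair)
    return total


def mutual_information(
    counts: VariantCounts, input_counts: VariantCounts | None = None
) -> MISummary:
    """MI between chosen order and meaning: pooled minus conditional entropy.

    ``delta_mi`` subtracts the MI of the training input; under the default
    design both meanings share the same 6:2 split, so input MI is 0 and
    delta_mi equals the output MI.
    """
    h_all = shannon_entropy(counts.pooled)
    h_cond = conditional_entropy(counts)
    mi = h_all - h_cond
    input_mi = 0.0
    if input_counts is not None:
        input_mi = (
            shannon_entropy(input_counts.pooled) - conditional_entropy(input_counts)
        )
    return MISummary(
        overall_entropy=h_all, conditional_entropy=h_cond, mi=mi, delta_mi=mi - input_mi
    )


def default_input_counts(
    condition=None, config: DesignConfig | None = None
) -> VariantCounts:
    """Training-input counts implied by the design (12:4 pooled by default)."""
    from .design import majority_order

    config = config or DesignConfig()
    n_maj = config.n_majority_per_meaning
    n_min = config.n_train_per_meaning - n_maj
    if condition is not None and majority_order(condition) is Order.PRENOMINAL:
        pair = (n_maj, n_min)
    else:
        pair = (n_min, n_maj)
    return VariantCounts({mid: pair for mid in config.meaning_ids})


def _counts_from_rows(rows: pd.DataFrame) -> VariantCounts:
    per_meaning: dict[str, tuple[int, int]] = {}
    for mid, grp in rows.groupby("meaning_id", sort=True):
        pre = int((grp["order"] == Order.PRENOMINAL.value).sum())
        post = int((grp["order"] == Order.POSTNOMINAL.value).sum())
        per_meaning[str(mid)] = (pre, post)
    return VariantCounts(per_meaning)


def participant_metrics(trials: pd.DataFrame, config: DesignConfig | None = None) -> pd.DataFrame:
    """Per-participant entropy and MI summary from a learning-experiment
    trial table.

    Test-phase rows provide the output counts; training rows provide each
    participant's actual input counts. Returns one row per participant with
    columns participant_id, condition, input_h, output_h, delta_h, mi,
    delta_mi, majority_prop, natural_prop.
    """
    required = {"participant_id", "condition", "phase", "meaning_id", "order"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    out = []
    for pid, grp in trials.groupby("participant_id", sort=True):
        test = grp[grp["phase"] == "test"]
        train = grp[grp["phase"] == "train"]
        test_counts = _counts_from_rows(test)
        train_counts = _counts_from_rows(train)
        ent = entropy_change(test_counts, train_counts)
        mi = mutual_information(test_counts, train_counts)
        out.append(
            {
                "participant_id": pid,
                "condition": grp["condition"].iloc[0],
                "input_h": ent.input_entropy,
                "output_h": ent.output_entropy,
                "delta_h": ent.delta_h,
                "mi": mi.mi,
                "delta_mi": mi.delta_mi,
                "majority_prop": float(test["is_majority"].mean())
                if "is_majority" in test
                else np.nan,
                "natural_prop": float(test["is_natural"].mean())
                if "is_natural" in test
                else np.nan,
            }
        )
    return pd.DataFrame(out)
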