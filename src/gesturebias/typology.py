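"""Spoken-language noun-phrase order typology (WALS-based counts).

Packaged constants give the number of spoken languages with each order of
adjectives and genitives relative to the noun, and the 2x2 cross-table of
the two, used to compare experimental order preferences with typology:
postnominal order dominates for adjectives, prenominal for genitives, and
the split system with prenominal genitives plus postnominal adjectives is
as common as the postnominal-harmonic system.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TypologyTable",
    "HarmonyCrossTab",
    "ADJECTIVE_TABLE",
    "GENITIVE_TABLE",
    "HARMONY_TABLE",
    "postnominal_proportion",
    "harmony_summary",
    "experiment_vs_typology",
]


@dataclass(frozen=True)
class TypologyTable:
    """Language counts for one dependent type's order relative to the noun.

    ``noun_first`` languages place the dependent after the noun
    (postnominal dependent); ``other`` covers languages with no dominant
    order or both orders.
    """

    dependent: str
    noun_first: int
    dependent_first: int
    other: int = 0

    def __post_init__(self) -> None:
        if min(self.noun_first, self.dependent_first, self.other) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass(frozen=True)
class HarmonyCrossTab:
    """Cross-classification of genitive and adjective order (counts of
    languages)."""

    ngen_nadj: int  # postnominal harmonic
    ngen_adjn: int  # split: N-Gen with Adj-N
    genn_nadj: int  # split: Gen-N with N-Adj
    genn_adjn: int  # prenominal harmonic

    def __post_init__(self) -> None:
        if min(self.ngen_nadj, self.ngen_adjn, self.genn_nadj, self.genn_adjn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.ngen_nadj + self.ngen_adjn + self.genn_nadj + self.genn_adjn


ADJECTIVE_TABLE = TypologyTable("adjective", noun_first=879, dependent_first=373, other=110)
GENITIVE_TABLE = TypologyTable("genitive", noun_first=468, dependent_first=685, other=96)
HARMONY_TABLE = HarmonyCrossTab(ngen_nadj=342, ngen_adjn=65, genn_nadj=342, genn_adjn=232)

#: Which dependent's typology each experimental meaning type maps onto.
MEANING_TO_TABLE = {"descriptive": ADJECTIVE_TABLE, "possessive": GENITIVE_TABLE}


def postnominal_proportion(table: TypologyTable, include_other: bool = False) -> float:
    """Share of languages placing the dependent after the noun.

    'Other' languages have no single dominant order, so they are excluded
    from the denominator by default.
    """
    denom = table.noun_first + table.dependent_first
    if include_other:
        denom += table.other
    if denom == 0:
        raise ZeroDivisionError("typology table has no classified languages")
    return table.noun_first / denom


def harmony_summary(crosstab: HarmonyCrossTab = HARMONY_TABLE) -> dict[str, float]:
    """Proportion of languages with each of the four order systems."""
    t = crosstab.total
    if t == 0:
        raise ZeroDivisionError("empty harmony cross-table")
    return {
        "harmonic-postnominal": crosstab.ngen_nadj / t,
        "harmonic-prenominal": crosstab.genn_adjn / t,
        "split-GenN-NAdj": crosstab.genn_nadj / t,
        "split-NGen-AdjN": crosstab.ngen_adjn / t,
    }


def experiment_vs_typology(
    exp1_proportions: dict[str, float] | None = None,
    include_other: bool = False,
) -> pd.DataFrame:
    """Pair typological postnominal proportions with experimental ones.

    ``exp1_proportions`` maps meaning type ('descriptive'/'possessive') to
    the observed proportion of postnominal choices; None yields a
    typology-only table.
    """
    exp1_proportions = exp1_proportions or {}
    rows = []
    for meaning, table in MEANING_TO_TABLE.items():
        rows.append(
            {
                "meaning_type": meaning,
                "dependent": table.dependent,
                "typology_postnominal": postnominal_proportion(table, include_other),
                "experiment_postnominal": exp1_proportions.get(meaning),
            }
        )
    return pd.DataFrame(rows)
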