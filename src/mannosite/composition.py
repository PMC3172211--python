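"""Compositional comparison of interacting vs non-interacting residues.

These exploratory summaries ask which residue types are over-represented at
mannose contact sites: per-letter percentage composition of the two label
groups, the same aggregated into physicochemical property classes, whole-
pattern composition, and per-window-position frequency differences (the
numeric table behind a two-sample sequence logo).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import ALPHABET, STANDARD_AA
from .patterns import Pattern
from .sequence_io import AnnotatedSequence

#: Default physicochemical classes.  Published composition figures in this
#: area rarely enumerate their groups, so the map is configurable.
DEFAULT_PROPERTY_CLASSES: dict[str, str] = {
    "charged": "DEKHR",
    "polar_uncharged": "STNQYC",
    "hydrophobic": "AVLIMFWP",
    "glycine": "G",
}


@dataclass
class CompositionTable:
    """Percentage composition of two groups plus their difference."""

    table: pd.DataFrame  # rows indexed by letter/class/(position, letter)
    grouping: str  # residue | property-class | pattern-level | per-position

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def _percentages(counts: dict[str, float], keys) -> pd.Series:
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty residue group")
    return pd.Series({k: 100.0 * counts.get(k, 0.0) / total for k in keys})


def residue_composition(chains: list[AnnotatedSequence]) -> CompositionTable:
    """Percent composition of the 20 standard letters per label group."""
    pos: dict[str, float] = {}
    neg: dict[str, float] = {}
    for chain in chains:
        for res, flag in zip(chain.residues, chain.labels):
            if res not in STANDARD_AA:
                continue
            bucket = pos if flag else neg
            bucket[res] = bucket.get(res, 0.0) + 1
    df = pd.DataFrame(
        {
            "interacting": _percentages(pos, STANDARD_AA),
            "non_interacting": _percentages(neg, STANDARD_AA),
        }
    )
    df["difference"] = df["interacting"] - df["non_interacting"]
    return CompositionTable(table=df, grouping="residue")


def property_composition(
    chains: list[AnnotatedSequence],
    property_map: dict[str, str] | None = None,
) -> CompositionTable:
    """Residue composition aggregated into physicochemical classes."""
    if property_map is None:
        property_map = DEFAULT_PROPERTY_CLASSES
    letter_to_class: dict[str, str] = {}
    for cls, letters in property_map.items():
        for letter in letters:
            if letter in letter_to_class:
                raise ValueError(f"letter {letter!r} mapped to two classes")
            letter_to_class[letter] = cls
    missing = set(STANDARD_AA) - set(letter_to_class)
    if missing:
        raise ValueError(f"property map leaves letters unmapped: {sorted(missing)}")
    base = residue_composition(chains).table
    rows = {}
    for cls in property_map:
        members = list(property_map[cls])
        rows[cls] = {
            "interacting": base.loc[members, "interacting"].sum(),
            "non_interacting": base.loc[members, "non_interacting"].sum(),
        }
    df = pd.DataFrame(rows).T.loc[list(property_map)]
    df["difference"] = df["interacting"] - df["non_interacting"]
    return CompositionTable(table=df, grouping="property-class")


def pattern_composition(
    pos_patterns: list[Pattern], neg_patterns: list[Pattern]
) -> CompositionTable:
    """Whole-window letter composition of positive vs negative patterns."""
    def counts(patterns: list[Pattern]) -> dict[str, float]:
        c: dict[str, float] = {}
        for p in patterns:
            for ch in p.window:
                c[ch] = c.get(ch, 0.0) + 1
        return c

    df = pd.DataFrame(
        {
            "interacting": _percentages(counts(pos_patterns), ALPHABET),
            "non_interacting": _percentages(counts(neg_patterns), ALPHABET),
        }
    )
    df["difference"] = df["interacting"] - df["non_interacting"]
    return CompositionTable(table=df, grouping="pattern-level")


def positional_frequency_difference(
    pos_patterns: list[Pattern], neg_patterns: list[Pattern]
) -> CompositionTable:
    """Per-position letter-frequency difference (two-sample logo data).

    For each window position the table holds freq(positives) minus
    freq(negatives) for each of the 21 letters; the center column is
    flagged.  Differences at each position sum to zero.
    """
    if not pos_patterns or not neg_patterns:
        raise ValueError("both pattern groups must be nonempty")
    lengths = {len(p) for p in pos_patterns} | {len(p) for p in neg_patterns}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    L = lengths.pop()

    def freq(patterns: list[Pattern]) -> np.ndarray:
        f = np.zeros((L, len(ALPHABET)))
        for p in patterns:
            for i, ch in enumerate(p.window):
                f[i, ALPHABET.index(ch)] += 1
        return f / len(patterns)

    diff = freq(pos_patterns) - freq(neg_patterns)
    center = (L - 1) // 2
    df = pd.DataFrame(diff, columns=list(ALPHABET))
    df.index = pd.Index(range(1, L + 1), name="position")
    df["is_center"] = [i == center + 1 for i in df.index]
    return CompositionTable(table=df, grouping="per-position")
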