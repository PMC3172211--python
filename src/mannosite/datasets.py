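"""Assembly of balanced ("main") and imbalanced ("realistic") pattern sets.

Both dataset flavours keep every positive pattern (interacting center) and
draw negatives uniformly without replacement from the pool of non-interacting
windows: one negative per positive for the main dataset, ``ratio`` negatives
per positive (default 10) for the realistic dataset.  Sampling is
deterministic under the seed; ordering is positives first, then the sampled
negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .patterns import DEFAULT_WINDOW, Pattern, generate_patterns
from .sequence_io import AnnotatedSequence

log = logging.getLogger(__name__)


@dataclass
class PatternDataset:
    patterns: list[Pattern]
    n_pos: int
    n_neg: int
    window: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_pos + self.n_neg != len(self.patterns):
            raise ValueError("class counts do not sum to pattern count")

    @property
    def ratio(self) -> float:
        return self.n_neg / self.n_pos if self.n_pos else float("nan")

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.positive for p in self.patterns], dtype=int)

    def __len__(self) -> int:
        return len(self.patterns)


def _pattern_pool(
    chains: list[AnnotatedSequence], window: int
) -> tuple[list[Pattern], list[Pattern]]:
    pos: list[Pattern] = []
    neg: list[Pattern] = []
    for chain in chains:
        for p in generate_patterns(chain, window):
            (pos if p.positive else neg).append(p)
    return pos, neg


def _sample_negatives(
    neg: list[Pattern], target: int, seed: int
) -> list[Pattern]:
    if target >= len(neg):
        if target > len(neg):
            log.warning(
                "negative pool (%d) smaller than requested %d; keeping all",
                len(neg), target,
            )
        return list(neg)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(neg), size=target, replace=False)
    return [neg[i] for i in sorted(idx)]


def build_dataset(
    chains: list[AnnotatedSequence],
    window: int = DEFAULT_WINDOW,
    ratio: float = 1.0,
    seed: int = 0,
) -> PatternDataset:
    """All positive patterns plus ``round(ratio * n_pos)`` sampled negatives."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    pos, neg = _pattern_pool(chains, window)
    if not pos:
        raise ValueError("no positive pattern in the input chains")
    sampled = _sample_negatives(neg, round(ratio * len(pos)), seed)
    return PatternDataset(
        patterns=pos + sampled,
        n_pos=len(pos),
        n_neg=len(sampled),
        window=window,
        seed=seed,
    )


def build_main_dataset(
    chains: list[AnnotatedSequence], window: int = DEFAULT_WINDOW, seed: int = 0
) -> PatternDataset:
    """Balanced dataset: negatives sampled to match the positive count."""
    return build_dataset(chains, window=window, ratio=1.0, seed=seed)


def build_realistic_dataset(
    chains: list[AnnotatedSequence],
    window: int = DEFAULT_WINDOW,
    ratio: float = 10.0,
    seed: int = 0,
) -> PatternDataset:
    """Imbalanced dataset mimicking natural class frequencies (default 1:10)."""
    return build_dataset(chains, window=window, ratio=ratio, seed=seed)


def export_tsv(ds: PatternDataset, path: str | Path) -> None:
    """Write the dataset as TSV: pattern, label, chain, center position."""
    with open(path, "w") as fh:
        fh.write(f"# window={ds.window}\tseed={ds.seed}\n")
        fh.write("pattern\tlabel\tchain\tposition\n")
        for p in ds.patterns:
            fh.write(f"{p.window}\t{int(p.positive)}\t{p.source[0]}\t{p.source[1]}\n")


def import_tsv(path: str | Path) -> PatternDataset:
    """Read a dataset previously written by :func:`export_tsv`."""
    window = None
    seed = 0
    patterns: list[Pattern] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    k, _, v = tok.partition("=")
                    if k == "window":
                        window = int(v)
                    elif k == "seed":
                        seed = int(v)
                continue
            if line.startswith("pattern\t"):
                continue
            win, label, chain, position = line.split("\t")
            patterns.append(
                Pattern(window=win, positive=bool(int(label)), source=(chain, int(position)))
            )
    if window is None:
        window = len(patterns[0].window) if patterns else DEFAULT_WINDOW
    n_pos = sum(p.positive for p in patterns)
    return PatternDataset(
        patterns=patterns,
        n_pos=n_pos,
        n_neg=len(patterns) - n_pos,
        window=window,
        seed=seed,
    )
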