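"""Synthetic labelled chains with the compositional structure of real
mannose-binding data.

Real contact maps show two signals that a window classifier can exploit:
interacting residues are enriched in D/E/N/Q/R/S/T/W/Y (polar and aromatic
side chains that hydrogen-bond or stack with the sugar), and residues
flanking a contact are enriched in S/T/G.  The generator emulates these
biases on top of a uniform background: interacting positions are placed in
short clusters (1-4 consecutive residues, binding pockets being local in
sequence), letters at interacting positions are drawn with up-weighted
contact-preferred residues, and letters within ``flank_reach`` of a contact
are drawn with up-weighted flank residues.  Everything is deterministic
under the seed.

It emulates composition only — no 3D geometry, no evolutionary covariance,
no surface/buried distinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import STANDARD_AA
from .encoders import PSSMMatrix
from .sequence_io import AnnotatedSequence

#: Residues over-represented at mannose contacts.
CENTER_PREFERRED = "DENQRSTWY"
#: Residues over-represented in the near flanks of a contact.
FLANK_PREFERRED = "STG"


def _center_default() -> dict[str, float]:
    return {a: 6.0 for a in CENTER_PREFERRED}


def _flank_default() -> dict[str, float]:
    return {a: 3.0 for a in FLANK_PREFERRED}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-scale defaults: 120 chains, ~2.7% interacting residues.

    ``center_bias`` and ``flank_bias`` are multiplicative sampling weights
    relative to the background distribution (absent letters default to 1).
    """

    n_chains: int = 120
    chain_length: tuple[int, int] = (200, 450)  # uniform inclusive
    mir_fraction: float = 0.027
    center_bias: dict[str, float] = field(default_factory=_center_default)
    flank_bias: dict[str, float] = field(default_factory=_flank_default)
    flank_reach: int = 3
    cluster_sizes: tuple[int, int] = (1, 4)
    cluster_separation: int = 1  # minimum gap (residues) between clusters
    background: dict[str, float] | None = None  # None = uniform over 20 AA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 < self.mir_fraction < 1:
            raise ValueError("mir_fraction must be in (0, 1)")
        for bias in (self.center_bias, self.flank_bias):
            if any(w <= 0 for w in bias.values()):
                raise ValueError("bias weights must be positive")
        lo, hi = self.chain_length
        if lo < 1 or hi < lo:
            raise ValueError("invalid chain length range")
        lo, hi = self.cluster_sizes
        if lo < 1 or hi < lo:
            raise ValueError("invalid cluster size range")
        if self.cluster_separation < 1:
            raise ValueError("cluster_separation must be >= 1")
        if self.flank_reach < 0:
            raise ValueError("flank_reach must be non-negative")

    def _distribution(self, upweight: dict[str, float]) -> np.ndarray:
        base = np.ones(len(STANDARD_AA))
        if self.background is not None:
            base = np.array([self.background.get(a, 0.0) for a in STANDARD_AA])
            if base.sum() <= 0:
                raise ValueError("background frequencies sum to zero")
        w = base * np.array([upweight.get(a, 1.0) for a in STANDARD_AA])
        return w / w.sum()

    @property
    def background_dist(self) -> np.ndarray:
        return self._distribution({})

    @property
    def center_dist(self) -> np.ndarray:
        return self._distribution(self.center_bias)

    @property
    def flank_dist(self) -> np.ndarray:
        return self._distribution(self.flank_bias)


def _place_clusters(
    length: int,
    target: int,
    sizes: tuple[int, int],
    separation: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mark ~target interacting positions in well-separated clusters."""
    labels = np.zeros(length, dtype=bool)
    placed = 0
    attempts = 0
    while placed < target and attempts < 50 * max(target, 1):
        attempts += 1
        size = min(int(rng.integers(sizes[0], sizes[1] + 1)), target - placed)
        if size > length:
            break
        start = int(rng.integers(0, length - size + 1))
        lo, hi = max(0, start - separation), min(length, start + size + separation)
        if labels[lo:hi].any():
            continue
        labels[start : start + size] = True
        placed += size
    return labels


def generate_chains(cfg: GeneratorConfig | None = None) -> list[AnnotatedSequence]:
    """Draw labelled chains per the configured biases; seeded and repeatable."""
    if cfg is None:
        cfg = GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    letters = np.array(list(STANDARD_AA))
    bg, ctr, flk = cfg.background_dist, cfg.center_dist, cfg.flank_dist

    chains: list[AnnotatedSequence] = []
    for c in range(cfg.n_chains):
        length = int(rng.integers(cfg.chain_length[0], cfg.chain_length[1] + 1))
        target = max(1, round(length * cfg.mir_fraction))
        labels = _place_clusters(
            length, target, cfg.cluster_sizes, cfg.cluster_separation, rng
        )
        is_flank = np.zeros(length, dtype=bool)
        for pos in np.flatnonzero(labels):
            lo = max(0, pos - cfg.flank_reach)
            hi = min(length, pos + cfg.flank_reach + 1)
            is_flank[lo:hi] = True
        is_flank &= ~labels
        residues = np.empty(length, dtype="<U1")
        for mask, dist in ((labels, ctr), (is_flank, flk), (~labels & ~is_flank, bg)):
            k = int(mask.sum())
            if k:
                residues[mask] = rng.choice(letters, size=k, p=dist)
        chains.append(
            AnnotatedSequence(
                chain_id=f"syn{c + 1:04d}",
                residues="".join(residues),
                labels=labels.tolist(),
            )
        )
    return chains


def _fixture_config(difficulty: str, seed: int) -> GeneratorConfig:
    """Generator settings behind the end-to-end fixtures.

    ``easy`` carries a strong, deliberately *compositional* signal: the nine
    contact-preferred letters are enriched uniformly across the whole
    binding region (contact +/- 8, one full window), so the total count of
    preferred letters separates the classes while no single window position
    is individually diagnostic.  ``hard`` is the generator's default
    weak-bias structure; ``null`` removes all bias, leaving no signal.
    """
    nine = {a: 5.0 for a in CENTER_PREFERRED}
    if difficulty == "easy":
        biases = dict(center_bias=nine, flank_bias=dict(nine), flank_reach=8)
    elif difficulty == "hard":
        biases = dict(flank_reach=3)  # defaults: modest center/flank bias
    elif difficulty == "null":
        biases = dict(center_bias={}, flank_bias={}, flank_reach=8)
    else:
        raise ValueError(
            f"difficulty must be one of ['easy', 'hard', 'null'], got {difficulty!r}"
        )
    return GeneratorConfig(
        n_chains=96,
        chain_length=(120, 260),
        cluster_sizes=(1, 1),
        cluster_separation=17,
        seed=seed,
        **biases,
    )


def make_end_to_end_fixture(
    difficulty: str = "easy", seed: int = 0
) -> tuple[list[AnnotatedSequence], list[AnnotatedSequence]]:
    """Disjoint (train, held-out) chain sets for pipeline-level tests.

    Sizes are kept modest (96 + 24 chains of 120-260 residues) so a full
    five-fold run completes in seconds on one CPU, while the no-signal
    control stays well powered (~500 patterns per class).  Contacts are isolated
    single residues spaced at least a window apart, so positive windows
    never overlap each other: cross-validated performance then measures the
    compositional signal alone, with no near-duplicate leakage between
    folds.
    """
    base = _fixture_config(difficulty, seed)
    train = generate_chains(base)
    held = generate_chains(replace(base, n_chains=24, seed=seed + 10_000))
    for i, chain in enumerate(held):
        chain.chain_id = f"held{i + 1:04d}"
    return train, held


def make_matched_pssms(
    chains: list[AnnotatedSequence], seed: int = 0, noise: float = 1.0
) -> dict[str, PSSMMatrix]:
    """Toy evolutionary profiles so the PSSM path is testable offline.

    Each row is a smoothed one-hot in log-odds form: a positive score for
    the observed residue, mildly negative elsewhere, plus integer noise.
    These are stand-ins for PSI-BLAST output, not simulations of real
    evolution.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, PSSMMatrix] = {}
    for chain in chains:
        n = len(chain)
        raw = np.full((n, 21), -2.0)
        raw[:, 20] = 0.0  # X slot: raw score defined as 0
        for i, res in enumerate(chain.residues):
            col = STANDARD_AA.find(res)
            if col >= 0:
                raw[i, col] = 7.0
        if noise > 0:
            raw[:, :20] += rng.integers(
                -round(noise), round(noise) + 1, size=(n, 20)
            )
        out[chain.chain_id] = PSSMMatrix.from_raw(chain.chain_id, chain.residues, raw)
    return out
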