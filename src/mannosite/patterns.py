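"""Sliding-window pattern generation.

Every residue of a chain becomes the center of one fixed-length window
("pattern").  The chain is padded with ``(L-1)/2`` dummy residues X on each
side, so a chain of length n yields exactly n overlapping patterns; a
pattern is positive when its center residue is labelled interacting.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alphabet import DUMMY
from .sequence_io import AnnotatedSequence

DEFAULT_WINDOW = 17


@dataclass(frozen=True)
class Pattern:
    """A fixed-length residue window labelled by its center residue.

    ``source`` records provenance as (chain_id, 1-based center position).
    """

    window: str
    positive: bool
    source: tuple[str, int]

    def __len__(self) -> int:
        return len(self.window)

    @property
    def center(self) -> str:
        return self.window[len(self.window) // 2]


def check_window_length(window_length: int) -> int:
    if window_length < 3 or window_length % 2 == 0:
        raise ValueError(
            f"window length must be an odd integer >= 3, got {window_length}"
        )
    return window_length


def generate_patterns(
    seq: AnnotatedSequence, window_length: int = DEFAULT_WINDOW
) -> list[Pattern]:
    """Create one window per residue of ``seq``.

    The i-th pattern is centered on residue i of the X-padded sequence and
    inherits that residue's interacting label.
    """
    check_window_length(window_length)
    if len(seq) == 0:
        raise ValueError(f"{seq.chain_id}: empty sequence")
    pad = (window_length - 1) // 2
    padded = DUMMY * pad + seq.residues + DUMMY * pad
    return [
        Pattern(
            window=padded[i : i + window_length],
            positive=seq.labels[i],
            source=(seq.chain_id, i + 1),
        )
        for i in range(len(seq))
    ]
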