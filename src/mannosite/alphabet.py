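"""Fixed residue alphabet shared by every encoding.

The feature encodings all index into a single 21-letter alphabet: the 20
standard amino acids in alphabetical one-letter order followed by the dummy
residue ``X`` used both for terminal window padding and for nonstandard
residues.  The order is part of the on-disk model contract and must never
change between versions.
"""

from __future__ import annotations

import logging

log = logging.getLogger(__name__)

#: Canonical alphabet order: 20 standard amino acids, then the dummy X.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWYX"

#: Standard residues only (no dummy).
STANDARD_AA: str = ALPHABET[:-1]

#: Letter -> column index in every 21-wide encoding.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

#: Nonstandard / ambiguous one-letter codes mapped to the dummy residue.
NONSTANDARD_CODES = frozenset("BZUOJ")

DUMMY = "X"


def normalize_residue(letter: str) -> str:
    """Map a one-letter residue code to the 21-letter alphabet.

    Standard residues pass through; the ambiguity and rare-residue codes
    B, Z, U, O, J (and X itself) become the dummy X.  Anything else raises
    ``ValueError``.
    """
    up = letter.upper()
    if up in AA_INDEX:
        return up
    if up in NONSTANDARD_CODES:
        log.warning("nonstandard residue code %r mapped to X", letter)
        return DUMMY
    raise ValueError(f"character {letter!r} is not a valid residue code")
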