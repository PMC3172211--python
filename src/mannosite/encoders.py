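"""Feature encodings for residue windows.

Three encodings of a length-L pattern are supported, all over the fixed
21-letter alphabet (:data:`mannosite.alphabet.ALPHABET`):

* **BPP** (binary profile): per-position one-hot, dimension L x 21.
* **PPP** (PSSM profile): per-position normalized evolutionary scores from a
  PSI-BLAST position-specific scoring matrix, dimension L x 21.
* **CPP** (composition profile): the amino-acid composition of the window,
  dimension 21 regardless of L.

PSSM files are consumed in the PSI-BLAST ASCII dialect (the ``-Q`` output:
header lines, then one row per residue with the position, the residue and 20
integer log-odds scores).  Raw log-odds are mapped into [0, 1] either with a
logistic squash (default) or matrix-wide min-max scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .alphabet import AA_INDEX, ALPHABET, DUMMY, STANDARD_AA
from .patterns import Pattern

Encoding = Literal["bpp", "ppp", "cpp"]

#: Column order PSI-BLAST prints its 20 score columns in.
_PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

N_ALPHA = len(ALPHABET)  # 21
_X_COL = AA_INDEX[DUMMY]


class PssmFormatError(ValueError):
    """Malformed PSI-BLAST ASCII PSSM file."""


def normalize_pssm(raw_score: float) -> float:
    """Squash a raw PSSM log-odds score into [0, 1] with the logistic map.

    Strictly increasing; 0 maps to 0.5, large positive scores approach 1 and
    large negative scores approach 0.
    """
    from scipy.special import expit

    return float(expit(raw_score))


@dataclass
class PSSMMatrix:
    """Per-residue evolutionary profile for one chain.

    ``raw`` holds the integer log-odds scores in alphabet order with the X
    column fixed at 0; ``rows`` is the normalized (n x 21) matrix actually
    used for encoding, every entry in [0, 1].
    """

    chain_id: str
    residues: str
    raw: np.ndarray
    rows: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.raw.shape != (len(self.residues), N_ALPHA):
            raise ValueError("raw score matrix shape does not match sequence")
        if self.rows.shape != self.raw.shape:
            raise ValueError("normalized matrix shape does not match raw")
        if np.any(self.rows < 0) or np.any(self.rows > 1):
            raise ValueError("normalized PSSM values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def from_raw(
        cls,
        chain_id: str,
        residues: str,
        raw: np.ndarray,
        normalization: Literal["logistic", "minmax"] = "logistic",
    ) -> "PSSMMatrix":
        from scipy.special import expit

        raw = np.asarray(raw, dtype=float)
        if normalization == "logistic":
            rows = expit(raw)
        elif normalization == "minmax":
            lo, hi = raw.min(), raw.max()
            rows = np.full_like(raw, 0.5) if hi == lo else (raw - lo) / (hi - lo)
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        return cls(chain_id=chain_id, residues=residues, raw=raw, rows=rows)


def read_pssm(
    path: str | Path,
    chain_id: str | None = None,
    normalization: Literal["logistic", "minmax"] = "logistic",
) -> PSSMMatrix:
    """Parse a PSI-BLAST ASCII PSSM file into a normalized profile.

    Columns are reordered from PSI-BLAST's native layout to the package
    alphabet order; the 21st (X) raw score is defined as 0.
    """
    path = Path(path)
    if chain_id is None:
        chain_id = path.stem
    lines = path.read_text().splitlines()

    col_order = _PSIBLAST_ORDER
    residues: list[str] = []
    raw_rows: list[list[int]] = []
    expected_pos = 0
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        # column header: 20 (or 40) single residue letters
        if all(len(t) == 1 and t.isalpha() for t in tokens) and len(tokens) >= 20:
            col_order = "".join(tokens[:20]).upper()
            if sorted(col_order) != sorted(STANDARD_AA):
                raise PssmFormatError(
                    f"line {lineno}: column header is not a 20-residue alphabet"
                )
            continue
        if not tokens[0].isdigit():
            continue  # preamble / trailing statistics
        if len(tokens) < 22:
            raise PssmFormatError(
                f"line {lineno}: expected position, residue and 20 scores, "
                f"got {len(tokens)} fields"
            )
        pos = int(tokens[0])
        expected_pos += 1
        if pos != expected_pos:
            raise PssmFormatError(
                f"line {lineno}: position {pos} out of order "
                f"(expected {expected_pos})"
            )
        res = tokens[1].upper()
        if len(res) != 1 or not res.isalpha():
            raise PssmFormatError(f"line {lineno}: bad residue field {tokens[1]!r}")
        try:
            scores = [int(t) for t in tokens[2:22]]
        except ValueError as exc:
            raise PssmFormatError(f"line {lineno}: non-integer score: {exc}") from exc
        residues.append(res)
        raw_rows.append(scores)

    if not raw_rows:
        raise PssmFormatError(f"{path}: no score rows found")

    raw = np.zeros((len(raw_rows), N_ALPHA))
    for i, scores in enumerate(raw_rows):
        for letter, val in zip(col_order, scores):
            raw[i, AA_INDEX[letter]] = val
    return PSSMMatrix.from_raw(
        chain_id, "".join(residues), raw, normalization=normalization
    )


def write_pssm(m: PSSMMatrix, path: str | Path) -> None:
    """Write a profile back out in the PSI-BLAST ASCII dialect (round-trippable)."""
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("    " + "   ".join(_PSIBLAST_ORDER) + "\n")
        for i, res in enumerate(m.residues):
            scores = [int(m.raw[i, AA_INDEX[a]]) for a in _PSIBLAST_ORDER]
            pct = " ".join("0" for _ in range(20))
            fh.write(
                f"{i + 1:5d} {res}  "
                + " ".join(f"{s:3d}" for s in scores)
                + f"  {pct}  0.00 0.00\n"
            )


def _check_window(window: str) -> None:
    for ch in window:
        if ch not in AA_INDEX:
            raise ValueError(f"character {ch!r} outside the 21-letter alphabet")


def encode_binary(p: Pattern) -> np.ndarray:
    """One-hot encode a window: L blocks of 21, a single 1 per block."""
    _check_window(p.window)
    vec = np.zeros(len(p.window) * N_ALPHA)
    for i, ch in enumerate(p.window):
        vec[i * N_ALPHA + AA_INDEX[ch]] = 1.0
    return vec


def encode_composition(p: Pattern) -> np.ndarray:
    """Composition profile: fraction of each of the 21 letters in the window."""
    _check_window(p.window)
    vec = np.zeros(N_ALPHA)
    for ch in p.window:
        vec[AA_INDEX[ch]] += 1.0
    return vec / len(p.window)


def encode_pssm(p: Pattern, m: PSSMMatrix) -> np.ndarray:
    """PSSM profile: concatenated normalized 21-rows for the window positions.

    Window positions that fall outside the chain (terminal X padding)
    contribute a pure-X row: zeros with the X slot set to 1.
    """
    chain_id, center = p.source
    if chain_id != m.chain_id:
        raise ValueError(
            f"pattern from chain {chain_id!r} cannot be encoded with the "
            f"profile of chain {m.chain_id!r}"
        )
    n = len(m)
    if not 1 <= center <= n:
        raise ValueError(f"center position {center} outside chain of length {n}")
    L = len(p.window)
    pad = (L - 1) // 2
    vec = np.zeros(L * N_ALPHA)
    for k in range(L):
        pos = center - pad + k  # 1-based chain position for window slot k
        if 1 <= pos <= n:
            vec[k * N_ALPHA : (k + 1) * N_ALPHA] = m.rows[pos - 1]
        else:
            if p.window[k] != DUMMY:
                raise ValueError(
                    f"window slot {k} maps outside chain {chain_id!r} but is "
                    f"not padding"
                )
            vec[k * N_ALPHA + _X_COL] = 1.0
    return vec


def encode_patterns(
    patterns: list[Pattern],
    encoding: Encoding,
    pssms: dict[str, PSSMMatrix] | None = None,
) -> np.ndarray:
    """Stack feature vectors for a pattern list into an (n, d) design matrix."""
    if encoding == "bpp":
        return np.array([encode_binary(p) for p in patterns])
    if encoding == "cpp":
        return np.array([encode_composition(p) for p in patterns])
    if encoding == "ppp":
        if pssms is None:
            raise ValueError("PSSM encoding requires per-chain profiles")
        return np.array([encode_pssm(p, pssms[p.source[0]]) for p in patterns])
    raise ValueError(f"unknown encoding {encoding!r}")
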