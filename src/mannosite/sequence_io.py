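"""Case-annotated FASTA input/output.

Residue-level binding annotations travel in a FASTA dialect in which case
carries the label: lowercase letters are interacting residues, uppercase
letters are non-interacting.  ``AnnotatedSequence`` is the in-memory form
(uppercase residues plus a parallel boolean label vector).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

from .alphabet import AA_INDEX, DUMMY, NONSTANDARD_CODES

log = logging.getLogger(__name__)

_WRAP = 60


class FastaFormatError(ValueError):
    """Malformed case-annotated FASTA input."""


@dataclass
class AnnotatedSequence:
    """A protein chain with a per-residue interacting flag.

    ``residues`` is uppercase over the 21-letter alphabet (nonstandard codes
    already mapped to X); ``labels[i]`` is True when residue ``i`` interacts
    with the ligand.
    """

    chain_id: str
    residues: str
    labels: list[bool]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) != len(self.labels):
            raise ValueError(
                f"{self.chain_id}: {len(self.residues)} residues but "
                f"{len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_interacting(self) -> int:
        return sum(self.labels)

    def to_case_string(self) -> str:
        """Render the chain with interacting residues in lowercase."""
        return "".join(
            r.lower() if flag else r for r, flag in zip(self.residues, self.labels)
        )


def _parse_record(header: str, seq: str, record_no: int) -> AnnotatedSequence:
    if not seq:
        raise FastaFormatError(f"record {record_no} ({header!r}): empty sequence")
    parts = header.split(None, 1)
    chain_id = parts[0] if parts else f"record{record_no}"
    description = parts[1] if len(parts) > 1 else ""
    residues = []
    labels = []
    for pos, ch in enumerate(seq, start=1):
        up = ch.upper()
        if up in NONSTANDARD_CODES:
            log.warning(
                "%s position %d: nonstandard residue %r mapped to X",
                chain_id, pos, ch,
            )
            up = DUMMY
        if up not in AA_INDEX:
            raise FastaFormatError(
                f"record {record_no} ({chain_id}): invalid character {ch!r} "
                f"at position {pos}"
            )
        residues.append(up)
        labels.append(ch.islower())
    return AnnotatedSequence(chain_id, "".join(residues), labels, description)


def read_annotated_fasta(path: str | Path | TextIO) -> list[AnnotatedSequence]:
    """Read case-annotated FASTA: lowercase = interacting, uppercase = not."""
    if hasattr(path, "read"):
        return _read_handle(path)  # type: ignore[arg-type]
    with open(path) as fh:
        return _read_handle(fh)


def _read_handle(fh: TextIO) -> list[AnnotatedSequence]:
    records: list[AnnotatedSequence] = []
    header: str | None = None
    chunks: list[str] = []
    n = 0
    for line in fh:
        line = line.rstrip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                n += 1
                records.append(_parse_record(header, "".join(chunks), n))
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise FastaFormatError("sequence data before first '>' header")
            chunks.append(line.strip())
    if header is not None:
        n += 1
        records.append(_parse_record(header, "".join(chunks), n))
    return records


def write_annotated_fasta(
    seqs: Iterable[AnnotatedSequence], path: str | Path | TextIO
) -> None:
    """Write chains as case-annotated FASTA, wrapped at 60 columns."""
    if hasattr(path, "write"):
        _write_handle(seqs, path)  # type: ignore[arg-type]
        return
    with open(path, "w") as fh:
        _write_handle(seqs, fh)


def _write_handle(seqs: Iterable[AnnotatedSequence], fh: TextIO) -> None:
    for s in seqs:
        header = s.chain_id if not s.description else f"{s.chain_id} {s.description}"
        fh.write(f">{header}\n")
        cased = s.to_case_string()
        for i in range(0, len(cased), _WRAP):
            fh.write(cased[i : i + _WRAP] + "\n")
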