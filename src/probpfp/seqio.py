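"""FASTA input/output and the core sequence/alignment containers.

Reading is done by a small line-tracked scanner so that malformed residue
characters can be reported with their line number; writing goes through
Biopython's FASTA writer.  Ambiguity codes (B, Z, X, U, O, ``*``) are
normalised to ``X`` with a logged warning; ``.`` gaps are normalised to
``-`` on alignment input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .matrices import ALPHABET, AMBIGUOUS

log = logging.getLogger(__name__)

GAP = "-"
_RESIDUES = set(ALPHABET)


@dataclass(frozen=True)
class ProteinSequence:
    """A named, ungapped protein sequence over the 21-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - _RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class MultipleAlignment:
    """An ordered set of equal-length gapped rows.

    Invariants: all rows share one length, ids are unique, and no column
    consists entirely of gaps.
    """

    def __init__(self, rows: list[tuple[str, str]]):
        if not rows:
            raise ValueError("alignment has no rows")
        ids = [r[0] for r in rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        length = len(rows[0][1])
        for sid, gapped in rows:
            if len(gapped) != length:
                raise ValueError(
                    f"row {sid!r} has length {len(gapped)}, expected {length}"
                )
        if length == 0:
            raise ValueError("alignment has zero columns")
        for k in range(length):
            if all(gapped[k] == GAP for _, gapped in rows):
                raise ValueError(f"column {k} consists entirely of gaps")
        self.rows: list[tuple[str, str]] = list(rows)
        self.length = length

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]

    def ungapped(self, k: int) -> str:
        return self.rows[k][1].replace(GAP, "")

    def sequences(self) -> list[ProteinSequence]:
        return [ProteinSequence(sid, g.replace(GAP, "")) for sid, g in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MultipleAlignment) and self.rows == other.rows

    def __repr__(self) -> str:
        return f"MultipleAlignment({len(self.rows)} rows x {self.length} cols)"


def _normalise_residue(ch: str, sid: str, lineno: int, warned: set) -> str:
    if ch in _RESIDUES and ch != "X":
        return ch
    if ch in AMBIGUOUS:
        if ch not in warned:
            warned.add(ch)
            log.warning(
                "sequence %r line %d: ambiguous residue %r mapped to X",
                sid, lineno, ch,
            )
        return "X"
    raise ValueError(f"invalid residue character {ch!r} at line {lineno}")


def _scan_fasta(path, allow_gaps: bool) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    warned: set[str] = set()
    sid = None
    parts: list[str] = []

    def flush():
        if sid is not None:
            records.append((sid, "".join(parts)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"empty FASTA header at line {lineno}")
                sid = header.split()[0]
                if sid in seen:
                    raise ValueError(f"duplicate sequence id {sid!r}")
                seen.add(sid)
                parts = []
            else:
                if sid is None:
                    raise ValueError(
                        f"sequence data before first header at line {lineno}"
                    )
                for ch in line.upper():
                    if ch in (GAP, "."):
                        if not allow_gaps:
                            raise ValueError(
                                f"gap character {ch!r} at line {lineno} "
                                "in unaligned sequence input"
                            )
                        parts.append(GAP)
                    else:
                        parts.append(_normalise_residue(ch, sid, lineno, warned))
    flush()
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def read_fasta(path) -> list[ProteinSequence]:
    """Read unaligned protein sequences, in file order."""
    return [ProteinSequence(sid, res) for sid, res in _scan_fasta(path, False)]


def read_alignment(path) -> MultipleAlignment:
    """Read a gapped FASTA alignment; all-gap columns are dropped with a warning."""
    rows = _scan_fasta(path, True)
    length = len(rows[0][1])
    for sid, gapped in rows:
        if len(gapped) != length:
            raise ValueError(f"alignment row {sid!r} length mismatch")
    keep = [
        k for k in range(length)
        if any(gapped[k] != GAP for _, gapped in rows)
    ]
    if len(keep) != length:
        log.warning("dropped %d all-gap columns on input", length - len(keep))
    return MultipleAlignment(
        [(sid, "".join(gapped[k] for k in keep)) for sid, gapped in rows]
    )


def write_fasta(aln: MultipleAlignment | list[ProteinSequence], path,
                width: int = 60) -> None:
    """Write an alignment or a list of sequences as FASTA, wrapped at `width`."""
    if width < 1:
        raise ValueError("line width must be positive")
    if isinstance(aln, MultipleAlignment):
        items = aln.rows
    else:
        items = [(s.id, s.residues) for s in aln]
    records = [
        SeqRecord(Seq(text), id=sid, description="") for sid, text in items
    ]
    with open(path, "w") as fh:
        FastaWriter(fh, wrap=width).write_file(records)
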