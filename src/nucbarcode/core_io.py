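"""Sequence records, FASTA/FASTQ input and output, IUPAC nucleotide utilities.

Every sequence in the pipeline flows through :class:`SeqRecord`. Sequences are
normalised to uppercase DNA on read ('U' becomes 'T'); degenerate IUPAC letters
are kept as-is. Species labels travel as a ``taxid=<int>`` token in the FASTA
description, or alternatively in a two-column sidecar TSV (sequence id, taxid).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

# IUPAC nucleotide codes as A/C/G/T bitmasks. Bit order: A=1, C=2, G=4, T=8.
IUPAC_BITS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# Degenerate code for each non-empty A/C/G/T bitmask (inverse of IUPAC_BITS).
BITS_TO_IUPAC: dict[int, str] = {bits: code for code, bits in IUPAC_BITS.items()}

_TAXID_RE = re.compile(r"\btaxid=(\d+)\b")


class FastaFormatError(ValueError):
    """Raised for malformed FASTA/FASTQ input; message names the line number."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence with an optional species taxon label."""

    id: str
    sequence: str
    description: str = ""
    species_taxid: int | None = None

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(seq: str, *, line: int | None = None) -> str:
    """Uppercase a nucleotide string, map U->T, and validate the alphabet."""
    out = seq.upper().replace("U", "T")
    for ch in out:
        if ch not in IUPAC_BITS:
            where = f" at line {line}" if line is not None else ""
            raise FastaFormatError(f"non-IUPAC character {ch!r}{where}")
    return out


def _parse_header(header: str) -> tuple[str, str, int | None]:
    parts = header.split(None, 1)
    seq_id = parts[0]
    description = parts[1] if len(parts) > 1 else ""
    m = _TAXID_RE.search(description)
    taxid = int(m.group(1)) if m else None
    return seq_id, description, taxid


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a (multi-line) FASTA file into an ordered list of records.

    A ``taxid=<int>`` token in the description populates ``species_taxid``.
    Malformed headers or non-IUPAC characters raise :class:`FastaFormatError`
    naming the offending line.
    """
    records: list[SeqRecord] = []
    current: SeqRecord | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None:
                    current.sequence = "".join(chunks)
                    records.append(current)
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"empty FASTA header at line {lineno}")
                seq_id, description, taxid = _parse_header(header)
                current = SeqRecord(seq_id, "", description, taxid)
                chunks = []
            else:
                if current is None:
                    raise FastaFormatError(
                        f"sequence data before first '>' header at line {lineno}"
                    )
                chunks.append(normalize_sequence(line, line=lineno))
    if current is not None:
        current.sequence = "".join(chunks)
        records.append(current)
    return records


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read FASTQ, discarding qualities; taxid tokens are honoured as in FASTA."""
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        seq_id, description, taxid = _parse_header(rec.description or rec.id)
        records.append(SeqRecord(seq_id, normalize_sequence(str(rec.seq)),
                                 description, taxid))
    return records


def read_sequences(path: str | Path) -> list[SeqRecord]:
    """Read FASTA or FASTQ, sniffing the format from the first character."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: Iterable[SeqRecord], path: str | Path,
                line_width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence bodies at ``line_width``.

    ``species_taxid`` is serialised as a ``taxid=<int>`` description token if
    not already present. Duplicate ids are logged as a warning, not an error.
    """
    if line_width <= 0:
        raise ValueError("line_width must be positive")
    seen: set[str] = set()
    with open(path, "w") as fh:
        for rec in records:
            if not rec.id:
                raise ValueError("record with empty id")
            if rec.id in seen:
                logger.warning("duplicate FASTA id %r", rec.id)
            seen.add(rec.id)
            desc = rec.description
            if rec.species_taxid is not None and not _TAXID_RE.search(desc):
                desc = (desc + " " if desc else "") + f"taxid={rec.species_taxid}"
            header = f">{rec.id} {desc}".rstrip()
            fh.write(header + "\n")
            seq = rec.sequence
            for i in range(0, max(len(seq), 1), line_width):
                fh.write(seq[i:i + line_width] + "\n")


def load_taxid_map(path: str | Path) -> dict[str, int]:
    """Load a two-column sidecar TSV (sequence id, taxid)."""
    mapping: dict[str, int] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FastaFormatError(
                    f"expected 2 tab-separated columns at line {lineno}")
            mapping[fields[0]] = int(fields[1])
    return mapping


def apply_taxid_map(records: Iterable[SeqRecord],
                    mapping: dict[str, int]) -> list[SeqRecord]:
    """Attach sidecar taxids to records lacking one (in place; returns list)."""
    out = list(records)
    for rec in out:
        if rec.species_taxid is None and rec.id in mapping:
            rec.species_taxid = mapping[rec.id]
    return out


def reverse_complement(seq: str) -> str:
    """Reverse-complement a nucleotide string, honouring IUPAC degeneracy."""
    try:
        return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r}") from None


def iupac_compatible(a: str, b: str) -> bool:
    """True when the two IUPAC codes share at least one concrete base."""
    return bool(IUPAC_BITS[a] & IUPAC_BITS[b])
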