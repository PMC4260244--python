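"""FASTQ/FASTA reading and writing with mate-pair association.

Qualities are parsed and carried but never used by the algorithm.
All coordinates in the package are 0-based, half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

UNPAIRED = "unpaired"
FORWARD = "forward"
REVERSE = "reverse"

_VALID = re.compile(r"^[ACGTNacgtn]+$")


class ParseError(ValueError):
    pass


class PairingError(ValueError):
    pass


@dataclass
class Read:
    """An identified nucleotide sequence, optionally one half of a pair."""

    id: str
    sequence: str
    quality: str | None = None
    mate_role: str = UNPAIRED

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("read id must be non-empty")
        if len(self.sequence) < 1:
            raise ParseError(f"read {self.id}: empty sequence")
        if not _VALID.match(self.sequence):
            raise ParseError(f"read {self.id}: non-nucleotide characters")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ParseError(
                f"read {self.id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    @property
    def fragment_id(self) -> str:
        return normalize_fragment_id(self.id)


@dataclass
class ReadPair:
    forward: Read
    reverse: Read

    def __post_init__(self) -> None:
        if self.forward.fragment_id != self.reverse.fragment_id:
            raise PairingError(
                f"mates {self.forward.id!r} and {self.reverse.id!r} do not "
                "share a fragment id"
            )


def normalize_fragment_id(read_id: str) -> str:
    """Strip Illumina mate-suffix dialects: ``/1``, ``/2``, `` 1:...``, `` 2:...``."""
    token = read_id.split(None, 1)
    head = token[0]
    if head.endswith(("/1", "/2")):
        return head[:-2]
    return head


def _sniff_format(path: Path) -> str:
    with open(path) as handle:
        for line in handle:
            if line.strip():
                if line.startswith("@"):
                    return "fastq"
                if line.startswith(">"):
                    return "fasta"
                raise ParseError(f"{path}: unrecognized sequence format")
    return "empty"


def _load_one(path: Path, mate_role: str) -> list[Read]:
    fmt = _sniff_format(path)
    if fmt == "empty":
        return []
    reads: list[Read] = []
    try:
        for record in SeqIO.parse(str(path), fmt):
            reads.append(Read(record.id, str(record.seq),
                              _quality_string(record), mate_role))
    except ValueError as exc:
        raise ParseError(f"{path}: record {len(reads)}: {exc}") from exc
    return reads


def _quality_string(record) -> str | None:
    scores = record.letter_annotations.get("phred_quality")
    if scores is None:
        return None
    return "".join(chr(q + 33) for q in scores)


def load_reads(path: str | Path, paired_path: str | Path | None = None
               ) -> list[Read] | list[ReadPair]:
    """Load reads from one file, or mate pairs from two.

    With two files records are paired positionally and checked by
    normalized fragment id.  Raises :class:`PairingError` on unequal
    counts or mismatched ids, :class:`ParseError` on malformed records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if paired_path is None:
        return _load_one(path, UNPAIRED)
    paired_path = Path(paired_path)
    if not paired_path.exists():
        raise FileNotFoundError(paired_path)
    fwd = _load_one(path, FORWARD)
    rev = _load_one(paired_path, REVERSE)
    if len(fwd) != len(rev):
        raise PairingError(
            f"unequal pair counts: {len(fwd)} in {path}, {len(rev)} in {paired_path}"
        )
    return [ReadPair(f, r) for f, r in zip(fwd, rev)]


def flatten(reads: Sequence[Read] | Sequence[ReadPair]) -> list[Read]:
    """All reads as a flat list, pairs expanded in forward/reverse order."""
    out: list[Read] = []
    for item in reads:
        if isinstance(item, ReadPair):
            out.extend((item.forward, item.reverse))
        else:
            out.append(item)
    return out


def write_fasta(records: Iterable[tuple[str, str, str]], path: str | Path,
                width: int = 70) -> None:
    """Write ``(id, sequence, annotation)`` triples as FASTA.

    The annotation, when non-empty, is appended to the header line after
    a space (used for transcript expression percentages).
    """
    with open(path, "w") as handle:
        for rec_id, sequence, annotation in records:
            if not rec_id:
                raise ValueError("record id must be non-empty")
            header = f">{rec_id} {annotation}".rstrip()
            handle.write(header + "\n")
            for start in range(0, len(sequence), width):
                handle.write(sequence[start:start + width] + "\n")


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            quality = read.quality or "I" * len(read.sequence)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{quality}\n")
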