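"""Stage (vi): length-normalized relative expression.

All input reads are remapped to the finished transcripts with the same
k-mer machinery used for scaffold mapping; each mapped read counts once
toward its vote-winning transcript.  A transcript's expression is its
read count divided by its length, reported as a percent of the sum of
those densities over all transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .guide_builder import GuideSequence
from .params import AssemblyParams
from .scaffold_mapper import build_index, map_read
from .sequence_io import Read
from .traversal import Transcript

log = logging.getLogger(__name__)


@dataclass
class ExpressionRow:
    transcript_id: str
    length: int
    count: int
    density: float
    percent: float


@dataclass
class ExpressionTable:
    rows: list[ExpressionRow]

    def by_id(self) -> dict[str, ExpressionRow]:
        return {row.transcript_id: row for row in self.rows}

    def write_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("transcript_id\tlength\tcount\tpercent\n")
            for row in self.rows:
                handle.write(f"{row.transcript_id}\t{row.length}\t"
                             f"{row.count}\t{row.percent:.4f}\n")


def quantify(transcripts: list[Transcript], reads: list[Read],
             params: AssemblyParams) -> ExpressionTable:
    """Remap reads to transcripts and fill ``expression_percent``.

    Raises ``ValueError`` with zero transcripts; with zero mapped reads
    all percents are 0 and a warning is logged.
    """
    if not transcripts:
        raise ValueError("cannot quantify without transcripts")
    guides = [GuideSequence(i, t.sequence, MERGED_SOURCE)
              for i, t in enumerate(transcripts)]
    index = build_index(guides, params.kmer_length)
    counts = [0] * len(transcripts)
    for read in reads:
        placement = map_read(read, index, params)
        if placement is not None:
            counts[placement.guide_id] += 1
    densities = [c / len(t.sequence) for c, t in zip(counts, transcripts)]
    total = sum(densities)
    if total == 0:
        log.warning("expression: no reads mapped to any transcript")
    rows = []
    for transcript, count, density in zip(transcripts, counts, densities):
        percent = 100.0 * density / total if total else 0.0
        transcript.expression_percent = percent
        rows.append(ExpressionRow(transcript.id, transcript.length, count,
                                  density, percent))
    return ExpressionTable(rows)


MERGED_SOURCE = "expression"
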