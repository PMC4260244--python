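"""Stage (iii): k-mer-index mapping of reads onto guide sequences.

Each guide's k-mers (k = 10 by default) are indexed with positions.
Every k-mer of a read votes for a (guide, offset, orientation) bin,
where the offset is the implied position of read base 0 on the guide;
the bin with the most votes wins.  Ties break to the lowest guide id,
then the lowest offset, preferring the forward orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .guide_builder import GuideSequence
from .params import AssemblyParams
from .sequence_io import Read
from .similarity import encode, kmer_values, reverse_complement

log = logging.getLogger(__name__)

FORWARD = "forward"
REVERSE = "reverse"

# offset keys are shifted by this much so they encode as non-negative ints
_OFFSET_BIAS = 1 << 20


@dataclass
class Placement:
    read_id: str
    guide_id: int
    offset: int
    orientation: str
    votes: int
    length: int  # read length, for span arithmetic

    @property
    def interval(self) -> tuple[int, int]:
        return self.offset, self.offset + self.length


@dataclass
class ScaffoldAlignment:
    """Reads placed at offsets on one guide; offsets may overhang."""

    guide: GuideSequence
    placements: list[Placement] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        if not self.placements:
            return 0, 0
        return (min(p.offset for p in self.placements),
                max(p.offset + p.length for p in self.placements))


class KmerIndex:
    """Positional k-mer library over a set of guides (sorted-array join)."""

    def __init__(self, guides: list[GuideSequence], k: int):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.guides = list(guides)
        all_values: list[np.ndarray] = []
        all_guides: list[np.ndarray] = []
        all_positions: list[np.ndarray] = []
        for guide in guides:
            positions, values = kmer_values(encode(guide.sequence), k)
            all_values.append(values)
            all_positions.append(positions)
            all_guides.append(np.full(len(values), guide.id, dtype=np.int64))
        if all_values:
            values = np.concatenate(all_values)
            order = np.argsort(values, kind="stable")
            self._values = values[order]
            self._guide_ids = np.concatenate(all_guides)[order]
            self._positions = np.concatenate(all_positions)[order]
        else:
            self._values = np.empty(0, dtype=np.int64)
            self._guide_ids = np.empty(0, dtype=np.int64)
            self._positions = np.empty(0, dtype=np.int64)

    def __len__(self) -> int:
        return len(self._values)

    def lookup(self, values: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """For query k-mer codes, return flat (query row, guide id, position)."""
        lo = np.searchsorted(self._values, values, side="left")
        hi = np.searchsorted(self._values, values, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty, empty
        starts = np.repeat(lo, counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        rows = np.repeat(np.arange(len(values)), counts)
        flat = starts + within
        return rows, self._guide_ids[flat], self._positions[flat]


def build_index(guides: list[GuideSequence], k: int) -> KmerIndex:
    return KmerIndex(guides, k)


def map_read(read: Read, index: KmerIndex,
             params: AssemblyParams) -> Placement | None:
    """Most-voted (guide, offset, orientation) placement, or ``None``."""
    keys_parts: list[np.ndarray] = []
    for orient_bit, seq in ((0, read.sequence),
                            (1, reverse_complement(read.sequence))):
        positions, values = kmer_values(encode(seq), index.k)
        if len(values) == 0:
            continue
        rows, guide_ids, guide_pos = index.lookup(values)
        if len(rows) == 0:
            continue
        offsets = guide_pos - positions[rows]
        keys_parts.append(
            ((guide_ids << 22) + (offsets + _OFFSET_BIAS)) * 2 + orient_bit)
    if not keys_parts:
        return None
    keys = np.concatenate(keys_parts)
    unique, counts = np.unique(keys, return_counts=True)
    winner = unique[np.argmax(counts)]  # first max = lowest (guide, offset, fwd)
    votes = int(counts.max())
    orient_bit = int(winner & 1)
    offset = int(((winner >> 1) & ((1 << 22) - 1)) - _OFFSET_BIAS)
    guide_id = int(winner >> 23)
    return Placement(read.id, guide_id, offset,
                     REVERSE if orient_bit else FORWARD,
                     votes, len(read.sequence))


def build_scaffolds(reads: list[Read], guides: list[GuideSequence],
                    params: AssemblyParams
                    ) -> tuple[list[ScaffoldAlignment], list[str]]:
    """One scaffold per guide that received at least one read.

    Returns the scaffolds and the ids of unmapped reads.  Raises
    ``ValueError`` when no guides are available.
    """
    if not guides:
        raise ValueError("cannot build scaffolds without guides")
    index = build_index(guides, params.kmer_length)
    by_guide: dict[int, ScaffoldAlignment] = {
        guide.id: ScaffoldAlignment(guide) for guide in guides}
    unmapped: list[str] = []
    for read in reads:
        placement = map_read(read, index, params)
        if placement is None:
            unmapped.append(read.id)
        else:
            by_guide[placement.guide_id].placements.append(placement)
    scaffolds = [s for s in by_guide.values() if s.placements]
    log.info("mapping: %d reads placed on %d scaffolds, %d unmapped",
             len(reads) - len(unmapped), len(scaffolds), len(unmapped))
    return scaffolds, unmapped


def dump_scaffolds(scaffolds: list[ScaffoldAlignment], path) -> None:
    with open(path, "w") as handle:
        handle.write("guide_id\tread_id\toffset\torientation\tvotes\n")
        for scaffold in scaffolds:
            for p in scaffold.placements:
                handle.write(f"{p.guide_id}\t{p.read_id}\t{p.offset}\t"
                             f"{p.orientation}\t{p.votes}\n")
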