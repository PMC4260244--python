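"""Stage (ii): greedy overlap assembly of partitions into guide sequences.

A random read seeds a growing guide sequence (GGS); reads matching it at
``guide_identity`` over a ``guide_window``-wide block are anchored onto
it and any overhanging bases extend the GGS.  Within the anchored
overlap the GGS bases win — guides are approximate templates, and true
per-site diversity is recovered later from the mapped reads.  Reads that
match without overhang (contained) are consumed along with extending
reads: they are fully represented by the guide, re-enter at mapping like
everything else, and letting them seed later guides only produces
redundant near-duplicate templates (three identical reads must yield one
guide, not three).  A final merge pass joins partial guides with the
same rule; at that stage a guide wholly contained in another is
absorbed.

For the default 98% / 100-base threshold, any qualifying window of
``w`` bases with at most ``floor((1-identity)*w)`` mismatches must keep
at least one exact shared k-mer, so an exact-k-mer anchor prescan is
lossless and avoids the full quadratic offset scan.  When that pigeonhole
guarantee does not hold for the configured thresholds, the full scan is
used instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .params import AssemblyParams
from .sequence_io import Read
from .similarity import (FORWARD, REVERSE, WindowMatch, _min_match_count,
                         _scan_diagonals, best_window_match, encode,
                         kmer_values, reverse_complement)

log = logging.getLogger(__name__)

MERGED = "merged"


@dataclass
class GuideSequence:
    id: int
    sequence: str
    source_partition: int | str


def _anchors_are_lossless(params: AssemblyParams) -> bool:
    window, k = params.guide_window, params.kmer_length
    max_mismatches = window - _min_match_count(window, params.guide_identity)
    return (window - k + 1) - max_mismatches * k >= 1


class _GgsMatcher:
    """Window matching of pool reads against one growing guide sequence.

    Pool reads are static, so their encodings and k-mer decompositions
    are cached across GGS updates.
    """

    def __init__(self, params: AssemblyParams):
        self.params = params
        self.lossless = _anchors_are_lossless(params)
        window, k = params.guide_window, params.kmer_length
        max_mismatches = window - _min_match_count(window,
                                                   params.guide_identity)
        # a qualifying window keeps at least this many exact shared
        # k-mers, all on its own diagonal (each mismatch kills <= k)
        self.min_anchor = (window - k + 1) - max_mismatches * k
        self.ggs = ""
        self.enc = np.empty(0, dtype=np.uint8)
        self._values = np.empty(0, dtype=np.int64)
        self._positions = np.empty(0, dtype=np.int64)
        self._read_cache: dict[str, tuple] = {}

    def set_ggs(self, ggs: str) -> None:
        self.ggs = ggs
        self.enc = encode(ggs)
        if self.lossless:
            positions, values = kmer_values(self.enc, self.params.kmer_length)
            order = np.argsort(values, kind="stable")
            self._values = values[order]
            self._positions = positions[order]

    def _read_views(self, read_seq: str):
        cached = self._read_cache.get(read_seq)
        if cached is None:
            views = []
            for orientation, seq in ((FORWARD, read_seq),
                                     (REVERSE, reverse_complement(read_seq))):
                enc = encode(seq)
                positions, values = kmer_values(enc, self.params.kmer_length)
                views.append((orientation, enc, positions, values))
            cached = tuple(views)
            self._read_cache[read_seq] = cached
        return cached

    def match(self, read_seq: str) -> WindowMatch | None:
        params = self.params
        if not self.lossless:
            return best_window_match(self.ggs, read_seq, params.guide_window,
                                     params.guide_identity)
        needed = _min_match_count(params.guide_window, params.guide_identity)
        best: tuple[int, int, int, str] | None = None
        for orientation, enc, positions, values in self._read_views(read_seq):
            lo = np.searchsorted(self._values, values, side="left")
            hi = np.searchsorted(self._values, values, side="right")
            counts = hi - lo
            total = int(counts.sum())
            if total == 0:
                continue
            starts = np.repeat(lo, counts)
            within = np.arange(total) - np.repeat(
                np.cumsum(counts) - counts, counts)
            read_pos = np.repeat(positions, counts)
            diagonals = self._positions[starts + within] - read_pos
            ds, ds_counts = np.unique(diagonals, return_counts=True)
            ds = ds[ds_counts >= self.min_anchor]
            if len(ds) == 0:
                continue
            hit = _scan_diagonals(self.enc, enc, ds, params.guide_window)
            if hit is not None and (best is None or hit[0] > best[0]):
                best = (*hit, orientation)
        if best is None or best[0] < needed:
            return None
        count, off_a, off_b, orientation = best
        return WindowMatch(off_a, off_b, count / params.guide_window, orientation)


def _lay_read(ggs: str, read_seq: str, match: WindowMatch) -> str:
    """Place the (oriented) read at the anchored offset; overhangs extend."""
    oriented = read_seq if match.orientation == FORWARD else \
        reverse_complement(read_seq)
    start = match.offset_a - match.offset_b  # read base 0 on the GGS
    prefix = oriented[:max(0, -start)]
    suffix_len = start + len(oriented) - len(ggs)
    suffix = oriented[len(oriented) - suffix_len:] if suffix_len > 0 else ""
    return prefix + ggs + suffix


def try_extend(ggs: str, read: Read, params: AssemblyParams,
               matcher: _GgsMatcher | None = None) -> tuple[str, str]:
    """Attempt to join a read to the GGS.

    Returns ``(new_ggs, status)`` with status one of ``"extended"``,
    ``"contained"`` (matched, no overhang) or ``"nomatch"``.
    """
    if matcher is not None:
        match = matcher.match(read.sequence)
    else:
        match = best_window_match(ggs, read.sequence, params.guide_window,
                                  params.guide_identity)
    if match is None:
        return ggs, "nomatch"
    extended = _lay_read(ggs, read.sequence, match)
    if len(extended) > len(ggs):
        return extended, "extended"
    return ggs, "contained"


def _grow_one_guide(pool: list[Read], params: AssemblyParams,
                    rng: np.random.Generator,
                    matcher: _GgsMatcher) -> str:
    """Seed a GGS from the pool and extend to exhaustion.

    Extending and contained reads are both consumed from the pool.
    """
    seed = pool.pop(int(rng.integers(len(pool))))
    ggs = seed.sequence
    while True:
        extended_any = False
        matcher.set_ggs(ggs)
        for read in list(pool):
            new_ggs, status = try_extend(ggs, read, params, matcher)
            if status == "nomatch":
                continue
            pool.remove(read)
            if status == "extended":
                ggs = new_ggs
                matcher.set_ggs(ggs)
                extended_any = True
        if not extended_any:
            return ggs


def build_guides(reads: list[Read], params: AssemblyParams,
                 rng: np.random.Generator | None = None,
                 source_partition: int | str = MERGED,
                 next_id: int = 0) -> list[GuideSequence]:
    """Greedy overlap assembly of one partition's reads into guides.

    Guides shorter than ``guide_window`` are dropped (their reads
    re-enter the pipeline at mapping).
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    pool = list(reads)
    matcher = _GgsMatcher(params)  # shared: caches read k-mer views
    guides: list[GuideSequence] = []
    while pool:
        sequence = _grow_one_guide(pool, params, rng, matcher)
        if len(sequence) >= params.guide_window:
            guides.append(GuideSequence(next_id + len(guides), sequence,
                                        source_partition))
    return guides


def merge_guides(guides: list[GuideSequence], params: AssemblyParams,
                 rng: np.random.Generator | None = None) -> list[GuideSequence]:
    """Final join pass: greedy extension with guides as pool and seeds.

    Guides sharing a qualifying window either extend one another
    (overhang) or, when contained, are absorbed into the covering guide.
    Guide count is non-increasing; ids are reassigned densely.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    pool = list(guides)
    merged: list[GuideSequence] = []
    matcher = _GgsMatcher(params)
    while pool:
        current = pool.pop(int(rng.integers(len(pool)))).sequence
        source: int | str = MERGED
        while True:
            changed = False
            matcher.set_ggs(current)
            for other in list(pool):
                match = matcher.match(other.sequence)
                if match is None:
                    continue
                extended = _lay_read(current, other.sequence, match)
                pool.remove(other)
                changed = True
                if len(extended) > len(current):
                    current = extended
                    matcher.set_ggs(current)
                # contained guides are absorbed either way
            if not changed:
                break
        merged.append(GuideSequence(len(merged), current, source))
    log.info("guide merge: %d -> %d guides", len(guides), len(merged))
    return merged
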