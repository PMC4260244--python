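"""Stage (i): seed-and-expand partitioning of forward reads.

A random unallocated read seeds a partition; every unallocated read
sharing a windowed-identity region with the seed joins it.  Expansion
cycles then probe the unallocated pool with up to ``expansion_sample``
reads sampled from the previous cycle's additions, until a cycle adds
nothing.  The step ends when no unallocated reads remain.

The windowed check itself is exact.  To keep the quadratic probe scan
tractable, candidate (read, diagonal) pairs are pre-screened with an FFT
cross-correlation bound: the total per-shift match count is an upper
bound on any windowed match count on that shift, so diagonals below the
required match count can be skipped without changing the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import AssemblyParams
from .sequence_io import Read
from .similarity import _min_match_count, encode


@dataclass
class Partition:
    id: int
    seed_read_id: str
    member_read_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.member_read_ids)


class _CorrelationScreen:
    """Bounds windowed match counts via one-hot cross-correlation."""

    def __init__(self, encoded: list[np.ndarray]):
        self.n = len(encoded)
        self._lengths = np.array([len(e) for e in encoded], dtype=np.int64)
        self.maxlen = int(self._lengths.max(initial=1))
        size = 1
        while size < 2 * self.maxlen:
            size *= 2
        self.size = size
        mat = np.full((self.n, self.maxlen), 4, dtype=np.uint8)
        for row, enc in enumerate(encoded):
            mat[row, :len(enc)] = enc
        self._fft = np.empty((4, self.n, size // 2 + 1), dtype=np.complex64)
        for code in range(4):
            onehot = (mat == code).astype(np.float32)
            self._fft[code] = np.fft.rfft(onehot, size, axis=1)

    def candidate_diagonals(self, probe_enc: np.ndarray, rows: np.ndarray,
                            needed: int
                            ) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per row: diagonals whose total match count can reach ``needed``.

        Diagonals use the ``best_window_match(probe, read)`` convention
        ``d = offset_probe - offset_read``; the second array of each
        pair is against the reverse complement of the read.  Any window
        at or above the identity threshold lies on a returned diagonal
        (the diagonal's total matches bound any window's matches), so
        restricting the exact scan to these diagonals is lossless.
        """
        lp = len(probe_enc)
        per_orientation: list[list[np.ndarray]] = []
        sliced = self._fft[:, rows, :]
        for reverse, enc in ((False, probe_enc), (True, 3 - probe_enc[::-1])):
            acc = np.zeros((len(rows), self.size // 2 + 1), dtype=np.complex64)
            for code in range(4):
                onehot = (enc[::-1] == code).astype(np.float32)
                acc += sliced[code] * np.fft.rfft(onehot, self.size)
            corr = np.fft.irfft(acc, self.size, axis=1)
            hit_rows, hit_shifts = np.nonzero(corr > needed - 0.5)
            out: list[np.ndarray] = [np.empty(0, dtype=np.int64)
                                     for _ in range(len(rows))]
            boundaries = np.searchsorted(hit_rows, np.arange(len(rows) + 1))
            for row in range(len(rows)):
                shifts = hit_shifts[boundaries[row]:boundaries[row + 1]]
                if len(shifts) == 0:
                    continue
                if reverse:
                    # rc(probe) vs read at output index m pairs probe
                    # against rc(read) on diagonal m - len(read) + 1
                    out[row] = shifts - int(self._lengths[rows[row]]) + 1
                else:
                    out[row] = lp - 1 - shifts
            per_orientation.append(out)
        return list(zip(per_orientation[0], per_orientation[1]))

    def candidates(self, probe_enc: np.ndarray, rows: np.ndarray,
                   needed: int) -> np.ndarray:
        """Boolean screen: row may contain a qualifying window."""
        diagonals = self.candidate_diagonals(probe_enc, rows, needed)
        return np.array([len(f) + len(r) > 0 for f, r in diagonals])


def _rc_encoded(enc: np.ndarray) -> np.ndarray:
    out = enc[::-1].copy()
    mask = out <= 3
    out[mask] = 3 - out[mask]
    return out


_CHUNK_PAIRS = 4096


def _batch_verify(probe_pad: np.ndarray, read_mat: np.ndarray,
                  pair_rows: np.ndarray, pair_diagonals: np.ndarray,
                  window: int, needed: int, out: np.ndarray) -> None:
    """Exact windowed check of many (read row, diagonal) pairs at once.

    ``probe_pad`` and ``read_mat`` are padded with code 4 (never
    matches), so padding needs no masking; sets ``out[row] = True`` for
    rows with a window of at least ``needed`` matches.
    """
    length = read_mat.shape[1]
    t = np.arange(length)
    for start in range(0, len(pair_rows), _CHUNK_PAIRS):
        rows = pair_rows[start:start + _CHUNK_PAIRS]
        ds = pair_diagonals[start:start + _CHUNK_PAIRS]
        i = np.maximum(ds, 0)[:, None] + t[None, :]
        j = i - ds[:, None]
        valid = (i < length) & (j < length)
        np.minimum(i, length - 1, out=i)
        np.minimum(j, length - 1, out=j)
        a = probe_pad[i]
        b = read_mat[rows[:, None], j]
        match = ((a == b) & (a != 4) & (b != 4) & valid).astype(np.int32)
        cs = np.cumsum(match, axis=1)
        win = cs[:, window - 1:].copy()
        win[:, 1:] -= cs[:, :-window]
        hits = win.max(axis=1) >= needed
        out[rows[hits]] = True


def partition_reads(reads: list[Read], params: AssemblyParams,
                    rng: np.random.Generator | None = None) -> list[Partition]:
    """Partition forward reads into groups of shared windowed similarity.

    Every read ends up in exactly one partition; reads matching nothing
    become singletons.  Deterministic for a fixed generator state.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    if not reads:
        return []
    window = params.partition_window
    needed = _min_match_count(window, params.partition_identity)
    encoded = [encode(read.sequence) for read in reads]
    screen = _CorrelationScreen(encoded)
    length = screen.maxlen
    read_mat = np.full((len(reads), length), 4, dtype=np.uint8)
    read_mat_rc = np.full((len(reads), length), 4, dtype=np.uint8)
    for row, enc in enumerate(encoded):
        read_mat[row, :len(enc)] = enc
        read_mat_rc[row, :len(enc)] = _rc_encoded(enc)

    unallocated = np.arange(len(reads))
    partitions: list[Partition] = []
    while len(unallocated):
        seed_pos = int(rng.integers(len(unallocated)))
        seed_idx = int(unallocated[seed_pos])
        unallocated = np.delete(unallocated, seed_pos)
        members = [seed_idx]
        frontier = [seed_idx]
        while frontier and len(unallocated):
            if len(frontier) <= params.expansion_sample:
                probes = list(frontier)
            else:
                probes = [frontier[i] for i in rng.choice(
                    len(frontier), size=params.expansion_sample,
                    replace=False)]
            added_mask = np.zeros(len(unallocated), dtype=bool)
            for probe in probes:
                pending = np.nonzero(~added_mask)[0]
                if len(pending) == 0:
                    break
                diagonals = screen.candidate_diagonals(
                    encoded[probe], unallocated[pending], needed)
                probe_pad = np.full(length, 4, dtype=np.uint8)
                probe_pad[:len(encoded[probe])] = encoded[probe]
                matched = np.zeros(len(reads), dtype=bool)
                for mat, side in ((read_mat, 0), (read_mat_rc, 1)):
                    pair_rows, pair_ds = [], []
                    for pos, (fwd, rev) in zip(pending, diagonals):
                        ds = (fwd, rev)[side]
                        if len(ds):
                            ds = np.unique(ds)
                            pair_rows.append(np.full(len(ds),
                                                     unallocated[pos]))
                            pair_ds.append(ds)
                    if pair_rows:
                        _batch_verify(probe_pad, mat,
                                      np.concatenate(pair_rows),
                                      np.concatenate(pair_ds),
                                      window, needed, matched)
                added_mask |= matched[unallocated]
            added = [int(i) for i in unallocated[added_mask]]
            unallocated = unallocated[~added_mask]
            members.extend(added)
            frontier = added
        partitions.append(Partition(
            id=len(partitions),
            seed_read_id=reads[seed_idx].id,
            member_read_ids=[reads[i].id for i in members],
        ))
    return partitions


def select_assemblable(partitions: list[Partition],
                       min_partition_size: int = 3
                       ) -> tuple[list[Partition], list[str]]:
    """Split partitions into assemblable ones and deferred read ids.

    Partitions with at least ``min_partition_size`` members progress to
    guide building; members of smaller partitions are deferred and
    re-enter the pipeline at mapping — no read is permanently discarded.
    """
    kept: list[Partition] = []
    deferred: list[str] = []
    for partition in partitions:
        if len(partition) >= min_partition_size:
            kept.append(partition)
        else:
            deferred.extend(partition.member_read_ids)
    return kept, deferred
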