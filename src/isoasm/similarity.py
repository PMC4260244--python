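"""Ungapped windowed identity and global identity primitives.

Windowed identity is a pure per-column (hamming-style) comparison of two
length-``window`` blocks, one from each sequence, maximized over every
pair of block offsets and over both orientations of the second sequence.
``N`` never matches anything, including another ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align

FORWARD = "forward"
REVERSE = "reverse"

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class WindowMatch:
    """Best ungapped window block shared by two sequences.

    ``offset_b`` is a position on *b as scanned*: for a reverse match it
    indexes into the reverse complement of ``b``.
    """

    offset_a: int
    offset_b: int
    identity: float
    orientation: str = FORWARD


def _min_match_count(window: int, min_identity: float) -> int:
    """Smallest integer match count satisfying ``count/window >= min_identity``."""
    return int(np.ceil(min_identity * window - 1e-9))


@lru_cache(maxsize=64)
def _diag_indices(la: int, lb: int, ds_key: tuple[int, ...]
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clipped gather indices and validity mask for a set of diagonals."""
    ds = np.asarray(ds_key, dtype=np.int64)
    lmin = min(la, lb)
    t = np.arange(lmin)
    i = np.maximum(ds, 0)[:, None] + t[None, :]
    j = i - ds[:, None]
    valid = (i < la) & (j < lb)
    return np.clip(i, 0, la - 1), np.clip(j, 0, lb - 1), valid


def _scan_diagonals(ea: np.ndarray, eb: np.ndarray, diagonals: np.ndarray,
                    window: int) -> tuple[int, int, int] | None:
    """Best window block over the given diagonals (``d = offset_a - offset_b``).

    Returns ``(match_count, offset_a, offset_b)`` for the maximal count,
    ties broken by smallest ``(offset_a, offset_b)``; ``None`` when no
    window fits on any diagonal.
    """
    la, lb = len(ea), len(eb)
    lmin = min(la, lb)
    if window > lmin or len(diagonals) == 0:
        return None
    ds = np.asarray(diagonals, dtype=np.int64)
    ii, jj, valid = _diag_indices(la, lb, tuple(ds.tolist()))
    va, vb = ea[ii], eb[jj]
    match = (va == vb) & (va != 4) & (vb != 4) & valid
    m = match.astype(np.int32)
    cs = np.zeros((len(ds), lmin + 1), dtype=np.int32)
    np.cumsum(m, axis=1, out=cs[:, 1:])
    win = cs[:, window:] - cs[:, :-window]
    # a window starting at t fits iff its last column t+window-1 is valid
    fits = valid[:, window - 1:]
    if not fits.any():
        return None
    win = np.where(fits, win, -1)
    best = int(win.max())
    if best < 0:
        return None
    rows, cols = np.nonzero(win == best)
    off_a = np.maximum(ds[rows], 0) + cols
    off_b = off_a - ds[rows]
    order = np.lexsort((off_b, off_a))[0]
    return best, int(off_a[order]), int(off_b[order])


def _best_one_orientation(ea: np.ndarray, eb: np.ndarray,
                          window: int) -> tuple[int, int, int] | None:
    la, lb = len(ea), len(eb)
    if la < window or lb < window:
        return None
    diagonals = np.arange(-(lb - window), la - window + 1)
    return _scan_diagonals(ea, eb, diagonals, window)


def best_window_match(a: str, b: str, window: int,
                      min_identity: float) -> WindowMatch | None:
    """Best ungapped length-``window`` block match between ``a`` and ``b``.

    Scans every relative offset pair of ``a`` against ``b`` in both
    orientations of ``b``.  Returns ``None`` unless the best identity
    reaches ``min_identity``.  Ties prefer the forward orientation, then
    the smallest ``(offset_a, offset_b)``.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    ea = encode(a)
    best: tuple[int, int, int, str] | None = None
    for orientation, eb in ((FORWARD, encode(b)),
                            (REVERSE, encode(reverse_complement(b)))):
        hit = _best_one_orientation(ea, eb, window)
        if hit is not None and (best is None or hit[0] > best[0]):
            best = (*hit, orientation)
    if best is None or best[0] < _min_match_count(window, min_identity):
        return None
    count, off_a, off_b, orientation = best
    return WindowMatch(off_a, off_b, count / window, orientation)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -0.5
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    # end gaps are cheap but not free: a genuine one-sided overhang is
    # still near-free (and its columns are excluded from the identity
    # denominator), while dodging a terminal substitution into a pair of
    # end gaps (2 * -0.5 < -0.5) never beats aligning it
    try:
        aligner.end_insertion_score = -0.5
        aligner.end_deletion_score = -0.5
    except AttributeError:  # biopython < 1.86 naming
        aligner.target_end_gap_score = -0.5
        aligner.query_end_gap_score = -0.5
    return aligner


def global_identity(a: str, b: str) -> float:
    """Identity of an optimal global alignment with free end gaps.

    Matches divided by alignment columns of the aligned core (terminal
    gap columns excluded, internal gap columns counted).  ``N`` never
    counts as a match.  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b and "N" not in a and "n" not in a:
        return 1.0
    alignment = _aligner().align(a.upper(), b.upper())[0]
    blocks_a, blocks_b = alignment.aligned
    if len(blocks_a) == 0:
        return 0.0
    ea, eb = encode(a), encode(b)
    matches = 0
    aligned_cols = 0
    for (sa, ta), (sb, tb) in zip(blocks_a, blocks_b):
        seg_a, seg_b = ea[sa:ta], eb[sb:tb]
        matches += int(np.sum((seg_a == seg_b) & (seg_a != 4) & (seg_b != 4)))
        aligned_cols += ta - sa
    span_a = int(blocks_a[-1][1] - blocks_a[0][0])
    span_b = int(blocks_b[-1][1] - blocks_b[0][0])
    columns = aligned_cols + (span_a - aligned_cols) + (span_b - aligned_cols)
    # terminal bases clipped on BOTH sequences are interior divergence,
    # not overhang: count them as (mismatching) columns so that only
    # genuine one-sided overhangs ride free
    columns += min(int(blocks_a[0][0]), int(blocks_b[0][0]))
    columns += min(len(a) - int(blocks_a[-1][1]), len(b) - int(blocks_b[-1][1]))
    return matches / columns if columns else 0.0


def strand_identity(a: str, b: str) -> float:
    """Global identity maximized over both orientations of ``a``."""
    return max(global_identity(a, b), global_identity(reverse_complement(a), b))


def kmer_values(enc: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, integer codes) of all k-mers of an encoded sequence.

    K-mers containing ``N`` are skipped.
    """
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    windows = enc[np.arange(n)[:, None] + np.arange(k)[None, :]]
    clean = (windows != 4).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    values = windows.astype(np.int64) @ powers
    positions = np.nonzero(clean)[0]
    return positions, values[clean]


def hamming_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Per-column match fraction of two equal-length encoded sequences."""
    if len(a) != len(b):
        raise ValueError("hamming identity requires equal lengths")
    if len(a) == 0:
        return 0.0
    return float(np.sum((a == b) & (a != 4) & (b != 4))) / len(a)
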