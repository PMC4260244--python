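"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately naive (pure-Python loops, no shared code
with the package beyond trivial helpers) so it can serve as a second
route for equivalence checks.
"""

from __future__ import annotations

import itertools

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def column_matches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x == y and x != "N" and y != "N")


def exhaustive_window_match(a: str, b: str, window: int, min_identity: float):
    """Scan every (offset_a, offset_b, orientation) block pair.

    Walks each diagonal with an incrementally maintained window sum
    (equivalent to re-counting every block, just not cubic).  Returns
    (offset_a, offset_b, identity, orientation) of the best block with
    forward preferred on ties, then smallest offsets; None if below
    threshold.
    """
    candidates = []
    for orient_bit, orientation, bb in ((0, "forward", b), (1, "reverse", rc(b))):
        for diag in range(-(len(bb) - window), len(a) - window + 1):
            i0, j0 = max(diag, 0), max(-diag, 0)
            length = min(len(a) - i0, len(bb) - j0)
            if length < window:
                continue
            cols = [1 if a[i0 + t] == bb[j0 + t] and a[i0 + t] != "N"
                    else 0 for t in range(length)]
            running = sum(cols[:window])
            candidates.append((-running, orient_bit, i0, j0, orientation))
            for t in range(1, length - window + 1):
                running += cols[t + window - 1] - cols[t - 1]
                candidates.append((-running, orient_bit, i0 + t, j0 + t,
                                   orientation))
    if not candidates:
        return None
    neg_count, _, off_a, off_b, orientation = min(candidates)
    identity = -neg_count / window
    if identity < min_identity - 1e-12:
        return None
    return off_a, off_b, identity, orientation


def hamming_components(fragments: list[str], min_identity: float) -> list[int]:
    """Connected-component labels of the hamming-identity graph."""
    n = len(fragments)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        width = len(fragments[i])
        identity = column_matches(fragments[i], fragments[j]) / width
        if identity >= min_identity - 1e-12:
            parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    relabel = {}
    return [relabel.setdefault(r, len(relabel)) for r in roots]


def window_match_graph_components(sequences: list[str], window: int,
                                  min_identity: float) -> list[int]:
    """Transitive closure of pairwise windowed matches (partition oracle)."""
    n = len(sequences)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        if exhaustive_window_match(sequences[i], sequences[j], window,
                                   min_identity) is not None:
            parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    relabel = {}
    return [relabel.setdefault(r, len(relabel)) for r in roots]


def best_offset_by_scoring(read: str, guides: list[str], k: int):
    """Per-offset exact k-mer vote counting (mapping argmax oracle).

    Returns (guide index, offset, orientation, votes) with the mapper's
    tie-break order, or None when no k-mer is shared.
    """
    best = None
    for orient_bit, seq in ((0, read), (1, rc(read))):
        read_kmers = {}
        for t in range(len(seq) - k + 1):
            kmer = seq[t:t + k]
            if "N" not in kmer:
                read_kmers.setdefault(kmer, []).append(t)
        for g_idx, guide in enumerate(guides):
            votes: dict[int, int] = {}
            for p in range(len(guide) - k + 1):
                kmer = guide[p:p + k]
                if "N" in kmer:
                    continue
                for t in read_kmers.get(kmer, ()):
                    votes[p - t] = votes.get(p - t, 0) + 1
            for offset, count in votes.items():
                key = (-count, g_idx, offset, orient_bit)
                if best is None or key < best[0]:
                    best = (key, (g_idx, offset, orient_bit, count))
    return None if best is None else best[1]
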