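"""Assembly assessment: similarity matching, chimera detection, lengths.

Identity between an assembled transcript and a reference is the
free-end-gap global identity, maximized over both orientations of the
transcript (assembly orientation is arbitrary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .similarity import (_best_one_orientation, encode, reverse_complement,
                         strand_identity)

DEFAULT_THRESHOLDS = (0.90, 0.95, 0.99)


@dataclass
class MatchSummary:
    """Per-threshold counts of matched transcripts and references."""

    thresholds: tuple[float, ...]
    transcripts_matched: dict[float, int]
    references_matched: dict[float, int]
    identity: np.ndarray  # transcripts x references


@dataclass
class ChimeraVerdict:
    transcript_id: str
    labels: list[str | None]
    switches: int
    chimeric: bool


@dataclass
class ChimeraReport:
    verdicts: list[ChimeraVerdict]

    @property
    def n_chimeric(self) -> int:
        return sum(v.chimeric for v in self.verdicts)


@dataclass
class LengthStats:
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    outliers: list[int]


def identity_matrix(transcripts: list[tuple[str, str]],
                    references: list[tuple[str, str]]) -> np.ndarray:
    matrix = np.zeros((len(transcripts), len(references)))
    for i, (_, t_seq) in enumerate(transcripts):
        for j, (_, r_seq) in enumerate(references):
            matrix[i, j] = strand_identity(t_seq, r_seq)
    return matrix


def match_summary(transcripts: list[tuple[str, str]],
                  references: list[tuple[str, str]],
                  thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
                  ) -> MatchSummary:
    """Counts of transcripts with a reference match (and vice versa) per
    identity threshold.  Counts are monotone non-increasing in the
    threshold."""
    if not transcripts or not references:
        raise ValueError("both sequence sets must be non-empty")
    matrix = identity_matrix(transcripts, references)
    eps = 1e-12
    t_counts = {th: int(np.sum(matrix.max(axis=1) >= th - eps))
                for th in thresholds}
    r_counts = {th: int(np.sum(matrix.max(axis=0) >= th - eps))
                for th in thresholds}
    return MatchSummary(tuple(thresholds), t_counts, r_counts, matrix)


def _best_window_identity(fragment: str, reference_enc_fwd: np.ndarray,
                          reference_enc_rev: np.ndarray) -> float:
    """Best ungapped identity of the whole fragment anywhere on the
    reference, either strand."""
    frag = encode(fragment)
    best = -1
    for ref in (reference_enc_fwd, reference_enc_rev):
        hit = _best_one_orientation(frag, ref, len(frag))
        if hit is not None and hit[0] > best:
            best = hit[0]
    return best / len(fragment) if best >= 0 else 0.0


def detect_chimeras(transcripts: list[tuple[str, str]],
                    references: list[tuple[str, str]],
                    window: int = 50,
                    min_run: int = 3) -> ChimeraReport:
    """Per-window best-source labelling and crossover detection.

    Each non-overlapping ``window``-base block of a transcript is
    labelled with the reference of highest ungapped identity (ties give
    no label).  A transcript is chimeric when its label sequence
    switches between two maximal runs of at least ``min_run``
    consecutive windows each.
    """
    ref_enc = [(ref_id, encode(seq), encode(reverse_complement(seq)))
               for ref_id, seq in references]
    verdicts: list[ChimeraVerdict] = []
    for t_id, t_seq in transcripts:
        labels: list[str | None] = []
        for start in range(0, len(t_seq) - window + 1, window):
            fragment = t_seq[start:start + window]
            scores = [(_best_window_identity(fragment, fwd, rev), ref_id)
                      for ref_id, fwd, rev in ref_enc]
            best = max(score for score, _ in scores)
            winners = [ref_id for score, ref_id in scores
                       if score >= best - 1e-12]
            labels.append(winners[0] if len(winners) == 1 else None)
        runs: list[tuple[str, int]] = []
        for label in labels:
            if label is None:
                continue
            if runs and runs[-1][0] == label:
                runs[-1] = (label, runs[-1][1] + 1)
            else:
                runs.append((label, 1))
        supported = [label for label, count in runs if count >= min_run]
        switches = sum(1 for a, b in zip(supported, supported[1:]) if a != b)
        verdicts.append(ChimeraVerdict(t_id, labels, switches, switches >= 1))
    return ChimeraReport(verdicts)


def length_stats(sequences: list[str]) -> LengthStats:
    """Five-number summary with 1.5*IQR outliers (linear-interpolation
    quartiles)."""
    if not sequences:
        raise ValueError("need at least one sequence")
    lengths = np.array([len(s) for s in sequences], dtype=np.float64)
    q1, median, q3 = np.percentile(lengths, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outliers = [int(v) for v in lengths if v < lo or v > hi]
    return LengthStats(float(lengths.min()), float(q1), float(median),
                       float(q3), float(lengths.max()), outliers)


def write_report(summary: MatchSummary, chimeras: ChimeraReport,
                 path) -> None:
    with open(path, "w") as handle:
        handle.write("metric\tthreshold\tvalue\n")
        for th in summary.thresholds:
            handle.write(f"transcripts_matched\t{th}\t"
                         f"{summary.transcripts_matched[th]}\n")
            handle.write(f"references_matched\t{th}\t"
                         f"{summary.references_matched[th]}\n")
        handle.write(f"chimeric_transcripts\t-\t{chimeras.n_chimeric}\n")
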