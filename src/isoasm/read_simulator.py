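"""Paired-end read simulation from reference transcripts.

Forward reads are copied verbatim from random positions; each mate is
copied from a 500-base window anchored on the forward read's last base
(clipped to the transcript) and emitted reverse-complemented (FR
geometry).  Per-transcript read counts are proportional to transcript
length (largest-remainder rounding).  An optional per-site substitution
error is applied independently to every emitted base.  A truth table
records, for every read, its source, start, orientation and injected
errors, sufficient to reproduce the read byte-exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .sequence_io import FORWARD, REVERSE, Read, ReadPair, write_fastq
from .similarity import encode

log = logging.getLogger(__name__)

_CHARS = np.array(list("ACGTN"), dtype="U1")


@dataclass
class SimulationConfig:
    references: list[tuple[str, str]]
    n_reads: int
    read_len: int = 250
    pair_window: int = 500
    error_rate: float = 0.0
    rng_seed: int = 0

    def validated(self) -> "SimulationConfig":
        if not self.references:
            raise ValueError("no reference transcripts")
        if not 0.0 <= self.error_rate <= 0.05:
            raise ValueError(f"error_rate out of [0, 0.05]: {self.error_rate}")
        if self.pair_window < self.read_len:
            raise ValueError("pair_window must be >= read_len")
        usable = [r for r in self.references if len(r[1]) >= self.read_len]
        for ref_id, seq in self.references:
            if len(seq) < self.read_len:
                log.warning("reference %s shorter than read length; rejected",
                            ref_id)
        if not usable:
            raise ValueError("no reference is at least read_len long")
        if self.n_reads < len(usable):
            raise ValueError("n_reads must be >= number of usable references")
        return SimulationConfig(usable, self.n_reads, self.read_len,
                                self.pair_window, self.error_rate,
                                self.rng_seed)


@dataclass
class TruthRecord:
    read_id: str
    source_id: str
    start: int
    orientation: str
    errors: tuple[tuple[int, str], ...] = ()

    @property
    def n_errors(self) -> int:
        return len(self.errors)


def allocate_reads(references: list[tuple[str, str]], n_reads: int) -> list[int]:
    """Length-proportional counts summing exactly to ``n_reads``.

    Largest-remainder rounding; remainder ties go to the earlier
    reference.
    """
    lengths = np.array([len(seq) for _, seq in references], dtype=np.float64)
    exact = n_reads * lengths / lengths.sum()
    counts = np.floor(exact).astype(np.int64)
    remainders = exact - counts
    shortfall = n_reads - int(counts.sum())
    if shortfall:
        order = np.lexsort((np.arange(len(references)), -remainders))
        counts[order[:shortfall]] += 1
    return counts.tolist()


def _apply_errors(codes: np.ndarray, error_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently; returns the error mask."""
    if error_rate <= 0:
        return np.zeros(codes.shape, dtype=bool)
    mask = (rng.random(codes.shape) < error_rate) & (codes < 4)
    shifts = rng.integers(1, 4, size=codes.shape)
    codes[mask] = (codes[mask] + shifts[mask]) % 4
    return mask


def _rows_to_strings(codes: np.ndarray) -> list[str]:
    chars = _CHARS[codes]
    return ["".join(row) for row in chars]


def simulate(config: SimulationConfig
             ) -> tuple[list[ReadPair], list[TruthRecord]]:
    """Generate paired reads and the corresponding truth records."""
    config = config.validated()
    rng = np.random.default_rng(config.rng_seed)
    counts = allocate_reads(config.references, config.n_reads)
    pairs: list[ReadPair] = []
    truth: list[TruthRecord] = []
    serial = 0
    rl = config.read_len
    for (ref_id, ref_seq), count in zip(config.references, counts):
        if count == 0:
            continue
        ref = encode(ref_seq)
        length = len(ref)
        starts = rng.integers(0, length - rl + 1, size=count)
        ends = starts + rl
        mate_lo = np.maximum(ends - config.pair_window, 0)
        mate_hi = ends - rl  # mate interval must fit inside the window
        mate_starts = mate_lo + rng.integers(
            0, mate_hi - mate_lo + 1, size=count)
        fwd_codes = ref[starts[:, None] + np.arange(rl)[None, :]].copy()
        rev_codes = ref[mate_starts[:, None] + np.arange(rl)[None, :]]
        rev_codes = (3 - rev_codes)[:, ::-1].copy()  # reverse complement
        fwd_errors = _apply_errors(fwd_codes, config.error_rate, rng)
        rev_errors = _apply_errors(rev_codes, config.error_rate, rng)
        fwd_strings = _rows_to_strings(fwd_codes)
        rev_strings = _rows_to_strings(rev_codes)
        for row in range(count):
            serial += 1
            fragment = f"r{serial:07d}"
            fwd = Read(f"{fragment}/1", fwd_strings[row], None, FORWARD)
            rev = Read(f"{fragment}/2", rev_strings[row], None, REVERSE)
            pairs.append(ReadPair(fwd, rev))
            truth.append(TruthRecord(
                fwd.id, ref_id, int(starts[row]), FORWARD,
                _error_tuple(fwd_errors[row], fwd_codes[row])))
            truth.append(TruthRecord(
                rev.id, ref_id, int(mate_starts[row]), REVERSE,
                _error_tuple(rev_errors[row], rev_codes[row])))
    return pairs, truth


def _error_tuple(mask: np.ndarray, codes: np.ndarray
                 ) -> tuple[tuple[int, str], ...]:
    positions = np.nonzero(mask)[0]
    return tuple((int(p), str(_CHARS[codes[p]])) for p in positions)


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("read_id\tsource_id\tstart\torientation\terrors\n")
        for record in truth:
            errors = ",".join(f"{p}:{b}" for p, b in record.errors)
            handle.write(f"{record.read_id}\t{record.source_id}\t"
                         f"{record.start}\t{record.orientation}\t{errors}\n")


def simulate_to_files(config: SimulationConfig, out_dir: str | Path,
                      prefix: str = "sim") -> tuple[Path, Path, Path]:
    """Run the simulator and write ``_1``/``_2`` FASTQ plus a truth TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs, truth = simulate(config)
    path_1 = out_dir / f"{prefix}_1.fastq"
    path_2 = out_dir / f"{prefix}_2.fastq"
    truth_path = out_dir / f"{prefix}_truth.tsv"
    write_fastq((p.forward for p in pairs), path_1)
    write_fastq((p.reverse for p in pairs), path_2)
    write_truth(truth, truth_path)
    return path_1, path_2, truth_path


def make_isoform_families(n_families: int, isoforms_per_family: int,
                          length: int, divergence: float,
                          rng_seed: int = 0) -> list[tuple[str, str]]:
    """Synthetic reference set: families of diverged isoforms.

    Each family draws one random ancestor; every isoform substitutes a
    ``divergence`` fraction of sites at its own random positions.
    Different families are independent random sequences.
    """
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(rng_seed)
    references: list[tuple[str, str]] = []
    n_subs = int(round(divergence * length))
    for family in range(1, n_families + 1):
        ancestor = rng.integers(0, 4, size=length)
        for isoform in range(1, isoforms_per_family + 1):
            codes = ancestor.copy()
            if n_subs:
                positions = rng.choice(length, size=n_subs, replace=False)
                codes[positions] = (codes[positions]
                                    + rng.integers(1, 4, size=n_subs)) % 4
            references.append((f"fam{family}_iso{isoform}",
                               "".join(_CHARS[codes])))
    return references
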