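"""End-to-end orchestration of the six assembly stages.

All stochastic choices (partition seeding, expansion sampling, guide
seeding) draw from one seeded generator, so a fixed seed reproduces the
whole run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation, expression, guide_builder, isoform_network
from . import partitioner, read_simulator, scaffold_mapper, sequence_io, traversal
from .params import AssemblyParams, validate
from .sequence_io import FORWARD, Read, ReadPair

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    params: dict
    input_digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    stages: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, sort_keys=True)
            handle.write("\n")


@dataclass
class AssemblyResult:
    transcripts: list[traversal.Transcript]
    expression: expression.ExpressionTable | None
    manifest: RunManifest


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_assembly(reads: list[Read] | list[ReadPair],
                 params: AssemblyParams,
                 out_dir: str | Path | None = None,
                 keep_intermediates: bool = False) -> AssemblyResult:
    """Run stages (i)-(vi) on in-memory reads.

    Paired input enables mate-pair path confirmation; single-end input
    skips it (noted in the manifest).
    """
    params = validate(params)
    rng = np.random.default_rng(params.rng_seed)
    manifest = RunManifest(params=asdict(params))
    paired = bool(reads) and isinstance(reads[0], ReadPair)
    all_reads = sequence_io.flatten(reads)
    if not all_reads:
        raise StageError("load", "no input reads")
    reads_by_id = {read.id: read for read in all_reads}
    if len(reads_by_id) != len(all_reads):
        raise StageError("load", "duplicate read ids in input")
    manifest.counts["input_reads"] = len(all_reads)
    if not paired:
        manifest.notes.append("single-end input: pair confirmation skipped")

    # (i) partitioning over forward reads only
    forward = [r for r in all_reads if r.mate_role in (FORWARD, "unpaired")]
    manifest.counts["forward_reads"] = len(forward)
    partitions = partitioner.partition_reads(forward, params, rng)
    kept, deferred = partitioner.select_assemblable(
        partitions, params.min_partition_size)
    manifest.counts["partitions"] = len(partitions)
    manifest.counts["partitions_kept"] = len(kept)
    manifest.counts["reads_partitioned"] = sum(len(p) for p in kept)
    manifest.counts["reads_deferred"] = len(deferred)
    manifest.stages.append("partition")
    log.info("partitioning: %d partitions (%d kept), %d reads deferred",
             len(partitions), len(kept), len(deferred))

    # (ii) guide assembly per partition, reverse mates travelling along
    mate_of: dict[str, str] = {}
    if paired:
        for pair in reads:
            mate_of[pair.forward.id] = pair.reverse.id
            mate_of[pair.reverse.id] = pair.forward.id
    guides: list[guide_builder.GuideSequence] = []
    for partition in kept:
        pool = [reads_by_id[rid] for rid in partition.member_read_ids]
        pool += [reads_by_id[mate_of[rid]] for rid in partition.member_read_ids
                 if rid in mate_of]
        guides.extend(guide_builder.build_guides(
            pool, params, rng, source_partition=partition.id,
            next_id=len(guides)))
    manifest.counts["guides"] = len(guides)
    guides = guide_builder.merge_guides(guides, params, rng)
    manifest.counts["guides_merged"] = len(guides)
    manifest.stages.append("guides")
    if not guides:
        raise StageError("guides", "no guide sequences could be assembled")

    # (iii) map every input read (deferred ones re-enter here)
    scaffolds, unmapped = scaffold_mapper.build_scaffolds(
        all_reads, guides, params)
    manifest.counts["scaffolds"] = len(scaffolds)
    manifest.counts["reads_mapped"] = len(all_reads) - len(unmapped)
    manifest.counts["reads_unmapped"] = len(unmapped)
    manifest.stages.append("mapping")

    # (iv)+(v) network, traversal and pair confirmation per scaffold
    placements_by_read: dict[str, scaffold_mapper.Placement] = {}
    for scaffold in scaffolds:
        for placement in scaffold.placements:
            placements_by_read[placement.read_id] = placement
    paths_total = 0
    paths_kept: list[traversal.TranscriptPath] = []
    for scaffold in scaffolds:
        network = isoform_network.build_network(scaffold, reads_by_id, params)
        paths = traversal.traverse(network, params)
        paths_total += len(paths)
        for path in paths:
            if not paired or traversal.confirm_with_pairs(
                    path, mate_of, placements_by_read, params):
                paths_kept.append(path)
    manifest.counts["paths"] = paths_total
    manifest.counts["paths_confirmed"] = len(paths_kept)
    manifest.stages.extend(["network", "traversal"])

    transcripts = traversal.emit_transcripts(paths_kept, params)
    manifest.counts["transcripts"] = len(transcripts)

    # (vi) expression
    table: expression.ExpressionTable | None = None
    if transcripts:
        table = expression.quantify(transcripts, all_reads, params)
    manifest.stages.append("expression")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_transcripts(transcripts, out_dir / "transcripts.fasta")
        if table is not None:
            table.write_tsv(out_dir / "expression.tsv")
        manifest.write(out_dir / "manifest.json")
        if keep_intermediates:
            sequence_io.write_fasta(
                [(f"guide{g.id}", g.sequence, f"partition={g.source_partition}")
                 for g in guides], out_dir / "guides.fasta")
            scaffold_mapper.dump_scaffolds(scaffolds, out_dir / "scaffolds.tsv")
    return AssemblyResult(transcripts, table, manifest)


def write_transcripts(transcripts: list[traversal.Transcript],
                      path: str | Path) -> None:
    records = []
    for t in transcripts:
        percent = t.expression_percent if t.expression_percent is not None else 0.0
        records.append((t.id, t.sequence,
                        f"length={t.length} expression={percent:.2f}%"))
    sequence_io.write_fasta(records, path)


def run_assembly_files(reads_path: str | Path,
                       paired_path: str | Path | None,
                       params: AssemblyParams,
                       out_dir: str | Path | None = None,
                       keep_intermediates: bool = False) -> AssemblyResult:
    try:
        reads = sequence_io.load_reads(reads_path, paired_path)
    except (sequence_io.ParseError, sequence_io.PairingError,
            FileNotFoundError) as exc:
        raise StageError("load", str(exc)) from exc
    if not reads:
        raise StageError("load", f"no reads in {reads_path}")
    result = run_assembly(reads, params, out_dir, keep_intermediates)
    result.manifest.input_digests[str(reads_path)] = _digest(reads_path)
    if paired_path is not None:
        result.manifest.input_digests[str(paired_path)] = _digest(paired_path)
    if out_dir is not None:
        result.manifest.write(Path(out_dir) / "manifest.json")
    return result


@dataclass
class BenchmarkReport:
    summary: evaluation.MatchSummary
    chimeras: evaluation.ChimeraReport
    lengths_assembled: evaluation.LengthStats
    lengths_reference: evaluation.LengthStats
    result: AssemblyResult


def run_benchmark(references: list[tuple[str, str]],
                  n_reads: int,
                  params: AssemblyParams,
                  read_len: int = 250,
                  pair_window: int = 500,
                  error_rate: float = 0.0,
                  thresholds: tuple[float, ...] = evaluation.DEFAULT_THRESHOLDS
                  ) -> BenchmarkReport:
    """Simulate reads from references, assemble, and evaluate the result."""
    config = read_simulator.SimulationConfig(
        references=references, n_reads=n_reads, read_len=read_len,
        pair_window=pair_window, error_rate=error_rate,
        rng_seed=params.rng_seed)
    pairs, _ = read_simulator.simulate(config)
    result = run_assembly(pairs, params)
    if not result.transcripts:
        raise StageError("evaluate", "assembly produced no transcripts")
    assembled = [(t.id, t.sequence) for t in result.transcripts]
    summary = evaluation.match_summary(assembled, references, thresholds)
    chimeras = evaluation.detect_chimeras(assembled, references)
    return BenchmarkReport(
        summary, chimeras,
        evaluation.length_stats([seq for _, seq in assembled]),
        evaluation.length_stats([seq for _, seq in references]),
        result)
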