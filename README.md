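# isoasm

Multi-isoform *de novo* transcript assembly for read data harboring
closely related sequence variants, with explicit chimera avoidance.
The assembler never needs a reference transcriptome; it accepts single-
or paired-end FASTQ/FASTA reads and emits transcripts with
length-normalized expression percentages in their FASTA headers.

## Pipeline

Six stages, orchestrated by `isoasm.pipeline.run_assembly`:

1. **Partitioning** (`partitioner`) — forward reads are grouped by
   iterative seed expansion: a random read seeds a partition, reads
   sharing 70% identity over a 100-base window join, and up to 12 of
   each cycle's additions probe the remaining pool until the partition
   closes. Partitions of ≥3 reads proceed; smaller ones re-enter at
   mapping.
2. **Guide assembly** (`guide_builder`) — greedy overlap extension
   within each partition (98% identity over a 100-base window anchors a
   read; overhangs extend the growing guide), followed by a global
   merge pass.
3. **Mapping** (`scaffold_mapper`) — all input reads are placed on the
   guide they are most similar to via 10-mer positional voting,
   producing scaffold alignments.
4. **Networking** (`isoform_network`) — each scaffold is tiled with
   non-overlapping windows (one third of the minimum read length);
   reads fully spanning a window contribute truncated fragments that
   are hamming-clustered (96% identity) into nodes; edges connect
   adjacent-window nodes sharing at least two reads.
5. **Traversal** (`traversal`) — transcripts are walks through the
   network in which every extension beyond the second node requires a
   single physical read spanning the last three windows; paired-end
   data additionally discards paths whose mates map at a rate below
   30%.
6. **Expression** (`expression`) — reads are remapped to the final
   transcripts; per-transcript read density (count/length) is reported
   as a percent of the total.

A paired-read simulator (`read_simulator`) generates length-normalized
250-base read pairs from reference transcripts (mate drawn from a
500-base window anchored on the forward read's last base, optional
per-site substitution error, full truth records), and `evaluation`
provides identity match summaries, window-label chimera detection and
length statistics.

## CLI

```sh
# simulate 5000 read pairs from reference transcripts
isoasm simulate --references refs.fasta --n-reads 5000 --error-rate 0.002 \
    --seed 1 --out-dir sim/

# assemble (paired-end)
isoasm assemble --reads-1 sim/sim_1.fastq --reads-2 sim/sim_2.fastq \
    --seed 1 --out-dir asm/

# compare transcripts back to the references
isoasm evaluate --transcripts asm/transcripts.fasta --references refs.fasta \
    --out report.tsv

# simulate + assemble + evaluate in one step
isoasm benchmark --references refs.fasta --n-reads 5000 --seed 1 \
    --out bench.json
```

`assemble` and `benchmark` accept `--min-read-len` (≥120),
`--min-transcript-len`, `--min-isoform-sim`, `--seed`, and an optional
`--config key=value` file (flags win). `--keep-intermediates` dumps
guides, scaffold placements and network tables. All randomness flows
from the single seed: fixed seed, byte-identical outputs.

## Layout

```
src/isoasm/
  params.py           all thresholds in one validated dataclass
  sequence_io.py      FASTQ/FASTA I/O, mate-pair association
  similarity.py       windowed ungapped identity, global identity, k-mers
  partitioner.py      stage (i)   seed-and-expand read partitioning
  guide_builder.py    stage (ii)  greedy overlap guide assembly
  scaffold_mapper.py  stage (iii) k-mer vote mapping onto guides
  isoform_network.py  stage (iv)  windowed fragment-cluster networks
  traversal.py        stage (v)   triplet-linkage constrained walks
  expression.py       stage (vi)  length-normalized expression
  read_simulator.py   paired-read benchmark generator + truth records
  evaluation.py       match summaries, chimera detection, length stats
  pipeline.py         orchestration, manifest, benchmark driver
  cli.py              click CLI (simulate / assemble / evaluate / benchmark)
```
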