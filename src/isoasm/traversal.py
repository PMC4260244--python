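"""Stage (v): transcripts as linkage-constrained walks over the network.

Paths start at every node of the first window and at any node without an
incoming edge.  The second node of a path must be edge-connected to the
first (edges already require the minimum shared-read count); every later
node additionally requires at least one read present in the last two
nodes and the candidate — a single physical read spanning three
consecutive windows.  This triplet rule is what suppresses chimeric
walks.  Paths may be confirmed with mate pairs, then concatenated node
consensi become transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .isoform_network import IsoformNetwork, NetworkNode
from .params import AssemblyParams
from .scaffold_mapper import Placement, ScaffoldAlignment

log = logging.getLogger(__name__)


@dataclass
class TranscriptPath:
    network: IsoformNetwork
    nodes: list[NetworkNode]

    @property
    def read_ids(self) -> set[str]:
        out: set[str] = set()
        for node in self.nodes:
            out |= node.read_ids
        return out

    @property
    def span(self) -> tuple[int, int]:
        windows = self.network.windows
        return (windows[self.nodes[0].window_index].start,
                windows[self.nodes[-1].window_index].end)

    @property
    def sequence(self) -> str:
        return "".join(node.consensus for node in self.nodes)


@dataclass
class Transcript:
    id: str
    sequence: str
    scaffold_guide_id: int
    expression_percent: float | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def traverse(network: IsoformNetwork,
             params: AssemblyParams) -> list[TranscriptPath]:
    """All maximal triplet-valid walks through the network.

    Breadth-first with a live-path cap (``params.max_live_paths``) as a
    guard against degenerate branching; truncation logs a warning.
    """
    if not network.nodes:
        return []
    nodes_by_id = {node.node_id: node for node in network.nodes}
    successors: dict[int, list[int]] = {}
    has_incoming: set[int] = set()
    for edge in network.edges:
        successors.setdefault(edge.from_node, []).append(edge.to_node)
        has_incoming.add(edge.to_node)
    first_window = min(w.index for w in network.windows)
    starts = [node for node in network.nodes
              if node.window_index == first_window
              or node.node_id not in has_incoming]
    complete: list[TranscriptPath] = []
    frontier: list[list[NetworkNode]] = [[node] for node in starts]
    truncated = False
    while frontier:
        next_frontier: list[list[NetworkNode]] = []
        for path in frontier:
            last = path[-1]
            extensions: list[NetworkNode] = []
            for succ_id in sorted(successors.get(last.node_id, ())):
                candidate = nodes_by_id[succ_id]
                if len(path) >= 2:
                    triplet = (path[-2].read_ids & last.read_ids
                               & candidate.read_ids)
                    if not triplet:
                        continue
                extensions.append(candidate)
            if extensions:
                for candidate in extensions:
                    next_frontier.append(path + [candidate])
            else:
                complete.append(TranscriptPath(network, path))
        if len(next_frontier) > params.max_live_paths:
            truncated = True
            next_frontier = next_frontier[:params.max_live_paths]
        frontier = next_frontier
    if truncated:
        log.warning("traversal: live-path cap %d hit; some walks dropped",
                    params.max_live_paths)
    return complete


def confirm_with_pairs(path: TranscriptPath,
                       mate_of: dict[str, str],
                       placements_by_read: dict[str, Placement],
                       params: AssemblyParams) -> bool:
    """Keep a path unless fewer than the required fraction of mates map.

    A mate counts as mapped when it places on the same scaffold with an
    interval overlapping the path's span, in either orientation.  Paths
    whose supporting reads have no mates are kept.
    """
    guide_id = path.network.scaffold.guide.id
    span_lo, span_hi = path.span
    total = 0
    mapped = 0
    for read_id in path.read_ids:
        mate_id = mate_of.get(read_id)
        if mate_id is None:
            continue
        total += 1
        placement = placements_by_read.get(mate_id)
        if placement is None or placement.guide_id != guide_id:
            continue
        lo, hi = placement.interval
        if lo < span_hi and hi > span_lo:
            mapped += 1
    if total == 0:
        return True
    return mapped / total >= params.pair_confirm_fraction - 1e-12


def emit_transcripts(paths: list[TranscriptPath], params: AssemblyParams,
                     id_prefix: str = "t") -> list[Transcript]:
    """Concatenate node consensi; drop short and exact-duplicate sequences."""
    seen: set[str] = set()
    transcripts: list[Transcript] = []
    for path in paths:
        sequence = path.sequence
        if len(sequence) < params.min_transcript_len:
            continue
        if sequence in seen:
            continue
        seen.add(sequence)
        transcripts.append(Transcript(
            f"{id_prefix}{len(transcripts) + 1}", sequence,
            path.network.scaffold.guide.id))
    return transcripts
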