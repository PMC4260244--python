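"""Stage (iv): scaffolds become windowed isoform networks.

Non-overlapping windows (width = one third of the minimum read length)
tile each scaffold's span.  Reads fully spanning a window contribute a
truncated fragment; fragments are single-linkage clustered by hamming
identity into nodes; edges connect nodes in adjacent windows that
physically share at least two reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import AssemblyParams
from .scaffold_mapper import FORWARD, ScaffoldAlignment
from .sequence_io import Read
from .similarity import encode, reverse_complement

_BASES = "ACGT"


@dataclass(frozen=True)
class Window:
    index: int
    start: int
    end: int

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class Fragment:
    read_id: str
    window_index: int
    subsequence: str


@dataclass
class NetworkNode:
    node_id: int
    window_index: int
    fragments: list[Fragment]
    consensus: str

    @property
    def read_ids(self) -> frozenset[str]:
        return frozenset(f.read_id for f in self.fragments)


@dataclass
class NetworkEdge:
    from_node: int
    to_node: int
    shared_reads: int


@dataclass
class IsoformNetwork:
    scaffold: ScaffoldAlignment
    windows: list[Window]
    nodes: list[NetworkNode]
    edges: list[NetworkEdge]

    def nodes_in_window(self, index: int) -> list[NetworkNode]:
        return [n for n in self.nodes if n.window_index == index]


def define_windows(span: tuple[int, int], min_read_len: int) -> list[Window]:
    """Tile the span with width ``min_read_len // 3`` windows.

    A trailing remainder of at least half a window becomes a final short
    window; a smaller remainder is appended to the last full window.
    Spans shorter than one window yield no windows.
    """
    start, end = span
    width = min_read_len // 3
    length = end - start
    if length < width:
        return []
    n_full = length // width
    remainder = length - n_full * width
    windows = [Window(i, start + i * width, start + (i + 1) * width)
               for i in range(n_full)]
    if remainder * 2 >= width:
        windows.append(Window(n_full, start + n_full * width, end))
    elif remainder:
        last = windows[-1]
        windows[-1] = Window(last.index, last.start, end)
    return windows


def collect_fragments(scaffold: ScaffoldAlignment, windows: list[Window],
                      reads_by_id: dict[str, Read]) -> list[list[Fragment]]:
    """Per-window fragments from reads fully covering the window.

    Fragments are oriented to scaffold coordinates (reverse-complement
    placements contribute reverse-complemented subsequences).
    """
    per_window: list[list[Fragment]] = [[] for _ in windows]
    if not windows:
        return per_window
    first_start = windows[0].start
    width = windows[0].width
    for placement in scaffold.placements:
        seq = reads_by_id[placement.read_id].sequence
        if placement.orientation != FORWARD:
            seq = reverse_complement(seq)
        lo, hi = placement.offset, placement.offset + len(seq)
        # candidate window indices covered by [lo, hi)
        for window in windows:
            if window.start < lo:
                continue
            if window.end > hi:
                break
            per_window[window.index].append(Fragment(
                placement.read_id, window.index,
                seq[window.start - lo:window.end - lo]))
    return per_window


def cluster_fragments(fragments: list[Fragment],
                      min_isoform_sim: float,
                      next_node_id: int = 0) -> list[NetworkNode]:
    """Single-linkage hamming clustering of one window's fragments.

    Two fragments link when their per-column identity is at least
    ``min_isoform_sim``; clusters are the connected components.  Columns
    containing ``N`` never match.  Consensus is the majority base per
    column, ties resolved to the lexicographically smallest base.
    """
    if not fragments:
        return []
    width = len(fragments[0].subsequence)
    if any(len(f.subsequence) != width for f in fragments):
        raise ValueError("fragments within a window must share a length")
    mat = np.stack([encode(f.subsequence) for f in fragments])
    n = len(fragments)
    eq = (mat[:, None, :] == mat[None, :, :]) & \
         (mat[:, None, :] != 4) & (mat[None, :, :] != 4)
    identity = eq.sum(axis=2) / width
    adjacency = identity >= min_isoform_sim - 1e-12
    labels = _connected_components(adjacency)
    nodes: list[NetworkNode] = []
    for label in sorted(set(labels)):
        members = [fragments[i] for i in range(n) if labels[i] == label]
        rows = mat[[i for i in range(n) if labels[i] == label]]
        nodes.append(NetworkNode(next_node_id + len(nodes),
                                 members[0].window_index, members,
                                 _consensus(rows)))
    return nodes


def _connected_components(adjacency: np.ndarray) -> list[int]:
    n = len(adjacency)
    labels = [-1] * n
    current = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        stack = [start]
        labels[start] = current
        while stack:
            node = stack.pop()
            for neighbor in np.nonzero(adjacency[node])[0]:
                if labels[neighbor] == -1:
                    labels[neighbor] = current
                    stack.append(int(neighbor))
        current += 1
    return labels


def _consensus(rows: np.ndarray) -> str:
    counts = np.zeros((4, rows.shape[1]), dtype=np.int64)
    for code in range(4):
        counts[code] = (rows == code).sum(axis=0)
    best = counts.argmax(axis=0)  # argmax takes the first (lex smallest) on ties
    out = np.array(list(_BASES), dtype="U1")[best]
    out[counts.sum(axis=0) == 0] = "N"
    return "".join(out)


def build_network(scaffold: ScaffoldAlignment, reads_by_id: dict[str, Read],
                  params: AssemblyParams) -> IsoformNetwork:
    """Windows, clustered nodes and shared-read edges for one scaffold."""
    windows = define_windows(scaffold.span, params.min_read_len)
    per_window = collect_fragments(scaffold, windows, reads_by_id)
    nodes: list[NetworkNode] = []
    for fragments in per_window:
        nodes.extend(cluster_fragments(fragments, params.min_isoform_sim,
                                       next_node_id=len(nodes)))
    by_window: dict[int, list[NetworkNode]] = {}
    for node in nodes:
        by_window.setdefault(node.window_index, []).append(node)
    edges: list[NetworkEdge] = []
    for index in sorted(by_window):
        for left in by_window.get(index, []):
            for right in by_window.get(index + 1, []):
                shared = len(left.read_ids & right.read_ids)
                if shared >= params.edge_min_shared_reads:
                    edges.append(NetworkEdge(left.node_id, right.node_id, shared))
    return IsoformNetwork(scaffold, windows, nodes, edges)


def dump_network(network: IsoformNetwork, node_path, edge_path) -> None:
    with open(node_path, "w") as handle:
        handle.write("node_id\twindow\tn_fragments\tconsensus\n")
        for node in network.nodes:
            handle.write(f"{node.node_id}\t{node.window_index}\t"
                         f"{len(node.fragments)}\t{node.consensus}\n")
    with open(edge_path, "w") as handle:
        handle.write("from\tto\tshared_reads\n")
        for edge in network.edges:
            handle.write(f"{edge.from_node}\t{edge.to_node}\t{edge.shared_reads}\n")
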