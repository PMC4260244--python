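import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isoasm.guide_builder import GuideSequence
from isoasm.isoform_network import (Fragment, Window, build_network,
                                    cluster_fragments, collect_fragments,
                                    define_windows)
from isoasm.params import AssemblyParams, validate
from isoasm.scaffold_mapper import Placement, ScaffoldAlignment
from isoasm.sequence_io import Read

from .conftest import mutate, random_seq
from .oracles import hamming_components


class TestDefineWindows:
    def test_default_width_is_fifty(self):
        windows = define_windows((0, 150), 150)
        assert [(w.start, w.end) for w in windows] == \
            [(0, 50), (50, 100), (100, 150)]

    def test_remainder_at_half_width_becomes_short_window(self):
        windows = define_windows((0, 175), 150)
        assert [(w.start, w.end) for w in windows] == \
            [(0, 50), (50, 100), (100, 150), (150, 175)]

    def test_small_remainder_appended_to_last_window(self):
        windows = define_windows((0, 170), 150)
        assert [(w.start, w.end) for w in windows] == \
            [(0, 50), (50, 100), (100, 170)]

    def test_span_shorter_than_window_gives_none(self):
        assert define_windows((0, 49), 150) == []

    def test_windows_tile_span_from_nonzero_start(self):
        windows = define_windows((-30, 130), 150)
        assert windows[0].start == -30
        assert windows[-1].end == 130
        for left, right in zip(windows, windows[1:]):
            assert left.end == right.start

    @settings(max_examples=50, deadline=None)
    @given(st.integers(120, 400), st.integers(0, 2000))
    def test_tiling_is_total_and_disjoint(self, min_read_len, length):
        windows = define_windows((0, length), min_read_len)
        width = min_read_len // 3
        if length < width:
            assert windows == []
        else:
            assert windows[0].start == 0
            assert windows[-1].end == length
            for left, right in zip(windows, windows[1:]):
                assert left.end == right.start
            for window in windows[:-1]:
                assert window.width >= width


def _scaffold(guide_seq, placements):
    return ScaffoldAlignment(GuideSequence(0, guide_seq, 0), placements)


class TestCollectFragments:
    def test_exact_tiling_read(self, rng, default_params):
        guide = random_seq(rng, 200)
        read = Read("r1", guide[:150])
        scaffold = _scaffold(guide, [Placement("r1", 0, 0, "forward", 1, 150)])
        windows = define_windows((0, 150), 150)
        per_window = collect_fragments(scaffold, windows, {"r1": read})
        assert [len(f) for f in per_window] == [1, 1, 1]
        assert per_window[0][0].subsequence == guide[:50]

    def test_offset_read_covers_interior_windows_only(self, rng, default_params):
        guide = random_seq(rng, 250)
        read = Read("r1", guide[25:175])
        scaffold = _scaffold(guide, [Placement("r1", 0, 25, "forward", 1, 150)])
        windows = define_windows((0, 200), 150)
        per_window = collect_fragments(scaffold, windows, {"r1": read})
        assert [len(f) for f in per_window] == [0, 1, 1, 0]
        assert per_window[1][0].subsequence == guide[50:100]

    def test_uncovered_window_empty(self, default_params):
        scaffold = _scaffold("A" * 300, [])
        windows = define_windows((0, 300), 150)
        per_window = collect_fragments(scaffold, windows, {})
        assert all(len(f) == 0 for f in per_window)

    def test_reverse_placement_oriented_to_scaffold(self, rng):
        from isoasm.similarity import reverse_complement
        guide = random_seq(rng, 150)
        read = Read("r1", reverse_complement(guide[:150]))
        scaffold = _scaffold(guide, [Placement("r1", 0, 0, "reverse", 1, 150)])
        windows = define_windows((0, 150), 150)
        per_window = collect_fragments(scaffold, windows, {"r1": read})
        assert per_window[0][0].subsequence == guide[:50]


class TestClusterFragments:
    def test_identical_fragments_one_node(self, rng):
        seq = random_seq(rng, 50)
        fragments = [Fragment(f"r{i}", 0, seq) for i in range(20)]
        nodes = cluster_fragments(fragments, 0.96)
        assert len(nodes) == 1
        assert nodes[0].consensus == seq
        assert len(nodes[0].fragments) == 20

    def test_two_diverged_groups_two_nodes(self, rng):
        seq_a = random_seq(rng, 50)
        seq_b = mutate(rng, seq_a, 5)  # identity 0.90 < 0.96
        fragments = [Fragment(f"a{i}", 0, seq_a) for i in range(10)] + \
                    [Fragment(f"b{i}", 0, seq_b) for i in range(10)]
        nodes = cluster_fragments(fragments, 0.96)
        assert len(nodes) == 2
        labels = hamming_components([f.subsequence for f in fragments], 0.96)
        assert len(set(labels)) == 2

    def test_small_divergence_single_node(self, rng):
        seq = random_seq(rng, 50)
        fragments = [Fragment("r0", 0, seq),
                     Fragment("r1", 0, mutate(rng, seq, 2)),  # 0.96 boundary
                     Fragment("r2", 0, seq)]
        nodes = cluster_fragments(fragments, 0.96)
        assert len(nodes) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_components_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        base = random_seq(rng, 30)
        fragments = []
        for i in range(40):
            n_subs = int(rng.integers(0, 4))
            fragments.append(Fragment(f"r{i}", 0, mutate(rng, base, n_subs)))
        nodes = cluster_fragments(fragments, 0.9)
        labels = hamming_components([f.subsequence for f in fragments], 0.9)
        assert len(nodes) == len(set(labels))
        # membership conservation
        assert sum(len(n.fragments) for n in nodes) == len(fragments)

    def test_consensus_majority_with_lexicographic_ties(self):
        fragments = [Fragment("a", 0, "AC"), Fragment("b", 0, "AG"),
                     Fragment("c", 0, "TC"), Fragment("d", 0, "TG")]
        nodes = cluster_fragments(fragments, 0.0)
        assert len(nodes) == 1
        assert nodes[0].consensus == "AC"  # ties -> lexicographically smallest

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            cluster_fragments([Fragment("a", 0, "ACGT"),
                               Fragment("b", 0, "ACG")], 0.9)


class TestBuildNetwork:
    def _deep_scaffold(self, rng, length=400, n_reads=30, read_len=150):
        guide = random_seq(rng, length)
        placements, reads = [], {}
        for i in range(n_reads):
            start = int(rng.integers(0, length - read_len + 1))
            rid = f"r{i}"
            reads[rid] = Read(rid, guide[start:start + read_len])
            placements.append(Placement(rid, 0, start, "forward", 1, read_len))
        # guarantee edge-to-edge coverage with two reads at each end
        # (edges require at least two shared reads)
        for j, start in enumerate((0, 0, length - read_len, length - read_len)):
            rid = f"edge{j}"
            reads[rid] = Read(rid, guide[start:start + read_len])
            placements.append(Placement(rid, 0, start, "forward", 1, read_len))
        return _scaffold(guide, placements), reads

    def test_single_isoform_chain(self, rng, default_params):
        scaffold, reads = self._deep_scaffold(rng)
        network = build_network(scaffold, reads, default_params)
        per_window = {w.index: network.nodes_in_window(w.index)
                      for w in network.windows}
        assert all(len(nodes) == 1 for nodes in per_window.values())
        assert len(network.edges) == len(network.windows) - 1

    def test_single_shared_read_no_edge(self, rng, default_params):
        guide = random_seq(rng, 100)
        reads = {"r1": Read("r1", guide), "r2": Read("r2", guide[:50]),
                 "r3": Read("r3", guide[50:])}
        scaffold = _scaffold(guide, [
            Placement("r1", 0, 0, "forward", 1, 100),
            Placement("r2", 0, 0, "forward", 1, 50),
            Placement("r3", 0, 50, "forward", 1, 50)])
        network = build_network(scaffold, reads, default_params)
        # only r1 spans both windows: 1 shared read < 2 -> no edge
        assert network.edges == []

    def test_edges_only_between_adjacent_windows(self, rng, default_params):
        scaffold, reads = self._deep_scaffold(rng)
        network = build_network(scaffold, reads, default_params)
        window_of = {n.node_id: n.window_index for n in network.nodes}
        for edge in network.edges:
            assert window_of[edge.to_node] == window_of[edge.from_node] + 1

    def test_fragment_conservation(self, rng, default_params):
        scaffold, reads = self._deep_scaffold(rng)
        windows = define_windows(scaffold.span, default_params.min_read_len)
        per_window = collect_fragments(scaffold, windows, reads)
        network = build_network(scaffold, reads, default_params)
        for window in windows:
            nodes = network.nodes_in_window(window.index)
            assert sum(len(n.fragments) for n in nodes) == \
                len(per_window[window.index])
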