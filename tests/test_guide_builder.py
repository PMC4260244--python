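import numpy as np
import pytest

from isoasm.guide_builder import (GuideSequence, _GgsMatcher,
                                  _anchors_are_lossless, build_guides,
                                  merge_guides, try_extend)
from isoasm.params import AssemblyParams, validate
from isoasm.sequence_io import Read
from isoasm.similarity import reverse_complement

from .conftest import mutate, random_seq


class TestTryExtend:
    def test_suffix_extension(self, rng, default_params):
        ggs = random_seq(rng, 300)
        novel = random_seq(rng, 50)
        read = Read("r1", ggs[200:300] + novel)
        extended, status = try_extend(ggs, read, default_params)
        assert status == "extended"
        assert extended == ggs + novel
        assert len(extended) == 350

    def test_prefix_extension(self, rng, default_params):
        ggs = random_seq(rng, 300)
        novel = random_seq(rng, 40)
        read = Read("r1", novel + ggs[:110])
        extended, status = try_extend(ggs, read, default_params)
        assert status == "extended"
        assert extended == novel + ggs

    def test_contained_read_does_not_extend(self, rng, default_params):
        ggs = random_seq(rng, 300)
        read = Read("r1", ggs[50:250])
        extended, status = try_extend(ggs, read, default_params)
        assert status == "contained"
        assert extended == ggs

    def test_below_threshold_no_match(self, rng, default_params):
        ggs = random_seq(rng, 300)
        # 5 of 100 bases changed everywhere: best window 95% < 98%
        read = Read("r1", mutate(rng, ggs[180:300], 6) + random_seq(rng, 30))
        for start in range(0, 21):  # ensure no clean 100-window anywhere
            window = read.sequence[start:start + 100]
        _, status = try_extend(ggs, read, default_params)
        assert status in ("nomatch", "contained")  # never a clean extension

    def test_reverse_complement_read_extends(self, rng, default_params):
        ggs = random_seq(rng, 300)
        novel = random_seq(rng, 50)
        read = Read("r1", reverse_complement(ggs[200:300] + novel))
        extended, status = try_extend(ggs, read, default_params)
        assert status == "extended"
        assert extended == ggs + novel

    def test_overlap_keeps_ggs_bases(self, rng, default_params):
        ggs = random_seq(rng, 300)
        overlap = mutate(rng, ggs[200:300], 1)  # 99% identity window
        read = Read("r1", overlap + random_seq(rng, 20))
        extended, status = try_extend(ggs, read, default_params)
        assert status == "extended"
        assert extended[:300] == ggs  # GGS wins inside the overlap


class TestAnchoredMatcherEquivalence:
    def test_matches_full_scan(self, rng, default_params):
        assert _anchors_are_lossless(default_params)
        ggs = random_seq(rng, 500)
        matcher = _GgsMatcher(default_params)
        matcher.set_ggs(ggs)
        cases = [
            ggs[100:250] + random_seq(rng, 100),       # extendable
            mutate(rng, ggs[50:300], 3),               # noisy contained
            random_seq(rng, 250),                      # unrelated
            reverse_complement(ggs[200:450]),          # reverse
        ]
        from isoasm.similarity import best_window_match
        for seq in cases:
            fast = matcher.match(seq)
            full = best_window_match(ggs, seq, 100, 0.98)
            assert (fast is None) == (full is None)
            if fast is not None:
                assert (fast.offset_a, fast.offset_b, fast.orientation) == \
                    (full.offset_a, full.offset_b, full.orientation)


class TestBuildGuides:
    def test_tiled_reads_reconstruct_transcript(self, rng, default_params):
        transcript = random_seq(rng, 1000)
        reads = [Read(f"r{i}", transcript[s:s + 250])
                 for i, s in enumerate(range(0, 751, 125))]
        guides = build_guides(reads, default_params,
                              np.random.default_rng(0), source_partition=0)
        assert len(guides) >= 1
        longest = max(guides, key=lambda g: len(g.sequence))
        assert longest.sequence in transcript

    def test_three_identical_reads_one_guide(self, rng, default_params):
        seq = random_seq(rng, 250)
        reads = [Read(f"r{i}", seq) for i in range(3)]
        guides = build_guides(reads, default_params, np.random.default_rng(0))
        assert len(guides) == 1
        assert guides[0].sequence == seq

    def test_diverged_isoforms_separate_guides(self, rng, default_params):
        # 10% divergence everywhere: no 100-base window at >= 98%
        iso_a = random_seq(rng, 600)
        iso_b = "".join(
            mutate(rng, iso_a[i:i + 10], 1) for i in range(0, 600, 10))
        reads = [Read(f"a{i}", iso_a[s:s + 250])
                 for i, s in enumerate(range(0, 351, 70))] + \
                [Read(f"b{i}", iso_b[s:s + 250])
                 for i, s in enumerate(range(0, 351, 70))]
        guides = build_guides(reads, default_params, np.random.default_rng(1))
        assert len(guides) >= 2
        from isoasm.similarity import strand_identity
        for guide in guides:
            best = max(strand_identity(guide.sequence, iso_a),
                       strand_identity(guide.sequence, iso_b))
            assert best >= 0.99  # each guide tracks a single isoform

    def test_guide_bases_bounded_by_read_bases(self, rng, default_params):
        transcript = random_seq(rng, 900)
        reads = [Read(f"r{i}", transcript[s:s + 250])
                 for i, s in enumerate(range(0, 651, 50))]
        guides = build_guides(reads, default_params, np.random.default_rng(2))
        assert sum(len(g.sequence) for g in guides) <= \
            sum(len(r.sequence) for r in reads)


class TestMergeGuides:
    def test_overlapping_guides_merge(self, rng, default_params):
        base = random_seq(rng, 450)
        guides = [GuideSequence(0, base[:300], 0),
                  GuideSequence(1, base[150:], 1)]
        merged = merge_guides(guides, default_params, np.random.default_rng(0))
        assert len(merged) == 1
        assert merged[0].sequence == base

    def test_unrelated_guides_unchanged(self, rng, default_params):
        guides = [GuideSequence(0, random_seq(rng, 400), 0),
                  GuideSequence(1, random_seq(rng, 400), 1)]
        merged = merge_guides(guides, default_params, np.random.default_rng(0))
        assert sorted(g.sequence for g in merged) == \
            sorted(g.sequence for g in guides)

    def test_empty_input(self, default_params):
        assert merge_guides([], default_params) == []

    def test_count_non_increasing(self, rng, default_params):
        base = random_seq(rng, 800)
        guides = [GuideSequence(i, base[s:s + 300], i)
                  for i, s in enumerate(range(0, 501, 100))]
        merged = merge_guides(guides, default_params, np.random.default_rng(3))
        assert len(merged) <= len(guides)

    def test_contained_guide_absorbed(self, rng, default_params):
        base = random_seq(rng, 500)
        guides = [GuideSequence(0, base, 0),
                  GuideSequence(1, base[100:350], 1)]
        merged = merge_guides(guides, default_params, np.random.default_rng(0))
        assert len(merged) == 1
        assert merged[0].sequence == base
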