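"""BEDPE loop ingestion, the loop filters, and peak-anchored statistics."""

import pytest

from iceberg.intervals import GenomicInterval, IntervalError, IntervalSet
from iceberg.loops import Loop, filter_loops, peak_anchored_stats, read_bedpe

from conftest import make_set


def write_bedpe(path, rows):
    path.write_text("".join("\t".join(str(f) for f in row) + "\n" for row in rows))


class TestReadBedpe:
    def test_basic_row_with_counts(self, tmp_path):
        path = tmp_path / "loops.bedpe"
        write_bedpe(path, [("c", 1000, 2000, "c", 50_000, 51_000, 3, 4)])
        loops = read_bedpe(path, count_cols=(6, 7))
        assert len(loops) == 1
        assert loops[0].size == 50_000
        assert loops[0].counts == (3.0, 4.0)
        assert loops[0].strength == 3.5

    def test_reversed_anchors_normalized(self, tmp_path):
        path = tmp_path / "loops.bedpe"
        write_bedpe(path, [("c", 50_000, 51_000, "c", 1000, 2000)])
        loop = read_bedpe(path)[0]
        assert loop.anchor1.start == 1000 and loop.anchor2.end == 51_000
        assert loop.size == 50_000

    def test_interchromosomal_skipped(self, tmp_path):
        path = tmp_path / "loops.bedpe"
        write_bedpe(
            path,
            [
                ("c1", 0, 100, "c2", 500, 600),
                ("c1", 0, 100, "c1", 5000, 5100),
            ],
        )
        assert len(read_bedpe(path)) == 1

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "loops.bedpe"
        path.write_text("c\t0\t100\tc\t500\n")
        with pytest.raises(IntervalError, match=":1"):
            read_bedpe(path)


class TestFilterLoops:
    def loop(self, size, counts):
        return Loop(
            GenomicInterval("c", 0, 1000),
            GenomicInterval("c", size - 1000, size),
            counts=counts,
        )

    def test_small_loop_dropped(self):
        assert filter_loops([self.loop(4000, (3, 3))]) == []

    def test_low_mean_count_dropped(self):
        assert filter_loops([self.loop(50_000, (1, 2))]) == []  # mean 1.5 < 2

    def test_absent_in_one_replicate_dropped(self):
        assert filter_loops([self.loop(50_000, (2, 0))]) == []

    def test_boundaries(self):
        # size must be strictly greater than the threshold; mean is inclusive
        assert filter_loops([self.loop(5000, (3, 3))]) == []
        kept = filter_loops([self.loop(5001, (2, 2))])
        assert len(kept) == 1

    def test_all_predicates_hold_post_hoc(self):
        loops = [
            self.loop(size, counts)
            for size in (3000, 5001, 80_000)
            for counts in ((0, 5), (1, 2), (2, 2), (6, 8))
        ]
        for loop in filter_loops(loops):
            assert loop.size > 5000
            assert loop.strength >= 2
            assert all(c > 0 for c in loop.counts)

    def test_monotone_in_thresholds(self):
        loops = [self.loop(s, (c, c)) for s in (6000, 20_000, 90_000)
                 for c in (1, 2, 5)]
        base = len(filter_loops(loops))
        assert len(filter_loops(loops, min_size=30_000)) <= base
        assert len(filter_loops(loops, min_mean_count=4)) <= base


class TestMatchReplicateLoops:
    def test_both_anchors_must_overlap(self):
        from iceberg.loops import match_replicate_loops

        a = Loop(GenomicInterval("c", 0, 1000), GenomicInterval("c", 50_000, 51_000),
                 counts=(3,))
        same = Loop(GenomicInterval("c", 500, 1500),
                    GenomicInterval("c", 50_500, 51_500), counts=(4,))
        one_anchor_only = Loop(GenomicInterval("c", 500, 1500),
                               GenomicInterval("c", 80_000, 81_000), counts=(4,))
        matched = match_replicate_loops([a], [same])
        assert len(matched) == 1
        assert matched[0].counts == (3, 4)
        assert match_replicate_loops([a], [one_anchor_only]) == []


class TestPeakAnchoredStats:
    def test_loops_per_peak_division(self):
        peaks = {"hi": make_set([(0, 1000), (200_000, 201_000)], chrom="c")}
        loops = [
            Loop(
                GenomicInterval("c", 100, 300),
                GenomicInterval("c", 50_000 + i * 1000, 51_000 + i * 1000),
                counts=(3, 3),
            )
            for i in range(12)
        ]
        stats = peak_anchored_stats(loops, peaks)
        g = stats.groups["hi"]
        assert g.n_loops == 12 and g.n_peaks == 2
        assert g.loops_per_peak == 6.0

    def test_log10_size(self):
        loop = Loop(
            GenomicInterval("c", 0, 1000),
            GenomicInterval("c", 99_000, 100_000),
            counts=(2, 2),
        )
        stats = peak_anchored_stats([loop], {"g": make_set([(0, 500)], chrom="c")})
        assert stats.groups["g"].log10_sizes == [pytest.approx(5.0)]

    def test_peak_without_anchor_not_in_percent_numerator(self):
        peaks = {"g": make_set([(0, 1000), (500_000, 501_000)], chrom="c")}
        loop = Loop(
            GenomicInterval("c", 100, 300),
            GenomicInterval("c", 50_000, 51_000),
            counts=(2, 2),
        )
        stats = peak_anchored_stats([loop], peaks)
        assert stats.groups["g"].percent_peaks_in_loops == pytest.approx(50.0)

    def test_empty_group_reports_zeros(self):
        stats = peak_anchored_stats([], {"empty": IntervalSet([])})
        g = stats.groups["empty"]
        assert (g.n_loops, g.n_peaks, g.loops_per_peak) == (0, 0, 0.0)

    def test_loop_may_count_in_two_groups(self):
        groups = {
            "a": make_set([(0, 1000)], chrom="c"),
            "b": make_set([(50_000, 51_000)], chrom="c"),
        }
        loop = Loop(
            GenomicInterval("c", 100, 300),
            GenomicInterval("c", 50_100, 50_300),
            counts=(2, 2),
        )
        stats = peak_anchored_stats([loop], groups)
        assert stats.groups["a"].n_loops == 1
        assert stats.groups["b"].n_loops == 1

    def test_brute_force_recount(self):
        """Hand-countable fixture: statistics match a direct recount."""
        groups = {
            "x": make_set([(0, 100), (1000, 1100), (90_000, 90_100)], chrom="c"),
        }
        loops = [
            Loop(GenomicInterval("c", 50, 80), GenomicInterval("c", 30_000, 30_100),
                 counts=(2, 4)),
            Loop(GenomicInterval("c", 1050, 1090), GenomicInterval("c", 60_000, 60_100),
                 counts=(3, 3)),
            Loop(GenomicInterval("c", 40_000, 40_100), GenomicInterval("c", 70_000, 70_100),
                 counts=(5, 5)),  # anchors hit no peak
        ]
        g = peak_anchored_stats(loops, groups).groups["x"]
        assert g.n_loops == 2
        assert g.loops_per_peak == pytest.approx(2 / 3)
        assert g.percent_peaks_in_loops == pytest.approx(100 * 2 / 3)
        assert sorted(g.strengths) == [3.0, 3.0]
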