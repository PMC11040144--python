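"""Interval containers, BED I/O, and the interval algebra against
per-base coverage oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iceberg.genome import GenomeModel
from iceberg.intervals import (
    IntervalError,
    intersect_count,
    merge_intervals,
    overlap_matrix,
    read_intervals,
    regions_at_least,
    write_intervals,
)

from conftest import (
    coverage_array,
    make_set,
    oracle_merge,
    oracle_overlaps,
    oracle_regions_at_least,
)


class TestGenomeModel:
    def test_round_trip_and_order(self, tmp_path):
        g = GenomeModel([("chr2", 500), ("chr1", 1000)])
        path = tmp_path / "genome.chrom.sizes"
        g.to_chrom_sizes(path)
        g2 = GenomeModel.from_chrom_sizes(path)
        assert g2.names == ["chr2", "chr1"]  # order of appearance, not lexicographic
        assert g2.length("chr1") == 1000

    def test_rejects_duplicates_and_bad_lengths(self):
        from iceberg.genome import GenomeError

        with pytest.raises(GenomeError):
            GenomeModel([("c", 10), ("c", 20)])
        with pytest.raises(GenomeError):
            GenomeModel([("c", 0)])


class TestBedIO:
    def test_unsorted_input_is_sorted(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t500\t600\nchr1\t10\t20\nchr1\t100\t300\n")
        ivs = read_intervals(path)
        assert [(iv.start, iv.end) for iv in ivs] == [(10, 20), (100, 300), (500, 600)]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.bed"
        path.write_text("")
        assert len(read_intervals(path)) == 0

    def test_start_after_end_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t10\t20\nchr1\t100\t50\n")
        with pytest.raises(IntervalError, match="bad.bed:2"):
            read_intervals(path)

    def test_non_integer_coordinate_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\tx\t20\n")
        with pytest.raises(IntervalError, match="bad.bed:1"):
            read_intervals(path)

    def test_comment_track_lines_skipped_and_extra_columns_ignored(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text(
            "# comment\ntrack name=x\nbrowser position\n"
            "chr1\t0\t10\tname\t960\t+\n"
        )
        ivs = read_intervals(path)
        assert len(ivs) == 1

    def test_write_read_round_trip(self, tmp_path):
        original = make_set([(3, 9), (15, 40), (40, 41)])
        path = tmp_path / "out.bed"
        write_intervals(original, path)
        assert read_intervals(path) == original

    def test_write_empty_set(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_intervals(make_set([]), path)
        assert path.read_text() == ""

    def test_genome_bounds_enforced(self, tmp_path):
        genome = GenomeModel([("chr1", 50)])
        path = tmp_path / "a.bed"
        path.write_text("chr1\t10\t100\n")
        with pytest.raises(IntervalError):
            read_intervals(path, genome=genome)


class TestMerge:
    def test_empty(self):
        assert len(merge_intervals(make_set([]))) == 0

    def test_overlapping_pair(self):
        merged = merge_intervals(make_set([(0, 10), (5, 20)]))
        assert [(iv.start, iv.end) for iv in merged] == [(0, 20)]

    def test_book_ended_merged_at_gap_zero(self):
        merged = merge_intervals(make_set([(0, 5), (5, 10)]), gap=0)
        assert [(iv.start, iv.end) for iv in merged] == [(0, 10)]

    def test_gap_bridges_separation(self):
        s = make_set([(0, 5), (8, 10)])
        assert len(merge_intervals(s, gap=2)) == 2
        assert len(merge_intervals(s, gap=3)) == 1

    def test_negative_gap_rejected(self):
        with pytest.raises(IntervalError):
            merge_intervals(make_set([(0, 5)]), gap=-1)


class TestIntersectCount:
    def test_identical_sets(self):
        s = make_set([(0, 10), (20, 30)])
        count, mask = intersect_count(s, s)
        assert count == 2 and mask.all()

    def test_disjoint_chromosomes(self):
        a = make_set([(0, 10)], chrom="chr1")
        b = make_set([(0, 10)], chrom="chr2")
        assert intersect_count(a, b)[0] == 0

    def test_half_open_boundary(self):
        a = make_set([(0, 10)])
        assert intersect_count(a, make_set([(9, 20)]))[0] == 1
        assert intersect_count(a, make_set([(10, 20)]))[0] == 0

    def test_counted_at_most_once(self):
        a = make_set([(0, 100)])
        b = make_set([(10, 20), (30, 40), (50, 60)])
        assert intersect_count(a, b)[0] == 1


class TestOverlapMatrix:
    def test_single_set_single_interval(self):
        m = overlap_matrix([make_set([(5, 15)])], ["a"])
        assert len(m.segments) == 1
        assert m.membership.tolist() == [[True]]

    def test_two_set_segmentation(self):
        a, b = make_set([(0, 10)], chrom="c"), make_set([(5, 15)], chrom="c")
        m = overlap_matrix([a, b], ["a", "b"])
        segs = [(iv.start, iv.end) for iv in m.segments]
        assert segs == [(0, 5), (5, 10), (10, 15)]
        assert m.membership.tolist() == [
            [True, False],
            [True, True],
            [False, True],
        ]

    def test_identical_sets_all_flagged(self):
        s = make_set([(0, 10), (20, 30)])
        m = overlap_matrix([s, s], ["a", "b"])
        assert m.membership.all()

    def test_duplicate_labels_rejected(self):
        with pytest.raises(IntervalError):
            overlap_matrix([make_set([(0, 1)]), make_set([(2, 3)])], ["x", "x"])

    def test_reconstruction_identity(self):
        """Flagged segments reproduce each input's base coverage exactly."""
        rng = np.random.default_rng(11)
        genome_len = 2000
        sets = []
        for _ in range(4):
            starts = rng.integers(0, genome_len - 30, size=12)
            sets.append(
                make_set([(int(s), int(s + rng.integers(1, 30))) for s in starts])
            )
        m = overlap_matrix(sets)
        for j, s in enumerate(sets):
            reconstructed = coverage_array(
                [seg for seg, flag in zip(m.segments, m.membership[:, j]) if flag],
                genome_len,
            )
            assert np.array_equal(reconstructed, coverage_array(s, genome_len))


class TestRegionsAtLeast:
    def test_three_set_example(self, toy_sets):
        m = overlap_matrix(list(toy_sets))
        x1 = regions_at_least(m, 1)
        assert [(iv.start, iv.end) for iv in x1] == [(0, 15), (20, 30)]
        x2 = regions_at_least(m, 2)
        assert [(iv.start, iv.end) for iv in x2] == [(5, 10)]
        assert len(regions_at_least(m, 3)) == 0

    def test_x_out_of_range(self, toy_sets):
        m = overlap_matrix(list(toy_sets))
        for bad in (0, 4):
            with pytest.raises(IntervalError):
                regions_at_least(m, bad)

    def test_identical_sets_any_threshold(self):
        s = make_set([(0, 10), (50, 80)])
        m = overlap_matrix([s, s, s])
        for x in (1, 2, 3):
            assert regions_at_least(m, x) == merge_intervals(s)

    def test_base_coverage_nested_in_x(self):
        rng = np.random.default_rng(5)
        genome_len = 5000
        sets = [
            make_set(
                [
                    (int(s), int(s) + int(rng.integers(1, 60)))
                    for s in rng.integers(0, genome_len - 60, size=15)
                ]
            )
            for _ in range(5)
        ]
        m = overlap_matrix(sets)
        prev = None
        for x in range(1, 6):
            cov = coverage_array(regions_at_least(m, x), genome_len)
            if prev is not None:
                assert not np.any(cov & ~prev)  # coverage shrinks with x
            prev = cov


@st.composite
def interval_lists(draw, genome_len=300, max_intervals=12):
    n = draw(st.integers(0, max_intervals))
    out = []
    for _ in range(n):
        start = draw(st.integers(0, genome_len - 2))
        end = draw(st.integers(start + 1, genome_len))
        out.append((start, end))
    return out


@settings(max_examples=60, derandomize=True, deadline=None)
@given(pairs=interval_lists(), gap=st.integers(0, 20))
def test_merge_matches_coverage_oracle(pairs, gap):
    merged = merge_intervals(make_set(pairs), gap=gap)
    assert [(iv.start, iv.end) for iv in merged] == oracle_merge(
        make_set(pairs), 300, gap=gap
    )


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    sets=st.lists(interval_lists(), min_size=1, max_size=4),
    data=st.data(),
)
def test_regions_at_least_matches_coverage_oracle(sets, data):
    interval_sets = [make_set(p) for p in sets]
    m = overlap_matrix(interval_sets)
    x = data.draw(st.integers(1, len(sets)))
    got = [(iv.start, iv.end) for iv in regions_at_least(m, x)]
    assert got == oracle_regions_at_least(interval_sets, 300, x)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(a=interval_lists(), b=interval_lists())
def test_intersect_matches_per_base_oracle(a, b):
    a_set, b_set = make_set(a), make_set(b)
    b_cov = coverage_array(b_set, 300)
    count, mask = intersect_count(a_set, b_set)
    expected = [oracle_overlaps(iv, b_cov) for iv in a_set]
    assert mask.tolist() == expected
    assert count == sum(expected)
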