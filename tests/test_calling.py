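"""The Poisson window caller: significance arithmetic, FDR control on
null data, spike recovery, and threshold nesting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iceberg.calling import (
    PeakCallError,
    PeakCallParams,
    benjamini_hochberg,
    call_peaks,
    threshold_peaks,
    window_p_value,
)
from iceberg.fragments import FragmentSet
from iceberg.genome import GenomeModel
from iceberg.intervals import GenomicInterval

from conftest import uniform_fragments


def spike_fragments(genome_len, n_bg, spike_region, n_spike, seed, frag_len=170):
    bg = uniform_fragments(n_bg, genome_len, seed)
    rng = np.random.default_rng(seed + 1)
    lo, hi = spike_region
    centers = rng.uniform(lo, hi, size=n_spike)
    spikes = [
        GenomicInterval(
            "chr1",
            max(0, int(c - frag_len / 2)),
            min(genome_len, int(c + frag_len / 2)),
        )
        for c in centers
    ]
    return FragmentSet.from_fragments(
        list(bg) + spikes, replicate_id="spiked", chrom_names=["chr1"]
    )


class TestWindowPValue:
    def test_exact_poisson_tail(self):
        """P(X >= 10 | lam=2) equals the explicit tail sum."""
        lam = 2.0
        head = sum(math.exp(-lam) * lam**k / math.factorial(k) for k in range(10))
        assert window_p_value(10, lam) == pytest.approx(1.0 - head, rel=1e-12)

    def test_zero_count_is_certain(self):
        assert window_p_value(0, 5.0) == 1.0


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.05], [0.05]),
            ([0.5, 0.5], [0.5, 0.5]),
        ],
    )
    def test_hand_computed_examples(self, p, expected):
        assert benjamini_hochberg(p) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [-0.1]):
            with pytest.raises(PeakCallError):
                benjamini_hochberg(bad)

    def test_input_order_preserved(self):
        p = [0.04, 0.01]
        assert benjamini_hochberg(p) == pytest.approx([0.04, 0.02])

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        p=st.lists(
            st.floats(1e-6, 1.0, exclude_min=False, allow_nan=False),
            min_size=1,
            max_size=200,
        )
    )
    def test_matches_brute_force_definition(self, p):
        """q_i = min over p_j >= p_i of m * p_j / rank_j."""
        q = benjamini_hochberg(p)
        m = len(p)
        ranks = {}
        for rank, idx in enumerate(np.argsort(np.asarray(p), kind="stable"), start=1):
            ranks[idx] = rank
        for i in range(m):
            brute = min(
                min(m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]), 1.0
            )
            assert q[i] == pytest.approx(brute, rel=1e-12)


class TestCallPeaks:
    def test_identical_treatment_and_control_yields_almost_nothing(self):
        frags = uniform_fragments(10_000, 1_000_000, seed=7)
        genome = GenomeModel([("chr1", 1_000_000)])
        result = call_peaks(frags, frags, genome)
        assert len(result) <= 2

    def test_spike_gives_exactly_one_covering_peak(self):
        genome = GenomeModel([("chr1", 100_000)])
        treat = spike_fragments(100_000, 1000, (50_000, 50_200), 200, seed=11)
        ctrl = uniform_fragments(1000, 100_000, seed=12)
        result = call_peaks(treat, ctrl, genome)
        assert len(result) == 1
        peak = result.peaks[0].interval
        assert peak.start < 50_200 and peak.end > 50_000
        assert result.peaks[0].summit in range(peak.start, peak.end)

    def test_zero_depth_control_instructs_pseudo_mode(self):
        genome = GenomeModel([("chr1", 1000)])
        treat = uniform_fragments(100, 1000, seed=1)
        empty = FragmentSet.from_fragments([], chrom_names=["chr1"])
        with pytest.raises(PeakCallError, match="pseudo-control"):
            call_peaks(treat, empty, genome)

    def test_pseudo_control_mode_finds_spike(self):
        genome = GenomeModel([("chr1", 100_000)])
        treat = spike_fragments(100_000, 1000, (30_000, 30_200), 150, seed=3)
        result = call_peaks(treat, None, genome)
        assert len(result) >= 1
        assert any(
            p.interval.start < 30_200 and p.interval.end > 30_000 for p in result
        )

    def test_fold_enrichment_ranks_invariant_to_depth_scaling(self):
        genome = GenomeModel([("chr1", 200_000)])
        rng = np.random.default_rng(9)
        weak = spike_fragments(200_000, 0, (50_000, 50_200), 40, seed=21)
        strong = spike_fragments(200_000, 0, (150_000, 150_200), 120, seed=22)
        bg = uniform_fragments(2000, 200_000, seed=23)
        treat = FragmentSet.from_fragments(
            list(bg) + list(weak) + list(strong), chrom_names=["chr1"]
        )
        ctrl = uniform_fragments(2000, 200_000, seed=24)
        doubled_treat = FragmentSet.from_fragments(
            list(treat) * 2, chrom_names=["chr1"]
        )
        doubled_ctrl = FragmentSet.from_fragments(
            list(ctrl) * 2, chrom_names=["chr1"]
        )
        def spike_signals(result):
            out = {}
            for region, tag in (((50_000, 50_200), "weak"),
                                ((150_000, 150_200), "strong")):
                hits = [
                    p.signal
                    for p in result
                    if p.interval.start < region[1] and p.interval.end > region[0]
                ]
                assert len(hits) == 1
                out[tag] = hits[0]
            return out

        # doubling depth adds power (possibly more marginal peaks) but the
        # fold-enrichment ordering of the planted spikes must not change
        for result in (
            call_peaks(treat, ctrl, genome),
            call_peaks(doubled_treat, doubled_ctrl, genome),
        ):
            signals = spike_signals(result)
            assert signals["strong"] > signals["weak"]

    def test_null_fdr_quick(self):
        """Fraction of significant windows on null data stays below alpha."""
        genome = GenomeModel([("chr1", 500_000)])
        n_sig, n_windows = 0, 0
        for seed in range(3):
            treat = uniform_fragments(5000, 500_000, seed=100 + seed)
            ctrl = uniform_fragments(5000, 500_000, seed=200 + seed)
            result = call_peaks(treat, ctrl, genome)
            n_sig += len(result)
            n_windows += 500_000 // 25
        assert n_sig / n_windows <= 0.05


class TestThresholdPeaks:
    @pytest.fixture()
    def called(self):
        genome = GenomeModel([("chr1", 100_000)])
        treat = spike_fragments(100_000, 1000, (50_000, 50_200), 200, seed=31)
        ctrl = uniform_fragments(1000, 100_000, seed=32)
        return call_peaks(
            treat, ctrl, genome, PeakCallParams(threshold_mode="p", threshold=0.01)
        )

    def test_cutoff_one_retains_all(self, called):
        assert len(threshold_peaks(called, "p", 1.0)) == len(called)

    def test_cutoff_below_min_p_empties(self, called):
        min_p = min(p.p_value for p in called)
        assert len(threshold_peaks(called, "p", min_p / 2)) == 0

    def test_stricter_is_subset_of_looser(self, called):
        loose = {p.interval for p in threshold_peaks(called, "q", 0.05)}
        strict = {p.interval for p in threshold_peaks(called, "q", 0.001)}
        assert strict <= loose

    def test_q_mode_filters_on_q(self, called):
        kept = threshold_peaks(called, "q", 0.05)
        assert all(p.q_value < 0.05 for p in kept)

    def test_invalid_cutoff_rejected(self, called):
        for bad in (0.0, 1.5, -0.2):
            with pytest.raises(PeakCallError):
                threshold_peaks(called, "p", bad)


def test_params_validation():
    with pytest.raises(PeakCallError):
        PeakCallParams(window=10, step=20)
    with pytest.raises(PeakCallError):
        PeakCallParams(local_scales=(10,))
    with pytest.raises(PeakCallError):
        PeakCallParams(threshold_mode="q", threshold=1.5)
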