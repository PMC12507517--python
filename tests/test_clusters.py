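"""Cluster analysis: anchors, cumulative windows, correlation, ranked halves."""

import math

import numpy as np
import pytest
from scipy import stats

from conftest import make_peak, make_site
from oracles import brute_pearson

from kbsites import (
    CohortSpec,
    compare_ranked_halves,
    correlation_curve,
    count_weak_sites,
    cumulative_z,
    gen_peak_cohort,
    gen_zscore_table,
    select_anchor,
)


class TestSelectAnchor:
    def test_unique_maximum(self):
        sites = [make_site(100, 14.0), make_site(300, 5.8)]
        assert select_anchor(sites, region_center=250).start == 100

    def test_tie_broken_by_distance_to_center(self):
        sites = [make_site(100, 7.0), make_site(260, 7.0)]
        assert select_anchor(sites, region_center=250).start == 260

    def test_remaining_tie_broken_by_start(self):
        sites = [make_site(240, 7.0), make_site(250, 7.0)]
        # centers 245 and 255 are equidistant from 250 -> smaller start wins
        assert select_anchor(sites, region_center=250).start == 240

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="no designated"):
            select_anchor([], region_center=250)


class TestCumulativeZ:
    @pytest.fixture
    def peak(self):
        # strong anchor plus weak sites 40 bp and 220 bp downstream
        return make_peak("p1", 20.0, [(400, 14.0), (440, 5.8), (620, 3.1)])

    def test_window_100_keeps_anchor_and_near_site(self, peak):
        assert cumulative_z(peak, 100) == pytest.approx(19.8)

    def test_window_500_keeps_all(self, peak):
        assert cumulative_z(peak, 500) == pytest.approx(22.9)

    def test_excluding_weak_leaves_anchor(self, peak):
        assert cumulative_z(peak, 500, include_weak=False) == pytest.approx(14.0)

    def test_monotone_and_nested_on_synthetic_cohort(self):
        table = gen_zscore_table(150, seed=5)
        peaks, _ = gen_peak_cohort(CohortSpec(n_peaks=20, seed=5), table)
        for p in peaks:
            prev_all = prev_strong = -1.0
            for L in range(10, 501, 10):
                cz_all = cumulative_z(p, L, include_weak=True)
                cz_strong = cumulative_z(p, L, include_weak=False)
                assert cz_all >= prev_all and cz_strong >= prev_strong
                assert cz_strong <= cz_all
                prev_all, prev_strong = cz_all, cz_strong

    def test_bad_window_rejected(self, peak):
        with pytest.raises(ValueError):
            cumulative_z(peak, 0)


class TestCountWeakSites:
    def test_counts_only_weak_class(self):
        peak = make_peak("p", 1.0, [(400, 14.0), (440, 5.8), (480, 3.0)])
        assert count_weak_sites(peak) == 2

    def test_strong_anchor_alone_counts_zero(self):
        assert count_weak_sites(make_peak("p", 1.0, [(400, 14.0)])) == 0

    def test_window_restriction(self):
        # weak sites at +100 and +400 from the anchor center
        peak = make_peak("p", 1.0, [(400, 14.0), (500, 5.0), (800, 5.0)])
        assert count_weak_sites(peak, window_length=500) == 1
        assert count_weak_sites(peak, window_length=1000) == 2


class TestCorrelationCurve:
    def _cohort(self, seed=11, n=30):
        table = gen_zscore_table(150, seed=seed)
        peaks, _ = gen_peak_cohort(CohortSpec(n_peaks=n, seed=seed), table)
        return peaks

    def test_perfect_linear_relation_gives_r_one(self):
        peaks = self._cohort()
        for p in peaks:
            p.chip_score = cumulative_z(p, 150)
        curve = correlation_curve(peaks, [150])
        assert curve.r_at(150) == pytest.approx(1.0)

    def test_equals_textbook_pearson(self):
        peaks = self._cohort()
        curve = correlation_curve(peaks, [10, 150, 500])
        for L in (10, 150, 500):
            x = [p.chip_score for p in peaks]
            y = [cumulative_z(p, L) for p in peaks]
            assert curve.r_at(L) == pytest.approx(brute_pearson(x, y), rel=1e-12)

    def test_zero_variance_marked_undefined(self):
        peaks = self._cohort(n=5)
        for p in peaks:
            p.chip_score = 3.0
        curve = correlation_curve(peaks, [10, 500])
        assert all(math.isnan(r) for r in curve.r_all + curve.r_strong_only)

    def test_too_few_peaks(self):
        with pytest.raises(ValueError, match=">= 3"):
            correlation_curve(self._cohort(n=4)[:2], [100])

    def test_signal_peaks_at_planted_span(self):
        table = gen_zscore_table(200, seed=1)
        spec = CohortSpec(n_peaks=100, span_bp=150, alpha=1.0, noise_sd=0.0, seed=1)
        peaks, _ = gen_peak_cohort(spec, table)
        curve = correlation_curve(peaks, [10, 150])
        assert curve.r_at(150) >= curve.r_at(10)


class TestRankedHalves:
    def _peaks_with_counts(self, top_counts, bottom_counts):
        peaks = []
        scores = list(range(len(top_counts) + len(bottom_counts), 0, -1))
        for i, c in enumerate(list(top_counts) + list(bottom_counts)):
            specs = [(400, 14.0)] + [(420 + 20 * j, 3.0) for j in range(c)]
            peaks.append(make_peak(f"r{i:02d}", float(scores[i]), specs))
        return peaks

    def test_identical_groups_degenerate(self):
        res = compare_ranked_halves(self._peaks_with_counts([3, 3], [3, 3]))
        assert (res.t_statistic, res.p_value) == (0.0, 1.0)

    def test_pooled_t_matches_hand_computation(self):
        res = compare_ranked_halves(self._peaks_with_counts([5, 6, 7], [1, 2, 3]))
        # pooled variance 1, t = 4 / sqrt(2/3), df = 4
        t_hand = 4.0 / math.sqrt(2.0 / 3.0)
        assert res.t_statistic == pytest.approx(t_hand, abs=5e-4)
        assert round(res.t_statistic, 3) == 4.899
        assert res.p_value == pytest.approx(2 * stats.t.sf(t_hand, df=4), rel=1e-9)
        assert res.p_value < 0.01
        assert (res.mean_top, res.mean_bottom) == (6.0, 2.0)

    def test_odd_n_extra_peak_goes_to_bottom(self):
        res = compare_ranked_halves(self._peaks_with_counts([4, 4], [1, 1, 1]))
        assert (res.n_top, res.n_bottom) == (2, 3)

    def test_planted_excess_detected(self):
        table = gen_zscore_table(200, seed=7)
        peaks, _ = gen_peak_cohort(CohortSpec(n_peaks=60, seed=7), table)
        res = compare_ranked_halves(peaks)
        assert res.p_value < 0.05
        assert res.mean_top > res.mean_bottom

    def test_too_few_peaks(self):
        with pytest.raises(ValueError, match=">= 4"):
            compare_ranked_halves(self._peaks_with_counts([1], [1, 2]))
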