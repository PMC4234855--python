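import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from peakscale.er_calls import (
    bh_qvalues,
    binomial_pvalue,
    find_summit,
    find_trough,
    merge_ssers,
    strand_concordance_filter,
    trim_pvalue_min,
)
from peakscale.mappability import MultiMappabilityProfile
from peakscale.preprocess import FragmentIndex
from peakscale.signal_io import GenomicInterval, SignalProfile


class TestMergeSsers:
    def test_overlap_coalesced(self):
        out = merge_ssers([GenomicInterval("c", 10, 20), GenomicInterval("c", 15, 30)])
        assert out == [GenomicInterval("c", 10, 30)]

    def test_book_ended_coalesced(self):
        out = merge_ssers([GenomicInterval("c", 10, 20), GenomicInterval("c", 20, 30)])
        assert out == [GenomicInterval("c", 10, 30)]

    def test_disjoint_untouched(self):
        ivs = [GenomicInterval("c", 10, 20), GenomicInterval("c", 40, 50)]
        assert merge_ssers(ivs) == ivs

    def test_repeated_interval_idempotent(self):
        ivs = [GenomicInterval("c", 10, 20)] * 5
        assert merge_ssers(ivs) == [GenomicInterval("c", 10, 20)]

    def test_chromosomes_kept_separate(self):
        ivs = [GenomicInterval("a", 10, 20), GenomicInterval("b", 10, 20)]
        assert len(merge_ssers(ivs)) == 2


class TestBinomialPvalue:
    def test_one_vs_one(self):
        # single normalized count on each side: p = C(2,2) * 0.5^2
        assert binomial_pvalue(1, 1, 10, 10, 10) == pytest.approx(0.25)

    def test_nine_vs_one(self):
        assert binomial_pvalue(9, 1, 10, 10, 10) == pytest.approx(0.5**10)

    def test_zero_control_gives_zero(self):
        assert binomial_pvalue(5, 0, 10, 10, 10) == 0.0

    def test_both_zero_gives_one(self):
        assert binomial_pvalue(0, 0, 10, 10, 10) == 1.0

    def test_matches_printed_sum(self):
        # direct expansion of the upper-tail sum for several count pairs
        for nc, nk in [(3, 2), (7, 7), (12, 4), (0, 5)]:
            total = nc + nk
            expected = sum(
                binom.pmf(r, total, 0.5) for r in range(nc + 1, total + 1)
            )
            assert binomial_pvalue(nc, nk, 50, 50, 50) == pytest.approx(expected)

    def test_length_normalization_scales_counts(self):
        # 20 reads over 2000 bp scaled to a 100 bp window -> 1 vs 1
        assert binomial_pvalue(20, 20, 2000, 2000, 100) == pytest.approx(0.25)

    def test_monotone_decreasing_in_chip_count(self):
        p = [binomial_pvalue(n, 10, 100, 100, 100) for n in range(0, 40)]
        assert all(b <= a for a, b in zip(p, p[1:]))

    def test_inclusive_convention(self):
        exclusive = binomial_pvalue(1, 1, 10, 10, 10)
        inclusive = binomial_pvalue(1, 1, 10, 10, 10, inclusive=True)
        assert inclusive == pytest.approx(0.75)
        assert inclusive > exclusive

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            binomial_pvalue(-1, 1, 10, 10, 10)


class TestBHQvalues:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_qvalues([0.2]), [0.2])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_qvalues([1.0] * 5), 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200))
    def test_matches_statsmodels_reference(self, p_values):
        from statsmodels.stats.multitest import multipletests

        ours = bh_qvalues(p_values)
        _, reference, _, _ = multipletests(p_values, method="fdr_bh")
        np.testing.assert_allclose(ours, reference, atol=1e-12)

    def test_threshold_agrees_with_step_up_rule(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 500) ** 2
        q = bh_qvalues(p)
        alpha = 0.05
        p_sorted = np.sort(p)
        below = np.flatnonzero(p_sorted <= alpha * np.arange(1, 501) / 500)
        n_reject = below[-1] + 1 if below.size else 0
        assert (q <= alpha).sum() == n_reject


def _index(positions, length=100_000, frag=20):
    positions = np.asarray(positions, dtype=np.int64)
    return FragmentIndex(positions, np.minimum(positions + frag, length))


class TestTrimPvalueMin:
    def test_uniform_enrichment_unchanged(self):
        # strong flat enrichment, empty control: the objective is flat at
        # its minimum and ties resolve to the widest region
        chip = _index(np.arange(100, 300))
        ctrl = _index([])
        iv = GenomicInterval("c", 100, 320)
        out = trim_pvalue_min(iv, chip, ctrl, 1.0)
        assert (out.start, out.end) == (100, 320)

    def test_right_half_enrichment_moves_start(self):
        # control dense enough that every sub-region holds control mass;
        # the printed tail is exactly 0 whenever the control count is 0,
        # which would otherwise dominate the minimization
        rng = np.random.default_rng(1)
        chip_pos = np.concatenate([
            rng.integers(0, 1000, 300),       # background everywhere
            rng.integers(500, 1000, 1200),    # enrichment in the right half
        ])
        ctrl_pos = rng.integers(0, 1000, 300)
        chip = _index(np.sort(chip_pos), frag=40)
        ctrl = _index(np.sort(ctrl_pos), frag=40)
        iv = GenomicInterval("c", 0, 1000)
        out = trim_pvalue_min(iv, chip, ctrl, 1.0)
        assert 400 <= out.start <= 560
        assert out.end > 900

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(2)
        chip_pos = np.sort(np.concatenate([
            rng.integers(0, 200, 30), rng.integers(80, 150, 60)
        ]))
        ctrl_pos = np.sort(rng.integers(0, 200, 30))
        chip, ctrl = _index(chip_pos, frag=10), _index(ctrl_pos, frag=10)
        iv = GenomicInterval("c", 0, 200)
        out = trim_pvalue_min(iv, chip, ctrl, 1.0)

        def logp(s, e):
            nc = chip.count(s, e)
            nk = ctrl.count(s, e)
            total = nc + nk
            if total == 0:
                return 0.0
            if nk == 0:
                return -np.inf
            return float(binom.logsf(nc, total, 0.5))

        # pass 1: best start against the fixed end, widest tie
        p1 = [logp(s, 200) for s in range(0, 200)]
        best_start = int(np.argmin(p1))
        # pass 2: best end for that start, widest tie
        p2 = [logp(best_start, e) for e in range(best_start + 1, 201)]
        arr = np.asarray(p2)
        best_end = best_start + 1 + (arr.size - 1 - int(np.argmin(arr[::-1])))
        assert (out.start, out.end) == (best_start, best_end)

    def test_output_contained_and_non_empty(self):
        rng = np.random.default_rng(3)
        chip = _index(np.sort(rng.integers(0, 500, 100)))
        ctrl = _index(np.sort(rng.integers(0, 500, 100)))
        iv = GenomicInterval("c", 50, 450)
        out = trim_pvalue_min(iv, chip, ctrl, 1.0)
        assert 50 <= out.start < out.end <= 450


class TestStrandConcordance:
    def _profiles(self, plus_total, minus_total, n=100):
        plus = SignalProfile("c", np.full(n, plus_total / n))
        minus = SignalProfile("c", np.full(n, minus_total / n))
        return plus, minus

    @pytest.mark.parametrize(
        "s_plus,s_minus,kept",
        [(20, 20, True), (10, 30, False), (10, 20, True), (30, 10, False)],
    )
    def test_factor_two_boundary(self, s_plus, s_minus, kept):
        plus, minus = self._profiles(s_plus, s_minus)
        iv = GenomicInterval("c", 0, 100)
        assert strand_concordance_filter(iv, plus, minus) is kept

    def test_single_strand_signal_discarded(self):
        plus, minus = self._profiles(20, 0)
        assert strand_concordance_filter(GenomicInterval("c", 0, 100), plus, minus) is False

    def test_no_signal_discarded(self):
        plus, minus = self._profiles(0, 0)
        assert strand_concordance_filter(GenomicInterval("c", 0, 100), plus, minus) is False


class TestSummitAndTrough:
    def test_summit_is_leftmost_maximum(self):
        raw = SignalProfile("c", np.array([1, 5, 2]))
        assert find_summit(GenomicInterval("c", 0, 3), raw) == 1
        raw = SignalProfile("c", np.array([1, 5, 5]))
        assert find_summit(GenomicInterval("c", 0, 3), raw) == 1
        raw = SignalProfile("c", np.array([3, 3, 3]))
        assert find_summit(GenomicInterval("c", 0, 3), raw) == 0

    def _mm(self, values, threshold=1.2):
        return MultiMappabilityProfile("c", np.asarray(values, dtype=float), threshold)

    def test_single_peak_has_no_trough(self):
        raw = SignalProfile("c", np.array([0, 2, 5, 2, 0]))
        mm = self._mm(np.ones(5))
        assert find_trough(GenomicInterval("c", 0, 5), raw, mm) is None

    def test_mappable_valley_between_two_peaks(self):
        values = np.array([0, 1, 6, 7, 6, 3, 1, 3, 6, 8, 6, 1, 0])
        raw = SignalProfile("c", values)
        mm = self._mm(np.ones(values.size))
        trough = find_trough(GenomicInterval("c", 0, values.size), raw, mm, window=2)
        assert trough == 6  # the minimum between the peaks at 3 and 9

    def test_repeat_valley_suppressed(self):
        values = np.array([0, 1, 6, 7, 6, 3, 1, 3, 6, 8, 6, 1, 0])
        raw = SignalProfile("c", values)
        mm = self._mm(np.full(values.size, 3.0))
        assert find_trough(GenomicInterval("c", 0, values.size), raw, mm, window=2) is None
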