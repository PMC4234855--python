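import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peakscale.multiscale import (
    CandidateER,
    candidate_ers,
    decompose,
    filter_oversmoothed,
    find_extrema,
    make_schedule,
    median_filter,
)
from peakscale.signal_io import GenomicInterval, SignalProfile


def naive_median(x: np.ndarray, window: int) -> np.ndarray:
    """Per-position sort-based median oracle; lower middle for even sizes."""
    half = window // 2
    out = np.empty_like(x)
    for i in range(x.size):
        w = np.sort(x[max(0, i - half) : i + half + 1])
        out[i] = w[(w.size - 1) // 2]
    return out


class TestMakeSchedule:
    def test_default_spectrum_has_25_scales(self):
        schedule = make_schedule(100, 2_500_000, 1.5)
        assert len(schedule) == 25
        assert schedule.windows[:4] == (100, 150, 225, 337)

    def test_single_scale(self):
        assert make_schedule(100, 100, 1.5).windows == (100,)

    def test_small_start_matches_direct_evaluation(self):
        schedule = make_schedule(10, 2_500_000, 1.5)
        assert schedule.windows[:4] == (10, 15, 22, 33)
        expected = []
        k = 0
        while True:
            w = int(np.floor(10 * 1.5**k))
            if w > 2_500_000:
                break
            if not expected or expected[-1] != w:
                expected.append(w)
            k += 1
        assert list(schedule.windows) == expected

    def test_strictly_increasing(self):
        windows = make_schedule(2, 1000, 1.1).windows
        assert all(b > a for a, b in zip(windows, windows[1:]))

    @pytest.mark.parametrize("args", [(0, 100, 1.5), (100, 100, 1.0), (200, 100, 1.5)])
    def test_invalid_parameters_raise(self, args):
        with pytest.raises(ValueError):
            make_schedule(*args)


class TestMedianFilter:
    def test_constant_profile_unchanged(self):
        p = SignalProfile("c", np.full(50, 4))
        for window in (1, 3, 10, 49):
            np.testing.assert_array_equal(median_filter(p, window).values, p.values)

    def test_impulse_removed(self):
        p = SignalProfile("c", np.array([0, 0, 9, 0, 0]))
        out = median_filter(p, 3).values
        np.testing.assert_array_equal(out, naive_median(p.values, 3))
        assert out[2] == 0

    @pytest.mark.parametrize("window", [1, 2, 3, 5, 10, 31, 100])
    def test_matches_naive_oracle(self, window):
        rng = np.random.default_rng(window)
        x = rng.poisson(5, 300)
        out = median_filter(SignalProfile("c", x), window).values
        np.testing.assert_array_equal(out, naive_median(x, window))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.integers(min_value=0, max_value=40), min_size=1, max_size=120),
        window=st.integers(min_value=1, max_value=60),
    )
    def test_oracle_property(self, values, window):
        x = np.asarray(values, dtype=np.int64)
        out = median_filter(SignalProfile("c", x), window).values
        np.testing.assert_array_equal(out, naive_median(x, window))

    def test_bounded_by_input_range(self):
        rng = np.random.default_rng(7)
        x = rng.integers(2, 9, 200)
        out = median_filter(SignalProfile("c", x), 21).values
        assert out.min() >= x.min() and out.max() <= x.max()


class TestFindExtrema:
    def test_strictly_increasing_has_no_interior_extrema(self):
        minima, maxima = find_extrema(np.arange(10))
        assert minima.size == 0 and maxima.size == 0

    def test_alternating_profile(self):
        minima, maxima = find_extrema(np.array([0, 1, 2, 1, 0, 1, 2]))
        np.testing.assert_array_equal(maxima, [2])
        np.testing.assert_array_equal(minima, [4])

    def test_plateau_yields_first_position(self):
        minima, maxima = find_extrema(np.array([0, 2, 2, 2, 0]))
        np.testing.assert_array_equal(maxima, [1])
        assert minima.size == 0

    def test_matches_neighborhood_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 6, 200)
        minima, maxima = find_extrema(x)
        # oracle: scan runs of equal values; a run lower than both distinct
        # neighbors is a minimum at its first position, symmetric for maxima
        runs = []
        start = 0
        for i in range(1, x.size + 1):
            if i == x.size or x[i] != x[start]:
                runs.append((start, i, x[start]))
                start = i
        exp_min, exp_max = [], []
        for k in range(1, len(runs) - 1):
            s, _, v = runs[k]
            left, right = runs[k - 1][2], runs[k + 1][2]
            if v < left and v < right:
                exp_min.append(s)
            if v > left and v > right:
                exp_max.append(s)
        np.testing.assert_array_equal(minima, exp_min)
        np.testing.assert_array_equal(maxima, exp_max)


class TestCandidateERs:
    def _decomp(self, values, windows=(3,)):
        profile = SignalProfile("c", np.asarray(values, dtype=np.int64))
        schedule = make_schedule(windows[0], windows[-1], 1.5)
        return decompose(profile, schedule), profile

    def test_single_bump_single_candidate(self):
        x = [0, 0, 1, 3, 5, 3, 1, 0, 0]
        decomp, raw = self._decomp(x)
        cands = candidate_ers(decomp, raw)[0]
        assert len(cands) == 1
        assert cands[0].max_raw == 5

    def test_flat_zero_profile_has_no_candidates(self):
        decomp, raw = self._decomp([0] * 20)
        assert candidate_ers(decomp, raw) == [[]]

    def test_two_bumps_merge_at_wide_scale(self):
        x = np.zeros(240, dtype=np.int64)
        x[40:80] = 6
        x[120:160] = 6  # valley of 40 bp between bumps of 40 bp
        profile = SignalProfile("c", x)
        narrow = decompose(profile, make_schedule(21, 21, 1.5))
        wide = decompose(profile, make_schedule(121, 121, 1.5))
        n_narrow = len(candidate_ers(narrow, profile)[0])
        n_wide = len(candidate_ers(wide, profile)[0])
        assert n_narrow == 2
        assert n_wide == 1

    def test_candidates_tile_without_overlap(self):
        rng = np.random.default_rng(11)
        profile = SignalProfile("c", rng.poisson(4, 500))
        decomp = decompose(profile, make_schedule(9, 9, 1.5))
        cands = candidate_ers(decomp, profile)[0]
        for a, b in zip(cands, cands[1:]):
            assert a.interval.end == b.interval.start

    def test_planted_block_survives_below_twice_width(self):
        x = np.zeros(4000, dtype=np.int64)
        x[1000:1500] = 8  # 500 bp block
        profile = SignalProfile("c", x)
        for window in (201, 501, 901):
            decomp = decompose(profile, make_schedule(window, window, 1.5))
            cands = candidate_ers(decomp, profile)[0]
            covering = [
                c for c in cands
                if c.interval.start <= 1250 < c.interval.end and c.max_smoothed >= 4
            ]
            assert covering, f"block lost at window {window}"


class TestFilterOversmoothed:
    def _cand(self, max_raw, max_smoothed):
        return CandidateER(GenomicInterval("c", 0, 10), 0, max_smoothed, max_raw)

    @pytest.mark.parametrize(
        "max_raw,max_smoothed,kept",
        [(5, 5, True), (10, 2, False), (8, 2, True), (1, 1, True)],
    )
    def test_ratio_threshold(self, max_raw, max_smoothed, kept):
        out = filter_oversmoothed([self._cand(max_raw, max_smoothed)], gamma=4)
        assert bool(out) is kept

    def test_zero_smoothed_max_discarded(self):
        assert filter_oversmoothed([self._cand(3, 0)], gamma=4) == []
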