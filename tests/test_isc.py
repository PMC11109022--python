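"""Windowed ISC against a naive oracle, window arithmetic, Fisher transform."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from audiencesync import (
    CHANNELS,
    WindowSpec,
    fisher_z,
    fisher_z_inv,
    pairwise_isc,
    sliding_window_isc,
    window_starts,
    windowed_pair_correlation,
)

from conftest import make_recording, make_track, random_masked_arrays


def naive_pearson(x, y):
    """Textbook Pearson r, written independently of the moment pipeline."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx <= 0 or syy <= 0:
        return math.nan
    return sxy / math.sqrt(sxx * syy)


def naive_windowed_corr(track_a, track_b, channel_idx, spec):
    """Oracle: per-window pairwise-complete Pearson r via explicit slicing."""
    x = track_a.intensities[:, channel_idx]
    y = track_b.intensities[:, channel_idx]
    joint = track_a.valid_mask & track_b.valid_mask
    out = []
    start = 0
    while start + spec.window_len <= len(x):
        m = joint[start : start + spec.window_len]
        cnt = int(m.sum())
        if cnt < max(spec.min_valid_fraction * spec.window_len, 3):
            out.append(math.nan)
        else:
            xs = [float(v) for v in x[start : start + spec.window_len][m]]
            ys = [float(v) for v in y[start : start + spec.window_len][m]]
            out.append(naive_pearson(xs, ys))
        start += spec.step
    return np.array(out)


class TestWindowStarts:
    def test_count_formula(self):
        starts = window_starts(9000, WindowSpec(3000, 100))
        assert len(starts) == 61
        assert starts[0] == 0 and starts[-1] == 6000

    def test_single_window_at_exact_length(self):
        assert window_starts(3000, WindowSpec(3000, 100)).tolist() == [0]

    def test_partial_window_dropped(self):
        assert len(window_starts(3099, WindowSpec(3000, 100))) == 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            window_starts(2999, WindowSpec(3000, 100))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 500), st.integers(1, 100), st.integers(0, 400))
    def test_count_property(self, window_len, step, extra):
        step = min(step, window_len)
        n = window_len + extra
        starts = window_starts(n, WindowSpec(window_len, step, 0.5))
        assert len(starts) == (n - window_len) // step + 1
        assert all(s + window_len <= n for s in starts)


class TestWindowedPairCorrelation:
    SPEC = WindowSpec(window_len=100, step=40, min_valid_fraction=0.5)

    def test_identical_sinusoids(self):
        t = np.arange(400)
        x = np.tile((0.5 + 0.4 * np.sin(t / 7))[:, None], (1, 8))
        a, b = make_track("a", x), make_track("b", x.copy())
        r = windowed_pair_correlation(a, b, "happy", self.SPEC)
        np.testing.assert_allclose(r, 1.0, atol=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.random((300, 8)) * 0.5
        y = 0.2 + 0.5 * x
        a, b = make_track("a", x), make_track("b", y)
        r = windowed_pair_correlation(a, b, "sad", self.SPEC)
        np.testing.assert_allclose(r, 1.0, atol=1e-10)

    def test_symmetry(self, rng):
        xs = random_masked_arrays(rng, 2, 300, missing_frac=0.2)
        a, b = make_track("a", xs[0]), make_track("b", xs[1])
        r_ab = windowed_pair_correlation(a, b, "fear", self.SPEC)
        r_ba = windowed_pair_correlation(b, a, "fear", self.SPEC)
        np.testing.assert_array_equal(r_ab, r_ba)

    def test_low_coverage_window_missing(self, rng):
        x = rng.random((100, 8))
        y = rng.random((100, 8))
        y[:60] = np.nan  # joint coverage 40% < 50%
        a, b = make_track("a", x), make_track("b", y)
        spec = WindowSpec(100, 100, 0.5)
        assert np.isnan(windowed_pair_correlation(a, b, "happy", spec)[0])

    def test_unknown_expression(self, rng):
        xs = random_masked_arrays(rng, 2, 120, 0)
        with pytest.raises(KeyError):
            windowed_pair_correlation(make_track("a", xs[0]),
                                      make_track("b", xs[1]),
                                      "joy", self.SPEC)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(2024)
        spec = WindowSpec(window_len=80, step=30, min_valid_fraction=0.4)
        for _ in range(10):
            xs = random_masked_arrays(rng, 2, 300, missing_frac=0.25)
            a, b = make_track("a", xs[0]), make_track("b", xs[1])
            for j, ch in enumerate(CHANNELS):
                fast = windowed_pair_correlation(a, b, ch, spec)
                slow = naive_windowed_corr(a, b, j, spec)
                np.testing.assert_allclose(fast, slow, atol=1e-10)


class TestSlidingWindowISC:
    def test_identical_tracks(self, rng):
        x = rng.random((300, 8))
        rec = make_recording([x.copy() for _ in range(3)])
        tc = sliding_window_isc(rec, WindowSpec(100, 50, 0.5))
        np.testing.assert_allclose(tc.mean_r, 1.0, atol=1e-10)
        assert np.all(tc.n_pairs == 3)

    def test_missing_pairs_excluded_from_mean(self, rng):
        # pair (a,b): r = 1; pair (a,c): r = 0; pair (b,c): insufficient overlap
        W = 40
        base = np.zeros((W, 8))
        base[:, 1] = np.tile([0.0, 1.0], W // 2)          # period 2
        ortho = np.zeros((W, 8))
        ortho[:, 1] = np.tile([0.0, 0.0, 1.0, 1.0], W // 4)  # period 4
        a = base.copy()
        b = base.copy()
        b[12:24] = np.nan            # joint(b,c) = 12 frames < half window
        c = ortho.copy()
        c[24:] = np.nan              # joint(a,c) = 24 frames >= half window
        for arr in (a, b, c):        # give the other channels variance
            arr[:, 0] = np.linspace(0.1, 0.9, W)
        rec = make_recording([a, b, c])
        tc = sliding_window_isc(rec, WindowSpec(W, W, 0.5))
        happy = CHANNELS.index("happy")
        assert tc.n_pairs[0, happy] == 2
        assert tc.mean_r[0, happy] == pytest.approx(0.5)

    def test_participant_order_invariance(self, rng):
        arrays = random_masked_arrays(rng, 4, 300, 0.1)
        rec1 = make_recording(arrays)
        rec2 = make_recording(arrays[::-1])
        spec = WindowSpec(100, 50, 0.5)
        tc1 = sliding_window_isc(rec1, spec)
        tc2 = sliding_window_isc(rec2, spec)
        np.testing.assert_allclose(tc1.mean_r, tc2.mean_r, atol=1e-12,
                                   equal_nan=True)

    def test_null_audience_time_course_near_zero(self):
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            arrays = [np.clip(0.5 + 0.1 * rng.standard_normal((3200, 8)), 0, 1)
                      for _ in range(10)]
            rec = make_recording(arrays)
            tc = sliding_window_isc(rec)
            means.append(np.nanmean(tc.mean_r))
        assert -0.03 < np.mean(means) < 0.03

    def test_single_participant_rejected(self, rng):
        rec = make_recording(random_masked_arrays(rng, 1, 200))
        with pytest.raises(ValueError):
            sliding_window_isc(rec, WindowSpec(100, 100))


class TestPairwiseISC:
    def test_identical_tracks_clipped_z(self, rng):
        x = rng.random((200, 8))
        rec = make_recording([x.copy(), x.copy()])
        tab = pairwise_isc(rec)
        assert np.allclose(tab.r, 1.0)
        assert np.allclose(tab.z, np.arctanh(1 - 1e-7))
        assert tab.z.iloc[0] == pytest.approx(8.4, abs=0.1)

    def test_whole_series_equals_single_window(self, rng):
        arrays = random_masked_arrays(rng, 3, 240, 0.1)
        rec = make_recording(arrays)
        spec = WindowSpec(window_len=240, step=240, min_valid_fraction=0.1)
        whole = pairwise_isc(rec, "whole_series")
        windowed = pairwise_isc(rec, "window_mean", spec)
        np.testing.assert_allclose(whole.r, windowed.r, atol=1e-10)

    def test_z_is_atanh_of_r(self, rng):
        rec = make_recording(random_masked_arrays(rng, 3, 300, 0.1))
        tab = pairwise_isc(rec)
        ok = tab.r.notna()
        np.testing.assert_allclose(
            tab.z[ok], np.arctanh(np.clip(tab.r[ok], -(1 - 1e-7), 1 - 1e-7))
        )

    def test_sparse_pair_missing(self):
        rng = np.random.default_rng(3)
        x = rng.random((50, 8))
        y = rng.random((50, 8))
        y[2:] = np.nan   # only 2 joint frames
        rec = make_recording([x, y])
        tab = pairwise_isc(rec)
        assert tab.r.isna().all()

    def test_unordered_pairs_sorted_by_id(self, rng):
        rec = make_recording(random_masked_arrays(rng, 3, 100, 0))
        tab = pairwise_isc(rec)
        assert (tab.participant_a < tab.participant_b).all()
        assert len(tab) == 3 * 8


class TestFisherTransform:
    @pytest.mark.parametrize(
        "r,expected",
        [(0.0, 0.0), (0.5, 0.549306), (-0.9, -1.472219)],
    )
    def test_known_values(self, r, expected):
        assert fisher_z(r) == pytest.approx(expected, abs=1e-6)

    def test_round_trip_grid(self):
        r = np.linspace(-0.999, 0.999, 1999)
        assert np.max(np.abs(fisher_z_inv(fisher_z(r)) - r)) <= 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    def test_odd_and_increasing(self):
        r = np.linspace(-0.99, 0.99, 199)
        z = fisher_z(r)
        np.testing.assert_allclose(z, -fisher_z(-r))
        assert np.all(np.diff(z) > 0)

    def test_clipping_keeps_extremes_finite(self):
        assert np.isfinite(fisher_z(1.0)) and np.isfinite(fisher_z(-1.0))
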