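"""Thick-pen and ensemble thick-pen boundary computations.

The reference implementation throughout is a direct loop over window
positions, written independently of the vectorised code under test.
"""

import math

import numpy as np
import pytest

from etpt.pen import PenConfig, etpt_boundaries, log_upper_boundaries, tpt_boundaries
from etpt.io import TimeSeriesSet


def brute_tpt(x, tau, gamma, shape="square"):
    """Loop-over-window reference for the classic transform."""
    t_len = len(x)
    lo, hi = math.ceil(-tau / 2), math.floor(tau / 2)
    upper, lower = np.empty(t_len), np.empty(t_len)
    for t in range(t_len):
        us, ls = [], []
        for k in range(lo, hi + 1):
            if 0 <= t + k < t_len and not np.isnan(x[t + k]):
                off = gamma * math.sqrt(tau**2 / 4 - k**2) if shape == "round" else 0.0
                us.append(x[t + k] + off)
                ls.append(x[t + k] - off)
        pad = (tau / 2) * gamma if shape == "square" else 0.0
        upper[t] = max(us) + pad
        lower[t] = min(ls) - pad
    return upper, lower


def brute_etpt(x, tau, gamma):
    """Loop-over-shift reference for the ensemble transform."""
    t_len = len(x)
    upper, lower = np.empty(t_len), np.empty(t_len)
    for t in range(t_len):
        maxes, mins = [], []
        for ell in range(tau + 1):
            window = [x[s] for s in range(t - ell, t + tau - ell + 1)
                      if 0 <= s < t_len and not np.isnan(x[s])]
            maxes.append(max(window))
            mins.append(min(window))
        upper[t] = np.mean(maxes) + (tau / 2) * gamma
        lower[t] = np.mean(mins) - (tau / 2) * gamma
    return upper, lower


class TestClassicBoundaries:
    @pytest.mark.parametrize("shape", ["square", "round"])
    def test_matches_brute_force_on_random_series(self, rng, shape):
        for _ in range(100):
            t_len = int(rng.integers(1, 51))
            tau = int(rng.integers(1, 13))
            gamma = float(rng.uniform(0, 0.5))
            x = rng.uniform(0, 10, t_len)
            b = tpt_boundaries(x, PenConfig(shape, tau, gamma))
            exp_u, exp_l = brute_tpt(x, tau, gamma, shape)
            np.testing.assert_allclose(b.upper[0], exp_u, atol=1e-12)
            np.testing.assert_allclose(b.lower[0], exp_l, atol=1e-12)

    def test_constant_series_square_pen(self):
        b = tpt_boundaries(np.full(8, 5.0), PenConfig("square", 4, 0.1))
        np.testing.assert_allclose(b.upper[0], 5.2)
        np.testing.assert_allclose(b.lower[0], 4.8)

    def test_spiky_series_edge_truncation(self):
        b = tpt_boundaries(np.array([0, 1, 0, 3, 0.0]), PenConfig("square", 2, 0.0))
        np.testing.assert_array_equal(b.upper[0], [1, 1, 3, 3, 3])
        np.testing.assert_array_equal(b.lower[0], [0, 0, 0, 0, 0])

    def test_monotone_series_window_ends(self):
        x = np.arange(1, 11, dtype=float)
        b = tpt_boundaries(x, PenConfig("square", 2, 0.0))
        np.testing.assert_array_equal(b.upper[0], np.minimum(x + 1, 10))
        np.testing.assert_array_equal(b.lower[0], np.maximum(x - 1, 1))

    def test_thicker_pen_widens_boundaries_interior(self, rng):
        x = rng.uniform(0, 5, 60)
        prev_u = prev_l = None
        for tau in (2, 4, 8, 16):
            b = tpt_boundaries(x, PenConfig("square", tau, 0.1))
            interior = slice(10, 50)
            if prev_u is not None:
                assert np.all(b.upper[0][interior] >= prev_u[interior] - 1e-12)
                assert np.all(b.lower[0][interior] <= prev_l[interior] + 1e-12)
            prev_u, prev_l = b.upper[0], b.lower[0]

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            tpt_boundaries(np.array([1.0, -0.5, 2.0]), PenConfig("square", 2))

    def test_missing_values_skipped_in_window(self):
        x = np.array([1.0, np.nan, 3.0, 2.0])
        b = tpt_boundaries(x, PenConfig("square", 2, 0.0))
        np.testing.assert_array_equal(b.upper[0], [1, 3, 3, 3])

    def test_unbridgeable_gap_raises(self):
        x = np.array([1.0, np.nan, np.nan, np.nan, 2.0])
        with pytest.raises(ValueError, match="no observed value"):
            tpt_boundaries(x, PenConfig("square", 1, 0.0))


class TestEnsembleBoundaries:
    def test_matches_brute_force_on_random_series(self, rng):
        for _ in range(100):
            t_len = int(rng.integers(1, 51))
            tau = int(rng.integers(1, 13))
            gamma = float(rng.uniform(0, 0.5))
            x = rng.uniform(0, 10, t_len)
            b = etpt_boundaries(x, PenConfig("square", tau, gamma))
            exp_u, exp_l = brute_etpt(x, tau, gamma)
            np.testing.assert_allclose(b.upper[0], exp_u, atol=1e-12)
            np.testing.assert_allclose(b.lower[0], exp_l, atol=1e-12)

    def test_constant_series(self):
        for tau in (1, 3, 8):
            b = etpt_boundaries(np.full(12, 7.0), PenConfig("square", tau, 0.1))
            np.testing.assert_allclose(b.upper[0], 7.0 + tau / 2 * 0.1)

    def test_shifted_window_average(self):
        b = etpt_boundaries(np.array([0, 1, 0, 3, 0.0]), PenConfig("square", 2, 0.0))
        assert b.upper[0][2] == pytest.approx(7 / 3)

    def test_gamma_floor_on_upper_boundary(self, rng):
        x = rng.uniform(0, 4, 30) * (rng.random(30) > 0.5)
        b = etpt_boundaries(x, PenConfig("square", 10, 0.1))
        assert b.upper[0].min() >= 0.5

    def test_zero_series_upper_is_exactly_the_floor(self):
        b = etpt_boundaries(np.zeros(25), PenConfig("square", 6, 0.1))
        assert b.upper[0].min() == b.upper[0].max()  # constant over t
        np.testing.assert_allclose(b.upper[0], 0.3, rtol=1e-15)

    def test_envelope_contains_padded_data(self, rng):
        x = rng.uniform(0, 10, 40)
        b = etpt_boundaries(x, PenConfig("square", 5, 0.2))
        assert np.all(b.upper[0] >= x + 0.5 - 1e-12)
        assert np.all(b.lower[0] <= x - 0.5 + 1e-12)

    def test_ensemble_is_smoother_than_classic_usually(self, rng):
        smoother = 0
        trials = 60
        for _ in range(trials):
            x = rng.uniform(0, 10, 80)
            pen = PenConfig("square", 6, 0.1)
            tv_classic = np.abs(np.diff(tpt_boundaries(x, pen).upper[0])).sum()
            tv_ensemble = np.abs(np.diff(etpt_boundaries(x, pen).upper[0])).sum()
            smoother += tv_ensemble <= tv_classic
        assert smoother >= 0.9 * trials

    def test_round_pen_rejected(self):
        with pytest.raises(ValueError, match="square"):
            etpt_boundaries(np.ones(5), PenConfig("round", 2))

    def test_batch_matches_single_rows(self, rng):
        mat = rng.uniform(0, 5, (4, 20))
        pen = PenConfig("square", 3, 0.1)
        batch = etpt_boundaries(mat, pen)
        for i in range(4):
            single = etpt_boundaries(mat[i], pen)
            np.testing.assert_allclose(batch.upper[i], single.upper[0])


def test_log_upper_boundaries_requires_positive_gamma():
    data = TimeSeriesSet(np.zeros((2, 10)))
    with pytest.raises(ValueError, match="gamma"):
        log_upper_boundaries(data, 5, gamma=0.0)
    logb = log_upper_boundaries(data, 5, gamma=0.1)
    assert np.all(np.isfinite(logb))


def test_pen_config_validation():
    with pytest.raises(ValueError):
        PenConfig("square", 0)
    with pytest.raises(ValueError):
        PenConfig("square", 3, -0.1)
    with pytest.raises(ValueError):
        PenConfig("hex", 3)
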