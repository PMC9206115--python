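import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortexwave.wave_metrics import (Movie, box_average, kymograph,
                                     normalize01, period_autocorr,
                                     relative_amplitude, summarize,
                                     temporal_width, xcorr_shift)


def make_movie(data, dt=1.0, dx=1.0):
    return Movie(np.asarray(data, float), dt, dx)


# ---------------------------------------------------------------- oracles

def _loop_prominence(y, k):
    """Topographic prominence of peak k by explicit walking."""
    n = len(y)
    left_min = y[k]
    i = k - 1
    while i >= 0 and y[i] <= y[k]:
        left_min = min(left_min, y[i])
        i -= 1
    right_min = y[k]
    i = k + 1
    while i < n and y[i] <= y[k]:
        right_min = min(right_min, y[i])
        i += 1
    return y[k] - max(left_min, right_min)


def brute_autocorr_period(trace, dt):
    """Independent O(n^2) autocorrelation + first-maximum scan."""
    x = np.asarray(trace, float) - np.mean(trace)
    n = len(x)
    acf = np.array([sum(x[i] * x[i + k] for i in range(n - k))
                    for k in range(n)])
    acf = acf / acf[0]
    for k in range(1, n - 1):
        if acf[k - 1] < acf[k] >= acf[k + 1]:
            if acf[k] >= 0.2 and _loop_prominence(acf, k) >= 0.05:
                if n * dt >= 3 * k * dt:
                    return k * dt
                return None
    return None


def brute_xcorr(a, b):
    """Full cross-correlation by explicit loops."""
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    n = len(a)
    lags = range(-(n - 1), n)
    vals = []
    for lag in lags:
        s = 0.0
        for i in range(n):
            j = i + lag
            if 0 <= j < n:
                s += a[i] * b[j]
        vals.append(s)
    return np.array(list(lags)), np.array(vals)


# ----------------------------------------------------------------- tests

class TestBoxAverage:
    def test_uniform_movie(self):
        tr = np.linspace(1, 5, 20)
        movie = make_movie(tr[:, None, None] * np.ones((1, 30, 30)))
        boxes = box_average(movie, 15)
        assert boxes.J.shape == (2, 2, 20)
        for i in range(2):
            for j in range(2):
                np.testing.assert_allclose(boxes.J[i, j], tr)

    def test_blockwise_constants(self):
        frame = np.block([[np.full((2, 2), 1.0), np.full((2, 2), 2.0)],
                          [np.full((2, 2), 3.0), np.full((2, 2), 4.0)]])
        movie = make_movie(np.repeat(frame[None], 8, axis=0))
        boxes = box_average(movie, 2)
        np.testing.assert_array_equal(boxes.J[:, :, 0],
                                      [[1.0, 2.0], [3.0, 4.0]])

    def test_matches_loop_oracle(self, rng):
        movie = make_movie(rng.random((10, 47, 61)))
        boxes = box_average(movie, 15)
        for i in range(boxes.J.shape[0]):
            for j in range(boxes.J.shape[1]):
                patch = movie.data[:, i * 15:(i + 1) * 15,
                                   j * 15:(j + 1) * 15]
                np.testing.assert_allclose(
                    boxes.J[i, j], patch.mean(axis=(1, 2)), atol=1e-12)

    def test_box_too_large(self):
        with pytest.raises(ValueError):
            box_average(make_movie(np.zeros((8, 10, 10))), 11)


class TestNormalize01:
    def test_basic(self):
        np.testing.assert_allclose(normalize01([0, 5, 10]), [0, 0.5, 1])

    def test_idempotent(self, rng):
        x = rng.random(50)
        once = normalize01(x)
        np.testing.assert_allclose(normalize01(once), once, atol=1e-15)

    @given(a=st.floats(0.1, 100), b=st.floats(-50, 50))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariant(self, a, b):
        x = np.sin(np.arange(40) * 0.3)
        np.testing.assert_allclose(normalize01(a * x + b), normalize01(x),
                                   atol=1e-9)

    def test_flat_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            normalize01(np.ones(10))


class TestPeriodAutocorr:
    def test_pure_sine(self):
        t = np.arange(200)
        assert period_autocorr(np.sin(2 * np.pi * t / 20), 1.0) == 20.0

    def test_white_noise_absent(self, rng):
        # false-positive rate under the prominence/height thresholds
        hits = sum(period_autocorr(rng.standard_normal(256), 1.0) is not None
                   for _ in range(50))
        assert hits <= 10

    def test_dominant_component(self):
        t = np.arange(400)
        tr = np.sin(2 * np.pi * t / 20) + 0.3 * np.sin(2 * np.pi * t / 7)
        assert period_autocorr(tr, 1.0) == pytest.approx(20.0, abs=1.0)

    def test_too_few_cycles(self):
        t = np.arange(40)
        assert period_autocorr(np.sin(2 * np.pi * t / 25), 1.0) is None

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            t = np.arange(128)
            T = rng.uniform(8, 30)
            tr = np.sin(2 * np.pi * t / T) + 0.1 * rng.standard_normal(128)
            got = period_autocorr(tr, 1.0)
            expected = brute_autocorr_period(tr, 1.0)
            assert got == expected

    def test_affine_invariance(self, rng):
        t = np.arange(256)
        tr = 1 + 0.5 * np.sin(2 * np.pi * t / 24)
        assert (period_autocorr(tr, 1.0)
                == period_autocorr(3.0 * tr + 7.0, 1.0))


class TestXcorrShift:
    def test_delay_recovered(self):
        t = np.arange(200)
        a = np.sin(2 * np.pi * t / 25)
        b = np.roll(a, 3)
        assert xcorr_shift(a, b, 2.0) == pytest.approx(6.0)

    def test_zero_for_identical(self):
        a = np.sin(np.arange(100) * 0.2)
        assert xcorr_shift(a, a, 1.0) == 0.0

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            xcorr_shift(np.ones(50), np.arange(50.0), 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            xcorr_shift(np.arange(10.0), np.arange(12.0), 1.0)

    def test_correlation_matches_brute_force(self, rng):
        """The library correlation core agrees with loops to 1e-9."""
        a = rng.standard_normal(64)
        b = rng.standard_normal(64)
        lags, brute = brute_xcorr(a, b)
        xa = a - a.mean()
        xb = b - b.mean()
        fast = np.correlate(xb, xa, mode="full")
        np.testing.assert_allclose(fast, brute, atol=1e-9)

    def test_affine_invariance(self):
        t = np.arange(300)
        a = np.sin(2 * np.pi * t / 30)
        b = np.roll(a, 5)
        assert (xcorr_shift(a, 4 * b + 2, 1.0)
                == xcorr_shift(a, b, 1.0))


class TestTemporalWidth:
    def test_rectangular_pulses(self):
        tr = np.zeros(300)
        for start in (40, 140, 240):
            tr[start:start + 20] = 1.0
        assert temporal_width(tr, 1.0) == pytest.approx(20.0, abs=1.0)

    def test_triangular_peaks(self):
        tr = np.zeros(300)
        tri = np.concatenate([np.linspace(0, 1, 21),
                              np.linspace(1, 0, 21)[1:]])
        for start in (40, 140, 240):
            tr[start:start + 41] = tri
        # half-height width of a triangle with base 2w=40 is w=20
        assert temporal_width(tr, 1.0) == pytest.approx(20.0, abs=1.0)

    def test_raised_sinusoid_half_period(self):
        t = np.arange(400)
        tr = 0.5 * (1 + np.sin(2 * np.pi * t / 40))
        assert temporal_width(tr, 1.0) == pytest.approx(20.0, abs=1.0)

    def test_no_peaks_absent(self):
        assert temporal_width(np.zeros(100), 1.0) is None


class TestRelativeAmplitude:
    def test_constant_zero(self):
        assert relative_amplitude(np.full(100, 3.0), None, 1.0) == 0.0

    def test_min_max_ratio(self):
        tr = np.concatenate([np.full(10, 2.0), np.full(10, 6.0)])
        assert relative_amplitude(tr, 20.0, 1.0) == pytest.approx(2.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            relative_amplitude(np.linspace(-1, 1, 50), None, 1.0)

    def test_matches_window_scan_oracle(self, rng):
        t = np.arange(256)
        tr = 2.0 + np.sin(2 * np.pi * t / 32) + 0.002 * t  # drifting baseline
        win = 32
        n_pos = len(tr) - win - 1 + 1
        expected = np.mean([(tr[i:i + win + 1].max() - tr[i:i + win + 1].min())
                            / tr[i:i + win + 1].min()
                            for i in range(n_pos)])
        got = relative_amplitude(tr, 32.0, 1.0)
        assert got == pytest.approx(expected, rel=1e-9)


class TestKymograph:
    def test_static_movie(self):
        frame = np.arange(100.0).reshape(10, 10)
        movie = make_movie(np.repeat(frame[None], 12, axis=0))
        ky = kymograph(movie, 4, axis="row")
        assert ky.shape == (12, 10)
        assert np.ptp(ky, axis=0).max() == 0.0

    def test_plane_wave_stripes(self):
        from cortexwave.synthetic_data import plane_wave_movie
        movie, truth = plane_wave_movie(period=24.0, wavelength=20.0,
                                        shape=(32, 96), dx=1.0, dt=2.0,
                                        duration=240.0, noise_sd=0.0)
        ky = kymograph(movie, 16, axis="row")
        # stripe slope: cross-correlate consecutive rows -> px shift/frame
        shifts = []
        for t in range(40, 60):
            cc = np.correlate(ky[t + 1] - ky[t + 1].mean(),
                              ky[t] - ky[t].mean(), mode="full")
            shifts.append(np.argmax(cc) - (ky.shape[1] - 1))
        speed = np.mean(shifts) * movie.dx / movie.dt
        assert speed == pytest.approx(truth.speed_um_s, rel=0.25)

    def test_orthogonal_line_temporal_period(self):
        from cortexwave.synthetic_data import plane_wave_movie
        movie, truth = plane_wave_movie(period=24.0, wavelength=20.0,
                                        shape=(32, 96), dx=1.0, dt=2.0,
                                        duration=240.0, noise_sd=0.0)
        ky = kymograph(movie, 10, axis="col")  # line orthogonal to k
        assert period_autocorr(ky[:, 5], movie.dt) == pytest.approx(24.0,
                                                                    abs=2.0)

    def test_out_of_bounds(self):
        movie = make_movie(np.zeros((8, 10, 10)))
        with pytest.raises(IndexError):
            kymograph(movie, 10, axis="row")

    def test_polyline(self):
        movie = make_movie(np.random.default_rng(0).random((8, 10, 12)))
        pts = [(0, 0), (1, 1), (2, 2)]
        ky = kymograph(movie, pts)
        assert ky.shape == (8, 3)
        np.testing.assert_array_equal(ky[:, 1], movie.data[:, 1, 1])


class TestSummarize:
    def test_uniform_oscillation(self):
        t = np.arange(120)
        tr = 2.0 + np.sin(2 * np.pi * t / 12)
        movie = make_movie(tr[:, None, None] * np.ones((1, 30, 30)), dt=2.0)
        rec = summarize(movie, box_px=15)
        assert rec.period_s == pytest.approx(24.0, abs=2.0)
        assert (rec.per_box["period_s"] == rec.per_box["period_s"][0]).all()

    def test_plane_wave_truth_recovery(self):
        from cortexwave.synthetic_data import plane_wave_movie
        movie, truth = plane_wave_movie(period=24.0, wavelength=20.0,
                                        baseline=2.0, amplitude=4.0,
                                        shape=(60, 60), dx=1.0, dt=2.0,
                                        duration=480.0, noise_sd=0.0)
        rec = summarize(movie, box_px=2)  # box << wavelength: negligible
        assert rec.period_s == pytest.approx(24.0, abs=movie.dt)
        assert rec.width_s == pytest.approx(truth.fwhm_s, abs=movie.dt)
        assert rec.rel_amplitude == pytest.approx(truth.rel_amplitude,
                                                  rel=0.05)

    def test_two_channel_shift(self):
        # period 60 s keeps an 18-s lag unambiguous (< period/2)
        from cortexwave.synthetic_data import follower_movie, plane_wave_movie
        movie, _ = plane_wave_movie(period=60.0, wavelength=20.0,
                                    shape=(30, 30), dx=1.0, dt=2.0,
                                    duration=600.0)
        follower, truth = follower_movie(movie, lag=18.0)
        rec = summarize(movie, follower, box_px=15)
        assert rec.shift_s == pytest.approx(18.0, abs=movie.dt)

    def test_shape_mismatch(self):
        a = make_movie(np.zeros((8, 10, 10)) + np.arange(8)[:, None, None])
        b = make_movie(np.zeros((8, 12, 10)) + np.arange(8)[:, None, None])
        with pytest.raises(ValueError, match="shape"):
            summarize(a, b)
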