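import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hrvcomplexity import preprocess as pp
from hrvcomplexity.sigio import EventSeries, UniformSignal
from hrvcomplexity.synth import gen_pacer


def sig(values, fs=1.0):
    return UniformSignal(values=np.asarray(values, dtype=float), fs=fs)


class TestDetrend:
    def test_linear_removes_line(self):
        t = np.arange(10.0)
        out = pp.detrend(sig(2 * t + 1), "linear")
        assert np.abs(out.values).max() < 1e-9

    def test_constant_removes_mean(self):
        out = pp.detrend(sig([5.0, 5.0, 5.0]), "constant")
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        x = sig(rng.standard_normal(50))
        once = pp.detrend(x, "linear")
        twice = pp.detrend(once, "linear")
        np.testing.assert_allclose(once.values, twice.values, atol=1e-10)


class TestDeduplicate:
    @pytest.mark.parametrize("inp,expected", [
        ([5, 5, 5, 7, 7, 3], [5, 7, 3]),
        ([1, 2, 1, 2], [1, 2, 1, 2]),
        ([4, 4, 4, 4], [4]),
    ])
    def test_runs_collapse(self, inp, expected):
        np.testing.assert_array_equal(pp.deduplicate(inp), expected)


class TestResampleUniform:
    def test_constant_rri(self):
        s = EventSeries.from_intervals([1000.0] * 10, kind="RRi")
        out = pp.resample_uniform(s, fs=4.0)
        np.testing.assert_allclose(out.values, 1000.0, atol=1e-9)
        assert out.fs == 4.0

    def test_monotone_input_monotone_output(self):
        s = EventSeries.from_intervals(np.linspace(800, 1100, 20), kind="RRi")
        out = pp.resample_uniform(s, fs=4.0)
        assert np.all(np.diff(out.values) >= -1e-12)

    def test_no_overshoot(self, rng):
        for _ in range(20):
            iv = 900 + 100 * rng.uniform(-1, 1, 30)
            s = EventSeries.from_intervals(iv, kind="RRi")
            out = pp.resample_uniform(s, fs=4.0)
            assert out.values.max() <= iv.max() + 1e-9
            assert out.values.min() >= iv.min() - 1e-9

    def test_sinusoidal_modulation_peak_recovered(self):
        # slow sinusoidal RRi: tachogram spectrum peaks at the
        # modulation frequency
        f_mod = 0.1
        t = 0.0
        intervals = []
        while t < 300.0:
            rr = 1000.0 + 50.0 * np.sin(2 * np.pi * f_mod * t)
            t += rr / 1000.0
            intervals.append(rr)
        s = EventSeries.from_intervals(intervals, kind="RRi")
        out = pp.resample_uniform(s, fs=4.0)
        v = out.values - out.values.mean()
        freqs = np.fft.rfftfreq(v.size, 1 / 4.0)
        spec = np.abs(np.fft.rfft(v * np.hanning(v.size)))
        peak = freqs[np.argmax(spec)]
        assert peak == pytest.approx(f_mod, abs=freqs[1] - freqs[0])


class TestSegment:
    def test_nested_prefix_lengths(self):
        x = sig(np.arange(315 * 4), fs=4.0)
        segs = pp.segment(x, pp.SegmentationPlan("nested", [1, 2, 3, 4, 5]))
        assert [len(s) for s in segs] == [240, 480, 720, 960, 1200]
        assert all(s.t0 == x.t0 for s in segs)

    def test_equal_fifths_balanced_and_conserving(self):
        x = sig(np.arange(1000.0), fs=4.0)
        segs = pp.segment(x, pp.SegmentationPlan("equal_fifths"))
        assert [len(s) for s in segs] == [200] * 5
        np.testing.assert_array_equal(
            np.concatenate([s.values for s in segs]), x.values)

    def test_event_series_half_open(self):
        s = EventSeries.from_intervals([30.0] * 10, kind="PP")  # 300 s total
        segs = pp.segment(s, pp.SegmentationPlan("nested", [1]))
        # events at 30..300 s; 1-min prefix keeps events with time < 60
        np.testing.assert_allclose(segs[0].times, [30.0])

    def test_too_short_raises(self):
        x = sig(np.arange(100.0), fs=1.0)
        with pytest.raises(ValueError, match="shorter"):
            pp.segment(x, pp.SegmentationPlan("nested", [5]))


class TestFinegrid:
    @pytest.mark.parametrize("x,method,n,expected", [
        ([0, 2], "linear", 1, [0, 1, 2]),
        ([0, 2], "nearest", 1, [0, 0, 2]),
        ([0, 3], "linear", 2, [0, 1, 2, 3]),
    ])
    def test_examples(self, x, method, n, expected):
        np.testing.assert_allclose(
            pp.finegrid_interpolate(x, method, n), expected)

    def test_length_formula(self, rng):
        x = rng.standard_normal(17)
        for n in (1, 2, 3):
            out = pp.finegrid_interpolate(x, "linear", n)
            assert out.size == 17 + 16 * n

    def test_linear_then_decimate_recovers(self, rng):
        x = rng.standard_normal(25)
        out = pp.finegrid_interpolate(x, "linear", 1)
        np.testing.assert_array_equal(out[::2], x)

    def test_invalid_n_points(self):
        with pytest.raises(ValueError):
            pp.finegrid_interpolate([0, 1], "linear", 4)


class TestAddNoise:
    def test_infinite_snr_is_identity(self, rng):
        x = sig(rng.standard_normal(256))
        out = pp.add_noise(x, "white", np.inf, seed=0)
        np.testing.assert_array_equal(out.values, x.values)

    def test_snr_respected(self, rng):
        x = sig(rng.standard_normal(2 ** 12))
        out = pp.add_noise(x, "white", 10.0, seed=1)
        noise = out.values - x.values
        snr = 10 * np.log10(np.var(x.values) / np.var(noise))
        assert snr == pytest.approx(10.0, abs=0.01)

    @pytest.mark.parametrize("colour,slope", [("white", 0.0), ("pink", -1.0),
                                              ("brown", -2.0), ("blue", 1.0)])
    def test_psd_slope(self, colour, slope):
        n = 2 ** 16
        rng = np.random.default_rng(7)
        noise = pp.coloured_noise(n, colour, rng)
        freqs = np.fft.rfftfreq(n)
        psd = np.abs(np.fft.rfft(noise)) ** 2
        # mid-band log-log regression
        mask = (freqs > 1e-3) & (freqs < 0.25)
        logf = np.log(freqs[mask])
        logp = np.log(psd[mask])
        bins = np.linspace(logf.min(), logf.max(), 20)
        idx = np.digitize(logf, bins)
        bf = np.array([logf[idx == i].mean() for i in range(1, 20)
                       if np.any(idx == i)])
        bp = np.array([logp[idx == i].mean() for i in range(1, 20)
                       if np.any(idx == i)])
        fit = np.polyfit(bf, bp, 1)[0]
        assert fit == pytest.approx(slope, abs=0.1)

    def test_reproducible(self, rng):
        x = sig(rng.standard_normal(128))
        a = pp.add_noise(x, "pink", 5.0, seed=42)
        b = pp.add_noise(x, "pink", 5.0, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_zero_variance_rejected(self):
        x = sig(np.ones(64))
        with pytest.raises(ValueError):
            pp.add_noise(x, "white", 10.0, seed=0)


class TestTransformAmplitude:
    def test_minmax(self):
        np.testing.assert_allclose(
            pp.transform_amplitude([2, 4, 6], "minmax"), [0, 0.5, 1])

    def test_binarize_b(self):
        np.testing.assert_array_equal(
            pp.transform_amplitude([1, 3, 2], "binarize_b"), [1, -1])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40)
           .filter(lambda v: max(v) - min(v) > 1e-6))
    @settings(deadline=None, max_examples=50)
    def test_zscore_moments(self, values):
        z = pp.transform_amplitude(values, "zscore")
        assert abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_input_rejected(self):
        for method in ("zscore", "minmax", "robust"):
            with pytest.raises(ValueError):
                pp.transform_amplitude([3.0, 3.0, 3.0], method)


class TestReverseArrangement:
    def test_monotone_extremes(self):
        _, a_inc, _ = pp.reverse_arrangement_test(np.arange(10.0))
        _, a_dec, _ = pp.reverse_arrangement_test(np.arange(10.0)[::-1])
        assert a_inc == 0
        assert a_dec == 45  # N(N-1)/2

    def test_null_mean_matches_closed_form(self, rng):
        # E[A] = N(N-1)/4 = 22.5 at N = 10
        a_vals = [pp.reverse_arrangement_test(rng.standard_normal(10))[1]
                  for _ in range(2000)]
        assert np.mean(a_vals) == pytest.approx(22.5, abs=0.5)

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.standard_normal(30)
        _, a1, _ = pp.reverse_arrangement_test(x)
        _, a2, _ = pp.reverse_arrangement_test(np.exp(x))
        assert a1 == a2

    def test_stationary_verdict_for_white_noise(self, rng):
        verdicts = [pp.reverse_arrangement_test(rng.standard_normal(50))[0]
                    for _ in range(40)]
        assert verdicts.count("nonstationary") <= 8  # ~5% expected


class TestBreathExtraction:
    def test_pacer_6bpm_40_60(self):
        rsp = gen_pacer(6.0, in_fraction=0.4, duration_s=90.0)
        b = pp.extract_breath_intervals(rsp)
        tol = 1.5 / rsp.fs
        assert np.allclose(b.inbreath.intervals, 4.0, atol=tol)
        assert np.allclose(b.outbreath.intervals, 6.0, atol=tol)
        assert np.allclose(b.peak_to_peak.intervals, 10.0, atol=tol)
        assert np.allclose(b.ratio, 1.5, atol=0.1)

    def test_symmetric_sinusoid_ratio_one(self):
        t = np.arange(0, 90, 1 / 32.0)
        rsp = UniformSignal(np.sin(2 * np.pi * 0.1 * t), fs=32.0)
        b = pp.extract_breath_intervals(rsp)
        assert np.allclose(b.ratio, 1.0, atol=0.05)

    def test_amplitude_invariance(self):
        rsp = gen_pacer(5.0, duration_s=90.0)
        big = UniformSignal(rsp.values * 7.3, fs=rsp.fs)
        b1 = pp.extract_breath_intervals(rsp)
        b2 = pp.extract_breath_intervals(big)
        np.testing.assert_allclose(b1.inbreath.intervals,
                                   b2.inbreath.intervals)

    def test_no_cycles_raises(self):
        flat = UniformSignal(np.zeros(320) + 1e-9 * np.arange(320), fs=32.0)
        with pytest.raises(ValueError):
            pp.extract_breath_intervals(flat)
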