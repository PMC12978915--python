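import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from emgmap import (
    METRICS,
    Psd,
    PsdParams,
    PreprocessParams,
    SegmentLabel,
    freq_domain_features,
    time_domain_features,
    welch_psd,
)
from emgmap.features import extract_features

FS = 1280.0  # 128-sample windows -> exact 10 Hz bins


def naive_time_domain(x, fs, window_s=0.25, overlap=0.5, eps=0.0, delta=0.0):
    """Plain-loop oracle for the five time-domain metrics."""
    x = list(map(float, x))
    n = len(x)
    duration = n / fs
    w = int(round(window_s * fs))
    hop = max(1, int(round(w * (1 - overlap))))
    rms = []
    i = 0
    while i + w <= n:
        rms.append((sum(v * v for v in x[i : i + w]) / w) ** 0.5)
        i += hop
    mean_rms = sum(rms) / len(rms)
    var = sum((r - mean_rms) ** 2 for r in rms) / (len(rms) - 1)
    zc = ssc = 0
    wfl = 0.0
    for i in range(n - 1):
        wfl += abs(x[i + 1] - x[i])
        if x[i] * x[i + 1] < 0 and abs(x[i] - x[i + 1]) >= eps:
            zc += 1
    for i in range(1, n - 1):
        dl, dr = x[i] - x[i - 1], x[i] - x[i + 1]
        if dl * dr > 0 and max(abs(dl), abs(dr)) >= delta:
            ssc += 1
    return {
        "meanRMS": mean_rms,
        "stdRMS": var**0.5,
        "SSC": ssc / duration,
        "ZC": zc / duration,
        "WFL": wfl,
    }


class TestWelch:
    def test_zero_signal(self):
        psd = welch_psd(np.zeros(2000), FS)
        assert np.all(psd.power == 0)

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(60 * FS))
        psd = welch_psd(x, FS)
        df = psd.freqs_hz[1] - psd.freqs_hz[0]
        assert np.sum(psd.power) * df == pytest.approx(np.var(x), rel=0.10)

    def test_sinusoid_concentration_vs_dft_oracle(self):
        from scipy.signal import get_window

        f0 = 200.0
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * f0 * t)
        psd = welch_psd(x, FS)
        k0 = int(round(f0 / (FS / 128)))
        frac = np.sum(psd.power[k0 - 1 : k0 + 2]) / np.sum(psd.power)
        assert frac >= 0.9
        # independent one-taper DFT oracle on a single segment
        w = get_window("blackman", 128)
        spec = np.abs(np.fft.rfft(w * x[:128])) ** 2
        frac_oracle = np.sum(spec[k0 - 1 : k0 + 2]) / np.sum(spec)
        assert frac == pytest.approx(frac_oracle, abs=0.02)

    def test_grid_spacing(self):
        psd = welch_psd(np.ones(1000), FS)
        np.testing.assert_allclose(np.diff(psd.freqs_hz), FS / 128)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter than nperseg"):
            welch_psd(np.zeros(100), FS)

    def test_matches_scipy_welch(self):
        """Dual-route check against the scipy implementation."""
        from scipy.signal import welch as scipy_welch

        rng = np.random.default_rng(5)
        x = rng.standard_normal(5000)
        psd = welch_psd(x, FS)
        f2, p2 = scipy_welch(
            x,
            fs=FS,
            window="blackman",
            nperseg=128,
            noverlap=64,
            detrend=False,
            scaling="density",
        )
        np.testing.assert_allclose(psd.freqs_hz, f2)
        np.testing.assert_allclose(psd.power, p2, rtol=1e-10, atol=1e-15)


class TestTimeDomain:
    def test_alternating_closed_form(self):
        n = 512
        x = np.tile([1.0, -1.0], n // 2)
        duration = n / FS
        out = time_domain_features(x, FS)
        assert out["ZC"] == pytest.approx((n - 1) / duration)
        assert out["SSC"] == pytest.approx((n - 2) / duration)
        assert out["WFL"] == pytest.approx(2 * (n - 1))
        assert out["meanRMS"] == pytest.approx(1.0)
        assert out["stdRMS"] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_ramp(self):
        x = np.linspace(0.0, 1.0, 2000)
        out = time_domain_features(x, FS)
        assert out["ZC"] == 0
        assert out["SSC"] == 0
        assert out["WFL"] == pytest.approx(1.0)

    def test_random_matches_loop_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(1000)
        out = time_domain_features(x, FS)
        oracle = naive_time_domain(x, FS)
        for k, v in oracle.items():
            assert out[k] == pytest.approx(v, rel=1e-12), k

    def test_thresholds_suppress_counts(self):
        x = np.tile([1e-6, -1e-6], 400)
        out = time_domain_features(x, FS, eps=1.0, delta=1.0)
        assert out["ZC"] == 0 and out["SSC"] == 0

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            time_domain_features(np.zeros(2), FS)

    @settings(max_examples=25, deadline=None)
    @given(
        hnp.arrays(
            np.float64,
            st.integers(min_value=800, max_value=1200),
            elements=st.integers(min_value=-5, max_value=5).map(float),
        )
    )
    def test_integer_signals_bitexact_vs_oracle(self, x):
        """WFL/ZC/SSC equal the loop oracle bit-for-bit on integer signals."""
        out = time_domain_features(x, FS)
        oracle = naive_time_domain(x, FS)
        assert out["WFL"] == oracle["WFL"]
        assert out["ZC"] == oracle["ZC"]
        assert out["SSC"] == oracle["SSC"]


def _psd(freqs, power):
    return Psd(np.asarray(freqs, float), np.asarray(power, float), PsdParams())


class TestFreqDomain:
    def test_single_line_spectrum(self):
        out = freq_domain_features(_psd([100.0, 200.0, 300.0], [5.0, 0.0, 0.0]))
        assert out["meanFreq"] == pytest.approx(100.0)
        assert out["medianFreq"] == pytest.approx(100.0)
        assert out["entropy"] == pytest.approx(0.0)
        assert out["SpecDef"] == pytest.approx(1.0)
        assert out["DP"] == pytest.approx(0.0)

    def test_flat_spectrum_max_entropy(self):
        f = np.linspace(30, 480, 46)
        out = freq_domain_features(_psd(f, np.ones_like(f)))
        assert out["entropy"] == pytest.approx(1.0)

    def test_two_bin_moment_oracle(self):
        # equal power at f and 2f: M0=2P, M1=3fP, M2=5f^2 P
        # => Omega1 = 1.5 f, Omega2 = sqrt(2.5) f, SpecDef = sqrt(2.5)/1.5
        out = freq_domain_features(_psd([100.0, 200.0], [3.0, 3.0]))
        assert out["SpecDef"] == pytest.approx(np.sqrt(2.5) / 1.5, rel=1e-12)
        assert out["meanFreq"] == pytest.approx(150.0)

    def test_median_interpolation(self):
        # cum power [0.25, 1.0]: crossing 0.5 interpolates to 133.33 Hz
        out = freq_domain_features(_psd([100.0, 200.0], [1.0, 3.0]))
        assert out["medianFreq"] == pytest.approx(100 + 100 * 0.25 / 0.75)
        # equal bins: cumulative reaches exactly 0.5 at the first bin
        out = freq_domain_features(_psd([100.0, 200.0], [1.0, 1.0]))
        assert out["medianFreq"] == pytest.approx(100.0)

    def test_dp_split(self):
        out = freq_domain_features(_psd([100.0, 200.0], [1.0, 3.0]))
        assert out["DP"] == pytest.approx(0.75)

    def test_out_of_band_excluded(self):
        out = freq_domain_features(
            _psd([5.0, 100.0, 200.0, 600.0], [99.0, 1.0, 1.0, 99.0])
        )
        assert out["meanFreq"] == pytest.approx(150.0)

    def test_silent_segment(self):
        with pytest.raises(ValueError, match="silent segment"):
            freq_domain_features(_psd([100.0, 200.0], [0.0, 0.0]))


class TestFreqProperties:
    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(4000)
        base = freq_domain_features(welch_psd(x, FS))
        for c in (1e-3, 7.3, 1e4):
            scaled = freq_domain_features(welch_psd(c * x, FS))
            for k in base:
                assert scaled[k] == pytest.approx(base[k], rel=1e-12), k

    def test_specdef_at_least_one(self):
        rng = np.random.default_rng(2)
        f = np.linspace(20, 500, 49)
        for _ in range(1000):
            p = rng.random(f.size)
            out = freq_domain_features(_psd(f, p))
            assert out["SpecDef"] >= 1.0 - 1e-12

    def test_bounds_and_entropy_range(self):
        rng = np.random.default_rng(3)
        f = np.linspace(20, 500, 49)
        for _ in range(200):
            out = freq_domain_features(_psd(f, rng.random(f.size)))
            assert f[0] <= out["meanFreq"] <= f[-1]
            assert f[0] <= out["medianFreq"] <= f[-1]
            assert 0.0 <= out["entropy"] <= 1.0
            assert 0.0 <= out["DP"] <= 1.0

    def test_downward_shift_decreases_location_metrics(self):
        rng = np.random.default_rng(4)
        f = np.linspace(20, 500, 49)
        p = rng.random(f.size) + 0.1
        base = freq_domain_features(_psd(f, p))
        shifted = freq_domain_features(_psd(f, np.append(p[1:], 0.0)))
        assert shifted["meanFreq"] < base["meanFreq"]
        assert shifted["medianFreq"] < base["medianFreq"]
        assert shifted["DP"] < base["DP"]


class TestExtract:
    def test_row_count_154(self, normalized_session):
        session, _ = normalized_session
        table = extract_features(session)
        assert len(table) == 14 * 11
        assert set(METRICS) <= set(table.columns)
        assert not table[list(METRICS)].isna().any().any()

    def test_control_stdrms_exactly_one(self, normalized_session):
        session, _ = normalized_session
        table = extract_features(session)
        for seg in ("C2", "C3"):
            vals = table[table["segment"] == seg]["stdRMS"]
            np.testing.assert_allclose(vals, 1.0, rtol=1e-12)

    def test_gain_monotonicity(self):
        from emgmap import Muscle, default_activation_map, scaled_down_config, simulate_session
        from emgmap.session_io import ALL_CHANNELS
        from emgmap import preprocess_session

        channels = tuple(c for c in ALL_CHANNELS if c.muscle is Muscle.DELTOID)
        cfg = scaled_down_config(n_participants=3, seed=0, channels=channels)
        tables = {}
        for g in (2.0, 4.0):
            amap = default_activation_map(gain={Muscle.DELTOID: g})
            session = simulate_session("p01", cfg, amap, 99)
            norm, _ = preprocess_session(session)
            tables[g] = extract_features(norm)
        for seg in ("F_LCC", "F_LMLO"):
            lo = tables[2.0]
            hi = tables[4.0]
            sel = lambda t: t[
                (t["segment"] == seg) & (t["channel"] == "deltoid_left")
            ]["meanRMS"].iloc[0]
            assert sel(hi) > sel(lo)

    def test_deterministic(self, normalized_session):
        session, _ = normalized_session
        a = extract_features(session)
        b = extract_features(session)
        assert a.equals(b)

    def test_subwindow_mode(self, normalized_session):
        session, _ = normalized_session
        table = extract_features(session, subwindow_s=2.0)
        assert len(table) == 14 * 11
        assert np.isfinite(table[list(METRICS)].to_numpy()).all()
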