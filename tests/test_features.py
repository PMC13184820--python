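import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycopore import features as ft
from glycopore import synthetic_data as sd
from glycopore.event_detection import EventRecord
from glycopore.trace_io import ValidationError

FS = 50_000.0


def make_event(segment, I0=100.0, fs=FS):
    segment = np.asarray(segment, dtype=float)
    return EventRecord(
        start=0, end=segment.size, segment=segment, I0=I0,
        dwell_time=segment.size / fs * 1000.0,
    )


def brute_force_apen(x, m=2, r_factor=0.2):
    """Independent O(n²) approximate entropy (direct definition)."""
    x = np.asarray(x, float)
    n = x.size
    r = r_factor * np.std(x)

    def phi(k):
        nt = n - k + 1
        total = 0.0
        for i in range(nt):
            count = 0
            for j in range(nt):
                if max(abs(x[i + d] - x[j + d]) for d in range(k)) <= r:
                    count += 1
            total += np.log(count / nt)
        return total / nt

    return phi(m) - phi(m + 1)


class TestDeltaRatio:
    def test_constant_blockade(self):
        ev = make_event(np.full(50, 3.0))
        assert ft.delta_ratio(ev) == pytest.approx(0.97)

    def test_segment_at_baseline_gives_zero(self):
        assert ft.delta_ratio(make_event(np.full(50, 100.0))) == 0.0

    def test_nonpositive_baseline_rejected(self):
        ev = make_event(np.full(50, 3.0), I0=0.0)
        with pytest.raises(ValidationError):
            ft.delta_ratio(ev)

    def test_median_is_robust_to_spikes(self):
        seg = np.full(100, 3.0)
        seg[10:14] = 60.0
        assert ft.delta_ratio(make_event(seg)) == pytest.approx(0.97)


class TestTimeDomain:
    def test_basic_statistics(self):
        out = ft.time_domain_features(make_event([1.0, 2.0, 3.0]))
        assert out["mean"] == 2.0
        assert out["median"] == 2.0
        assert out["std"] == pytest.approx(1.0)

    def test_constant_segment_has_missing_shape_stats(self):
        out = ft.time_domain_features(make_event(np.full(20, 5.0)))
        assert out["std"] == 0.0
        assert np.isnan(out["skew"]) and np.isnan(out["kurt"])

    def test_gaussian_sample_has_zero_skew_and_excess_kurtosis(self, rng):
        out = ft.time_domain_features(make_event(rng.normal(10, 2, 200_000)))
        assert out["skew"] == pytest.approx(0.0, abs=0.02)
        assert out["kurt"] == pytest.approx(0.0, abs=0.05)


class TestMorphology:
    def test_square_event(self):
        out = ft.morphological_features(make_event(np.full(50, 50.0)))
        assert out["blockade_charge"] == pytest.approx(50.0)  # 50 pA × 1 ms
        assert out["fwhm"] == pytest.approx(1.0)
        assert out["rise_time"] == 0.0

    def test_symmetric_triangle_rise_fall_are_40pct_of_duration(self):
        # depth ramps 0→50 pA over the first half, back down over the second:
        # 10–90% of each ramp spans 0.8·(T/2) = 0.4·T
        up = np.arange(2.0, 52.0, 2.0)
        d = np.concatenate([up, up[::-1]])
        out = ft.morphological_features(make_event(100.0 - d))
        T = d.size / FS * 1000.0
        assert out["rise_time"] == pytest.approx(0.4 * T)
        assert out["fall_time"] == pytest.approx(0.4 * T)

    def test_noisy_square_fwhm_matches_dwell(self, presets, rng):
        spec = presets["GT1b"]
        fwhms, dwells = [], []
        for k in range(200):
            n = int(rng.integers(10, 30))
            seg = sd.simulate_event_segment(spec, 100.0, n, FS, seed=k)
            out = ft.morphological_features(make_event(seg))
            fwhms.append(out["fwhm"])
            dwells.append(n / FS * 1000.0)
        ratio = np.median(np.array(fwhms) / np.array(dwells))
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_never_blocking_event_yields_missing(self):
        out = ft.morphological_features(make_event(np.full(20, 101.0)))
        assert np.isnan(out["rise_time"]) and np.isnan(out["fwhm"])


class TestWelchPSD:
    def test_sinusoid_peak_at_tone_frequency(self):
        t = np.arange(4096) / FS
        x = np.sin(2 * np.pi * 1000.0 * t)
        f, p = ft.welch_psd(x, FS)
        assert abs(f[np.argmax(p)] - 1000.0) < FS / 256

    def test_parseval_consistency(self, rng):
        x = rng.normal(0, 2.0, 8192)
        f, p = ft.welch_psd(x, FS)
        power = np.sum(p) * (f[1] - f[0])
        assert power == pytest.approx(np.var(x), rel=0.05)

    def test_white_noise_spectrum_is_flat(self, rng):
        x = rng.normal(0, 1.0, 65_536)
        f, p = ft.welch_psd(x, FS)
        thirds = np.array_split(p[f > 0], 3)
        means = [np.mean(b) for b in thirds]
        assert max(means) / min(means) < 1.3

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValidationError):
            ft.welch_psd(np.ones(5), FS)


class TestSpectralFeatures:
    def test_single_bin_spectrum(self):
        f = np.array([0.0, 100.0, 200.0])
        p = np.array([0.0, 1.0, 0.0])
        out = ft.spectral_features(f, p)
        assert out["spectral_entropy"] == 0.0
        assert out["spectral_centroid"] == 100.0

    def test_uniform_spectrum_has_unit_entropy(self):
        f = np.linspace(0, 5000, 65)
        p = np.ones_like(f)
        out = ft.spectral_features(f, p)
        assert out["spectral_entropy"] == pytest.approx(1.0)

    def test_band_powers_sum_to_at_most_one(self, rng):
        x = rng.normal(0, 1, 2048)
        f, p = ft.welch_psd(x, FS)
        out = ft.spectral_features(f, p)
        assert out["bp_low"] + out["bp_mid"] + out["bp_high"] <= 1 + 1e-9

    def test_band_powers_sum_to_one_when_edges_span_nyquist(self, rng):
        # at 10 kHz sampling the default top edge (5 kHz) IS the Nyquist
        x = rng.normal(0, 1, 2048)
        f, p = ft.welch_psd(x, 10_000.0)
        out = ft.spectral_features(f, p)
        total = out["bp_low"] + out["bp_mid"] + out["bp_high"]
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_ar1_vs_white_noise_ordering(self, rng):
        """Analytic AR(1) PSD ∝ 1/(1+ρ²−2ρcos ω): more bp_low, lower centroid."""
        from scipy.signal import lfilter

        white = rng.normal(0, 1, 32_768)
        ar1 = lfilter([1.0], [1.0, -0.9], rng.normal(0, 1, 32_768))
        outs = []
        for x in (ar1, white):
            f, p = ft.welch_psd(x, FS)
            outs.append(ft.spectral_features(f, p))
        assert outs[0]["bp_low"] > outs[1]["bp_low"]
        assert outs[0]["spectral_centroid"] < outs[1]["spectral_centroid"]

    def test_zero_power_yields_missing(self):
        out = ft.spectral_features(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        assert np.isnan(out["spectral_centroid"])


class TestApproximateEntropy:
    def test_constant_signal_is_zero(self):
        assert ft.approximate_entropy(np.full(100, 5.0)) == 0.0

    def test_short_segment_is_missing(self):
        assert np.isnan(ft.approximate_entropy(np.arange(30.0)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 200)
        assert ft.approximate_entropy(x, min_samples=50) == pytest.approx(
            brute_force_apen(x), abs=1e-12
        )

    def test_noise_more_complex_than_sine(self, rng):
        t = np.arange(400)
        sine = np.sqrt(2) * np.sin(2 * np.pi * t / 40)
        noise = rng.normal(0, 1, 400)
        assert ft.approximate_entropy(noise) > ft.approximate_entropy(sine)


class TestSpikeDetection:
    def test_clean_gaussian_segment_has_no_spikes(self, rng):
        count, rate, _ = ft.detect_spikes_mad(rng.normal(5, 1, 500), dwell_ms=10.0)
        assert count == 0

    def test_planted_spikes_counted(self, rng):
        seg = rng.normal(5, 0.5, 600)
        for s in (100, 300, 500):
            seg[s : s + 4] += 40.0
        count, rate, mask = ft.detect_spikes_mad(seg, dwell_ms=12.0)
        assert count == 3
        assert rate == pytest.approx(0.25)
        assert mask.sum() >= 9

    def test_constant_segment_no_spikes(self):
        count, _, _ = ft.detect_spikes_mad(np.full(100, 5.0), dwell_ms=2.0)
        assert count == 0


class TestExtraction:
    def test_square_event_has_all_features(self):
        seg = np.full(200, 3.0) + np.random.default_rng(0).normal(0, 0.5, 200)
        out = ft.extract_features(make_event(seg), FS)
        assert set(out) == set(ft.FEATURE_NAMES)
        present = {k: v for k, v in out.items() if not np.isnan(v)}
        assert set(present) == set(ft.FEATURE_NAMES)
        assert out["delta_ratio"] == pytest.approx(0.97, abs=0.01)

    def test_five_sample_event_misses_spectral_and_apen(self):
        out = ft.extract_features(make_event([3.0, 3.5, 2.5, 3.1, 2.9]), FS)
        assert np.isnan(out["approx_entropy"])
        assert np.isnan(out["spectral_centroid"])
        assert not np.isnan(out["mean"]) and not np.isnan(out["std"])

    def test_excluded_event_rejected(self):
        ev = make_event(np.full(10, 3.0))
        ev.excluded = True
        with pytest.raises(ValidationError):
            ft.extract_features(ev, FS)

    def test_deterministic_and_order_independent(self, presets):
        events = sd.simulate_labeled_events([presets["GT1b"]], 30, seed=3)
        t1 = ft.extract_feature_table(events)
        t2 = ft.extract_feature_table(list(reversed(events)))
        merged = t2.iloc[::-1].reset_index(drop=True)
        pd.testing.assert_frame_equal(t1, merged)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_current_scale_invariance(self, scale):
        """Scaling current (and I0) leaves dimensionless features unchanged."""
        rng = np.random.default_rng(99)
        seg = 3.0 + rng.normal(0, 0.5, 120)
        a = ft.extract_features(make_event(seg), FS)
        b = ft.extract_features(make_event(seg * scale, I0=100.0 * scale), FS)
        for name in ("delta_ratio", "skew", "kurt", "spectral_entropy", "approx_entropy"):
            assert b[name] == pytest.approx(a[name], rel=1e-9, abs=1e-9)


class TestMissingRate:
    def test_fraction_per_feature(self):
        df = pd.DataFrame({n: np.ones(10) for n in ft.FEATURE_NAMES})
        df.loc[:2, "approx_entropy"] = np.nan
        assert ft.missing_rate(df)["approx_entropy"] == pytest.approx(0.30)
        assert ft.missing_rate(df)["mean"] == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            ft.missing_rate(pd.DataFrame(columns=ft.FEATURE_NAMES))

    def test_long_dwell_population_recovers_apen(self, presets):
        """Long-residence events make ApEn nearly always computable."""
        long_spec = presets["GT1c"]          # τ_slow 3.19 ms
        short_spec = presets["GT1c_M113R"]   # τ 0.40 ms
        long_t = ft.extract_feature_table(
            sd.simulate_labeled_events([long_spec], 300, seed=5)
        )
        short_t = ft.extract_feature_table(
            sd.simulate_labeled_events([short_spec], 300, seed=6)
        )
        long_rate = ft.missing_rate(long_t)["approx_entropy"]
        short_rate = ft.missing_rate(short_t)["approx_entropy"]
        assert long_rate < short_rate - 0.2
        # restricted to the slow component, the missing rate is near zero
        slow = long_t[long_t["dwell_time"] > 1.5]
        assert ft.missing_rate(slow)["approx_entropy"] < 0.05
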