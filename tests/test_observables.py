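import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctcsim.observables import (
    BANDS,
    FrequencyBand,
    band_power,
    bandpass_phase,
    eeg_proxy,
    plv,
    plv_between,
    relative_power,
    welch_psd,
)

FS = 500.0


def sinusoid(freq, length=60.0, fs=FS, phase=0.0):
    t = np.arange(int(length * fs)) / fs
    return np.sin(2 * np.pi * freq * t + phase), t


class TestEEGProxy:
    def _result(self, topology):
        from ctcsim.engine import IntegrationSettings, integrate

        return integrate(topology, None,
                         IntegrationSettings(duration=0.5, burn_in=5.0, seed=0))

    def test_default_weights_sum_cortical_pair(self, topology):
        res = self._result(topology)
        np.testing.assert_allclose(
            eeg_proxy(res), res.series("SG_E") + res.series("GIG_E"))

    def test_linearity_in_weights(self, topology):
        res = self._result(topology)
        one = eeg_proxy(res, {"SG_E": 1.0, "GIG_E": 1.0})
        two = eeg_proxy(res, {"SG_E": 2.0, "GIG_E": 2.0})
        np.testing.assert_allclose(two, 2 * one)

    def test_rejects_noncortical_and_empty_weights(self, topology):
        res = self._result(topology)
        with pytest.raises(ValueError, match="cortical"):
            eeg_proxy(res, {"RELAY_E": 1.0})
        with pytest.raises(ValueError, match="zero"):
            eeg_proxy(res, {"SG_E": 0.0})


class TestWelch:
    def test_peak_at_sinusoid_frequency(self):
        x, _ = sinusoid(10.0)
        s = welch_psd(x, FS)
        assert s.peak_frequency(0.5) == pytest.approx(10.0, abs=0.125)

    def test_white_noise_flat_within_ten_percent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=int(200 * FS))
        s = welch_psd(x, FS)
        mask = (s.freqs >= 1) & (s.freqs <= 80)
        chunks = np.array_split(s.psd[mask], 8)
        means = np.array([c.mean() for c in chunks])
        assert np.max(np.abs(means / means.mean() - 1)) < 0.10

    def test_total_power_matches_variance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=int(120 * FS))
        s = welch_psd(x, FS, detrend=False)
        total = np.trapezoid(s.psd, s.freqs)
        assert total == pytest.approx(x.var(), rel=0.05)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            welch_psd(np.zeros(100), FS, segment_length=4.0)

    def test_resolution(self):
        x, _ = sinusoid(10.0)
        s = welch_psd(x, FS)
        assert s.freqs[1] - s.freqs[0] <= 0.25


class TestBandPower:
    def test_two_hz_tone_lives_in_delta(self):
        x, _ = sinusoid(2.0)
        s = welch_psd(x, FS)
        per_band = {name: band_power(s, name) * (b.hi - b.lo)
                    for name, b in BANDS.items()}
        assert per_band["delta"] / sum(per_band.values()) > 0.95
        assert band_power(s, "gamma") < 1e-6 * band_power(s, "delta")

    def test_relative_power_of_reference_is_one(self):
        x, _ = sinusoid(12.0)
        s = welch_psd(x, FS)
        for band in BANDS:
            assert relative_power(s, s, band) == 1.0

    def test_empty_band_rejected(self):
        x, _ = sinusoid(2.0)
        s = welch_psd(x, FS)
        with pytest.raises(ValueError):
            band_power(s, FrequencyBand("bad", 300.0, 310.0))


class TestBandpassPhase:
    def test_phase_slope_matches_frequency(self):
        x, _ = sinusoid(12.0, length=30.0)
        phase = bandpass_phase(x, "sigma", FS)
        slope = np.polyfit(np.arange(len(phase)) / FS, np.unwrap(phase), 1)[0]
        assert slope == pytest.approx(2 * np.pi * 12.0, rel=0.01)

    def test_out_of_band_attenuated_20db(self):
        from scipy import signal as sps

        sos = sps.butter(4, [10, 17], btype="bandpass", fs=FS, output="sos")
        w, h = sps.sosfreqz(sos, worN=4096, fs=FS)
        # zero-phase application doubles the attenuation in dB
        gain_db = 2 * 20 * np.log10(np.abs(h[np.argmin(np.abs(w - 30.0))]) + 1e-300)
        assert gain_db < -20.0

    def test_cos_vs_sin_quarter_cycle_lag(self):
        a, _ = sinusoid(12.0, phase=np.pi / 2)  # cos
        b, _ = sinusoid(12.0)                   # sin
        pa = bandpass_phase(a, "sigma", FS)
        pb = bandpass_phase(b, "sigma", FS)
        lag = np.angle(np.exp(1j * (pa - pb)))
        assert np.allclose(lag, np.pi / 2, atol=0.02)

    def test_zero_phase_filter_preserves_alignment(self):
        x, _ = sinusoid(12.0, length=30.0)
        from scipy import signal as sps

        sos = sps.butter(4, [10, 17], btype="bandpass", fs=FS, output="sos")
        y = sps.sosfiltfilt(sos, x)
        corr = np.correlate(y - y.mean(), x - x.mean(), mode="full")
        assert np.argmax(corr) == len(x) - 1

    def test_band_above_nyquist_rejected(self):
        x, _ = sinusoid(5.0, length=10.0, fs=100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_phase(x, "gamma", 100.0)


class TestPLV:
    def test_identical_phases_give_exactly_one(self):
        x, _ = sinusoid(12.0)
        p = bandpass_phase(x, "sigma", FS)
        assert plv(p, p).plv == pytest.approx(1.0, abs=1e-12)

    def test_constant_offset_preserves_locking(self):
        x, _ = sinusoid(12.0)
        p = bandpass_phase(x, "sigma", FS)
        assert plv(p, p + 1.234).plv == pytest.approx(1.0, abs=1e-9)

    def test_independent_uniform_phases_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-np.pi, np.pi, size=100_000)
        b = rng.uniform(-np.pi, np.pi, size=100_000)
        assert plv(a, b).plv <= 0.02

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            plv(np.zeros(10), np.zeros(11))

    def test_symmetry_exact(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(-np.pi, np.pi, size=5000)
        b = rng.uniform(-np.pi, np.pi, size=5000)
        assert plv(a, b).plv == plv(b, a).plv

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounds_on_arbitrary_phases(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 2000)
        a = rng.normal(scale=10, size=n)
        b = rng.normal(scale=10, size=n)
        value = plv(a, b).plv
        assert 0.0 <= value <= 1.0

    def test_plv_between_series(self):
        x, _ = sinusoid(12.0)
        r = plv_between(x, np.roll(x, 3), "sigma", FS, pair=("a", "b"))
        assert r.plv > 0.99
        assert r.band.name == "sigma"


def test_spectral_estimate_stable_under_doubling():
    """Doubling the record length changes band power by less than a few
    relative standard errors of the Welch estimate."""
    from ctcsim.fixtures import FixtureSpec, make_fixture

    for seed in (0, 1, 2):
        short = make_fixture(FixtureSpec("filtered_noise", length=100.0, seed=seed,
                                         parameters={"band": "sigma"}))
        long = make_fixture(FixtureSpec("filtered_noise", length=200.0, seed=seed,
                                        parameters={"band": "sigma"}))
        bp_s = band_power(welch_psd(short.signals["x"], FS), "sigma")
        bp_l = band_power(welch_psd(long.signals["x"], FS), "sigma")
        # ~50 segments of 4 s at 50% overlap -> relative SE ~ 1/sqrt(50)
        assert abs(bp_l / bp_s - 1) < 0.45
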