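"""EEG proxy, spectral summaries and phase-locking functional connectivity.

The EEG proxy is the equally weighted sum of the excitatory cortical
potentials (SG_E + GIG_E); positive values denote depolarization.  Power
spectra are Welch averaged periodograms (4 s Hann segments, 50 % overlap)
computed after decimating the integration grid to 500 Hz with a zero-phase
FIR anti-alias filter, which resolves the delta band (0.25 Hz resolution)
while covering gamma to 80 Hz.  Band powers are the *mean* in-band PSD and
relative powers are ratios of condition to reference band power.

Functional connectivity between two series is the phase-locking value
(PLV): both series are zero-phase band-pass filtered (4th-order
Butterworth, forward-backward), instantaneous phases are extracted from
the analytic signal, and the PLV is the modulus of the time-averaged unit
phasor of the phase difference; PLV = 1 means complete phase locking,
PLV = 0 complete desynchronization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .engine import SimulationResult

__all__ = [
    "FrequencyBand",
    "BANDS",
    "SpectralSummary",
    "PLVResult",
    "eeg_proxy",
    "decimate_to",
    "welch_psd",
    "band_power",
    "relative_power",
    "bandpass_phase",
    "plv",
    "plv_between",
]

_CORTICAL = ("SG_E", "SG_I", "GIG_E", "GIG_I")

#: Target sample rate (Hz) of the analysis grid.
ANALYSIS_FS = 500.0

#: Filter-transient guard (s) discarded at each end before phase extraction.
PHASE_EDGE_GUARD = 1.0


@dataclass(frozen=True)
class FrequencyBand:
    """A named EEG frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("need lo < hi")


#: The canonical bands: delta 1-4 Hz, sigma (sleep spindles) 10-17 Hz,
#: beta 17-30 Hz and broadband gamma 30-80 Hz.
BANDS: dict[str, FrequencyBand] = {
    "delta": FrequencyBand("delta", 1.0, 4.0),
    "sigma": FrequencyBand("sigma", 10.0, 17.0),
    "beta": FrequencyBand("beta", 17.0, 30.0),
    "gamma": FrequencyBand("gamma", 30.0, 80.0),
}


def _as_band(band) -> FrequencyBand:
    return BANDS[band] if isinstance(band, str) else band


@dataclass
class SpectralSummary:
    """Welch PSD of one channel plus derived band powers."""

    freqs: np.ndarray
    psd: np.ndarray
    sample_rate: float
    channel: str = "EEG"

    def band_power(self, band) -> float:
        return band_power(self, band)

    def peak_frequency(self, fmin: float = 0.5, fmax: float | None = None) -> float:
        """Frequency of maximal PSD, restricted to [fmin, fmax]."""
        fmax = fmax if fmax is not None else self.freqs[-1]
        mask = (self.freqs >= fmin) & (self.freqs <= fmax)
        if not mask.any():
            raise ValueError("empty frequency window")
        return float(self.freqs[mask][np.argmax(self.psd[mask])])


@dataclass(frozen=True)
class PLVResult:
    """Phase coherence of one channel pair in one band."""

    pair: tuple
    band: FrequencyBand
    plv: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.plv <= 1.0 + 1e-12:
            raise ValueError("PLV must lie in [0, 1]")


def eeg_proxy(
    result: SimulationResult, weights: Mapping[str, float] | None = None
) -> np.ndarray:
    """Weighted sum of cortical potential series (default SG_E + GIG_E).

    Weights on non-cortical populations are rejected: the EEG originates
    from population activity in the cortical layers.
    """
    if weights is None:
        weights = {"SG_E": 1.0, "GIG_E": 1.0}
    bad = [p for p, w in weights.items() if p not in _CORTICAL and w != 0.0]
    if bad:
        raise ValueError(f"EEG weights allowed on cortical populations only, got {bad}")
    if all(w == 0.0 for w in weights.values()):
        raise ValueError("all EEG weights are zero")
    out = np.zeros(len(result.time))
    for p, w in weights.items():
        if w != 0.0:
            out += w * result.series(p)
    return out


def decimate_to(series: np.ndarray, fs_in: float, fs_out: float = ANALYSIS_FS):
    """Anti-alias filtered decimation to the analysis sample rate."""
    if fs_out > fs_in:
        raise ValueError("cannot decimate upwards")
    q = int(round(fs_in / fs_out))
    if abs(fs_in / fs_out - q) > 1e-9:
        raise ValueError("sample-rate ratio must be an integer")
    x = np.asarray(series, dtype=float)
    if q == 1:
        return x, fs_in
    # demean before the polyphase filter: a large DC offset would otherwise
    # leak edge transients across the whole spectrum
    m = x.mean()
    return sps.resample_poly(x - m, 1, q) + m, fs_in / q


def welch_psd(
    series: np.ndarray,
    sample_rate: float,
    segment_length: float = 4.0,
    overlap: float = 0.5,
    channel: str = "EEG",
    detrend: str = "constant",
) -> SpectralSummary:
    """Welch averaged-periodogram PSD (Hann taper, one-sided, mV^2/Hz).

    Default 4 s segments give a 0.25 Hz frequency resolution.
    """
    series = np.asarray(series, dtype=float)
    nperseg = int(round(segment_length * sample_rate))
    if nperseg < 2:
        raise ValueError("segment shorter than two samples")
    if len(series) < nperseg:
        raise ValueError(
            f"series of {len(series)} samples is shorter than one "
            f"{nperseg}-sample segment"
        )
    freqs, psd = sps.welch(
        series,
        fs=sample_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)),
        detrend=detrend,
    )
    return SpectralSummary(freqs=freqs, psd=psd, sample_rate=sample_rate, channel=channel)


def band_power(summary: SpectralSummary, band) -> float:
    """Mean in-band PSD (mV^2/Hz averaged over in-band frequency bins)."""
    band = _as_band(band)
    mask = (summary.freqs >= band.lo) & (summary.freqs <= band.hi)
    if not mask.any():
        raise ValueError(f"no frequency bins inside band {band.name}")
    return float(summary.psd[mask].mean())


def relative_power(summary_cond: SpectralSummary, summary_ref: SpectralSummary, band) -> float:
    """Ratio of condition to reference mean in-band PSD."""
    return band_power(summary_cond, band) / band_power(summary_ref, band)


def bandpass_phase(
    series: np.ndarray,
    band,
    sample_rate: float,
    order: int = 4,
    edge_guard: float = PHASE_EDGE_GUARD,
) -> np.ndarray:
    """Instantaneous phase of the band-limited analytic signal, in (-pi, pi].

    Zero-phase (forward-backward) Butterworth band-pass, then Hilbert
    analytic signal.  ``edge_guard`` seconds are discarded at each end to
    suppress filter transients.
    """
    band = _as_band(band)
    if band.hi >= sample_rate / 2:
        raise ValueError("band upper edge must lie below the Nyquist frequency")
    sos = sps.butter(order, [band.lo, band.hi], btype="bandpass", fs=sample_rate, output="sos")
    if not np.all(np.abs(sps.sos2zpk(sos)[1]) < 1.0):
        raise ValueError("unstable band-pass filter design; lower the order")
    x = sps.sosfiltfilt(sos, np.asarray(series, dtype=float))
    phase = np.angle(sps.hilbert(x))
    guard = int(round(edge_guard * sample_rate))
    if guard > 0 and len(phase) > 2 * guard:
        phase = phase[guard:-guard]
    return phase


def plv(phase_a: np.ndarray, phase_b: np.ndarray, pair=("a", "b"), band=None) -> PLVResult:
    """Phase-locking value: modulus of the mean unit phasor of the phase lag."""
    phase_a = np.asarray(phase_a, dtype=float)
    phase_b = np.asarray(phase_b, dtype=float)
    if phase_a.shape != phase_b.shape:
        raise ValueError("phase series must have equal length")
    value = float(np.abs(np.mean(np.exp(1j * (phase_a - phase_b)))))
    band = _as_band(band) if band is not None else FrequencyBand("broadband", 0.0, np.inf)
    return PLVResult(pair=tuple(pair), band=band, plv=min(value, 1.0))


def plv_between(
    series_a: np.ndarray,
    series_b: np.ndarray,
    band,
    sample_rate: float,
    pair=("a", "b"),
) -> PLVResult:
    """Band-pass both series, extract phases and compute their PLV."""
    pa = bandpass_phase(series_a, band, sample_rate)
    pb = bandpass_phase(series_b, band, sample_rate)
    return plv(pa, pb, pair=pair, band=_as_band(band))
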