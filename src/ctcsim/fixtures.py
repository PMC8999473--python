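"""Synthetic test signals with known ground truth for the observables.

Three kinds of labelled signals, independent of the full network
simulator:

* ``sinusoid`` — a pure tone with known frequency, amplitude and phase.
* ``filtered_noise`` — Gaussian white noise band-passed into a target band.
* ``coupled_oscillators`` — two noisy Kuramoto-style phase oscillators
  with adjustable coupling; their asymptotic PLV tends to 0 as the
  coupling vanishes and to 1 as it dominates the phase noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .observables import BANDS, FrequencyBand

__all__ = ["FixtureSpec", "FixtureSet", "make_fixture"]

_KINDS = ("sinusoid", "coupled_oscillators", "filtered_noise")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one labelled synthetic signal set."""

    kind: str
    length: float = 60.0           # s
    sample_rate: float = 500.0     # Hz
    seed: int = 0
    parameters: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {_KINDS}")
        if self.length <= 0 or self.sample_rate <= 0:
            raise ValueError("length and sample_rate must be positive")
        pars = dict(self.parameters)
        if self.kind == "sinusoid":
            if pars.get("frequency", 10.0) <= 0:
                raise ValueError("sinusoid frequency must be positive")
        if self.kind == "coupled_oscillators":
            if pars.get("coupling", 0.0) < 0:
                raise ValueError("coupling must be non-negative")


@dataclass
class FixtureSet:
    """Signals plus their ground-truth metadata."""

    time: np.ndarray
    signals: dict
    metadata: dict
    sample_rate: float


def _band_of(frequency: float) -> str | None:
    for name, band in BANDS.items():
        if band.lo <= frequency <= band.hi:
            return name
    return None


def make_fixture(spec: FixtureSpec) -> FixtureSet:
    """Generate the signal set described by ``spec`` (deterministic in seed)."""
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    n = int(round(spec.length * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    pars = dict(spec.parameters)

    if spec.kind == "sinusoid":
        f0 = float(pars.get("frequency", 10.0))
        amp = float(pars.get("amplitude", 1.0))
        phase = float(pars.get("phase", 0.0))
        x = amp * np.sin(2 * np.pi * f0 * t + phase)
        meta = {"frequency": f0, "amplitude": amp, "phase": phase, "band": _band_of(f0)}
        return FixtureSet(time=t, signals={"x": x}, metadata=meta, sample_rate=spec.sample_rate)

    if spec.kind == "filtered_noise":
        band = pars.get("band", "sigma")
        band = BANDS[band] if isinstance(band, str) else band
        level = float(pars.get("noise_level", 1.0))
        sos = sps.butter(4, [band.lo, band.hi], btype="bandpass", fs=spec.sample_rate, output="sos")
        x = sps.sosfiltfilt(sos, level * rng.normal(size=n))
        meta = {"band": band.name, "noise_level": level}
        return FixtureSet(time=t, signals={"x": x}, metadata=meta, sample_rate=spec.sample_rate)

    # coupled_oscillators: d phi1 = w1 dt + s dW1;
    # d phi2 = (w2 + K sin(phi1 - phi2)) dt + s dW2.
    # K = 0 -> independent phases (PLV -> 0); K >> s, |w1 - w2| -> locked
    # (PLV -> 1, phase lag arcsin((w2 - w1)/K)).
    f1 = float(pars.get("frequency", 12.0))
    f2 = float(pars.get("frequency_2", f1 + 0.5))
    K = float(pars.get("coupling", 0.0))
    noise = float(pars.get("noise_level", 2.0))  # rad / sqrt(s)
    dt = 1.0 / spec.sample_rate
    w1, w2 = 2 * np.pi * f1, 2 * np.pi * f2
    dW = rng.normal(0.0, np.sqrt(dt), size=(n, 2)) * noise
    phi = np.zeros((n, 2))
    for i in range(1, n):
        p1, p2 = phi[i - 1]
        phi[i, 0] = p1 + w1 * dt + dW[i, 0]
        phi[i, 1] = p2 + (w2 + K * np.sin(p1 - p2)) * dt + dW[i, 1]
    sigs = {"x": np.cos(phi[:, 0]), "y": np.cos(phi[:, 1]),
            "phase_x": np.mod(phi[:, 0] + np.pi, 2 * np.pi) - np.pi,
            "phase_y": np.mod(phi[:, 1] + np.pi, 2 * np.pi) - np.pi}
    meta = {
        "frequency": f1,
        "frequency_2": f2,
        "coupling": K,
        "noise_level": noise,
        "band": _band_of(f1),
        "plv_limit_zero_coupling": 0.0,
        "plv_limit_strong_coupling": 1.0,
    }
    return FixtureSet(time=t, signals=sigs, metadata=meta, sample_rate=spec.sample_rate)
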