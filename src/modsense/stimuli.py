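"""Synthesis of modulation-detection stimuli.

Two stimulus families are supported:

* **Temporal**: broadband Gaussian noise (0.05–8.0 kHz) whose envelope is
  sinusoidally amplitude-modulated at 8 or 64 Hz.  Modulation depth ``m`` in
  (0, 1] is expressed in dB as ``20*log10(m)`` (0 dB = full modulation).
* **Spectral**: a complex of 800 equal-amplitude sinewave components
  log-spaced on 0.1–5.0 kHz.  The target carries a sinusoidal spectral
  ripple at 0.5 cycles/octave whose size is expressed as the peak-to-trough
  range in dB; the standard has a flat spectrum.  Both receive raised-cosine
  edge tapers and a speech-shaped long-term spectral weighting.

All stimuli are 500 ms with 20-ms cosine-squared onset/offset ramps, RMS
equalized, and presented at a nominal 68 dB level; the spectral task roves
the per-interval level by ±3 dB to remove loudness cues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.io import wavfile

__all__ = [
    "StimulusSpec",
    "Waveform",
    "RippleEnvelope",
    "depth_to_db",
    "db_to_depth",
    "make_carrier_noise",
    "apply_temporal_am",
    "make_ripple_envelope",
    "synthesize_spectral",
    "apply_ramps",
    "equalize_rms",
    "set_presentation_level",
    "synthesize_interval",
    "write_wav",
]

#: Band edges of the temporal-task noise carrier, Hz.
CARRIER_BAND_HZ = (50.0, 8000.0)
#: Component count and band of the spectral-ripple complex.
N_RIPPLE_COMPONENTS = 800
RIPPLE_BAND_HZ = (100.0, 5000.0)
#: Ripple rate in cycles per octave.
RIPPLE_RATE_CPO = 0.5
#: Digital RMS that maps to the nominal presentation level.
REFERENCE_RMS = 0.05


@dataclass(frozen=True)
class StimulusSpec:
    """Full parameterization of one modulation-detection interval."""

    kind: Literal["temporal", "spectral"]
    modulation_rate: float  # Hz (temporal) or cycles/octave (spectral)
    depth_dB: float  # 20*log10(m) <= 0 (temporal); peak-to-trough >= 0 (spectral)
    duration_s: float = 0.5
    ramp_ms: float = 20.0
    nominal_level_dB: float = 68.0
    rove_dB: float = 0.0
    sample_rate: float = 44100.0

    def __post_init__(self) -> None:
        if self.kind not in ("temporal", "spectral"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.kind == "temporal" and self.depth_dB > 0:
            raise ValueError("temporal depth_dB must be <= 0 (20*log10(m), m <= 1)")
        if self.kind == "spectral" and self.depth_dB < 0:
            raise ValueError("spectral depth_dB (peak-to-trough) must be >= 0")
        if self.duration_s <= 2 * self.ramp_ms / 1000.0:
            raise ValueError("duration must exceed the two ramps")
        top = CARRIER_BAND_HZ[1] if self.kind == "temporal" else RIPPLE_BAND_HZ[1]
        if self.sample_rate < 2 * top:
            raise ValueError(f"sample_rate {self.sample_rate} Hz cannot represent {top} Hz")
        if self.rove_dB < 0:
            raise ValueError("rove_dB is a half-range and must be >= 0")

    @classmethod
    def temporal(cls, rate_hz: float, depth_dB: float, **kw) -> "StimulusSpec":
        return cls(kind="temporal", modulation_rate=rate_hz, depth_dB=depth_dB, **kw)

    @classmethod
    def spectral(cls, depth_dB: float, rate_cpo: float = RIPPLE_RATE_CPO, **kw) -> "StimulusSpec":
        kw.setdefault("rove_dB", 3.0)
        return cls(kind="spectral", modulation_rate=rate_cpo, depth_dB=depth_dB, **kw)


@dataclass
class Waveform:
    """A sampled waveform; amplitudes are dimensionless, calibrated so that
    ``REFERENCE_RMS`` corresponds to the nominal presentation level."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def copy(self) -> "Waveform":
        return Waveform(self.samples.copy(), self.sample_rate)


@dataclass
class RippleEnvelope:
    """Per-component amplitudes (dB) of the spectral-ripple complex."""

    component_freqs: np.ndarray  # Hz, strictly increasing, log-spaced
    component_amps_dB: np.ndarray
    envelope_phase: float  # radians

    def __post_init__(self) -> None:
        self.component_freqs = np.asarray(self.component_freqs, dtype=np.float64)
        self.component_amps_dB = np.asarray(self.component_amps_dB, dtype=np.float64)
        if len(self.component_freqs) != N_RIPPLE_COMPONENTS:
            raise ValueError(f"expected {N_RIPPLE_COMPONENTS} components")
        if np.any(np.diff(self.component_freqs) <= 0):
            raise ValueError("component frequencies must be strictly increasing")

    def peak_to_trough_dB(self) -> float:
        return float(self.component_amps_dB.max() - self.component_amps_dB.min())


def depth_to_db(m: float) -> float:
    """Convert linear modulation depth ``m`` in (0, 1] to dB, ``20*log10(m)``.

    ``m = 1`` (full modulation) maps to 0 dB; shallower modulation is more
    negative.  ``m = 0`` has no dB representation and raises.
    """
    if not 0 < m <= 1:
        raise ValueError(f"modulation depth must be in (0, 1], got {m}")
    return float(20.0 * np.log10(m))


def db_to_depth(d: float) -> float:
    """Inverse of :func:`depth_to_db`: dB (<= 0) back to linear depth."""
    if d > 0:
        raise ValueError(f"depth in dB must be <= 0, got {d}")
    return float(10.0 ** (d / 20.0))


def make_carrier_noise(spec: StimulusSpec, seed: int) -> Waveform:
    """Broadband Gaussian noise carrier band-limited to 0.05–8.0 kHz.

    Band limiting is a frequency-domain brick wall: rFFT bins outside the
    band are zeroed.  Deterministic for a fixed seed.
    """
    if spec.kind != "temporal":
        raise ValueError("noise carrier is only defined for temporal stimuli")
    if spec.sample_rate < 16000:
        raise ValueError("sample_rate must be >= 16 kHz to represent the carrier band")
    rng = np.random.default_rng(seed)
    n = round(spec.duration_s * spec.sample_rate)
    x = rng.standard_normal(n)
    spectrum = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, d=1.0 / spec.sample_rate)
    lo, hi = CARRIER_BAND_HZ
    spectrum[(freqs < lo) | (freqs > hi)] = 0.0
    y = np.fft.irfft(spectrum, n)
    return Waveform(y, spec.sample_rate)


def apply_temporal_am(
    carrier: Waveform, rate_hz: float, m: float, mod_phase: float = 0.0
) -> Waveform:
    """Sinusoidal amplitude modulation: multiply by ``1 + m*sin(2*pi*f*t + phi)``."""
    if not 0 <= m <= 1:
        raise ValueError(f"modulation depth must be in [0, 1], got {m}")
    t = np.arange(len(carrier.samples)) / carrier.sample_rate
    modulator = 1.0 + m * np.sin(2 * np.pi * rate_hz * t + mod_phase)
    return Waveform(carrier.samples * modulator, carrier.sample_rate)


def _ripple_freqs() -> np.ndarray:
    lo, hi = RIPPLE_BAND_HZ
    return np.logspace(np.log10(lo), np.log10(hi), N_RIPPLE_COMPONENTS)


def make_ripple_envelope(depth_dB: float, env_phase: float = 0.0) -> RippleEnvelope:
    """Sinusoidal spectral envelope at 0.5 cycles/octave over the 800
    log-spaced components; ``depth_dB`` is the peak-to-trough range so the
    sinusoid's amplitude is ``depth_dB / 2``.  Depth 0 gives a flat envelope.
    """
    if depth_dB < 0:
        raise ValueError("ripple depth (peak-to-trough dB) must be >= 0")
    freqs = _ripple_freqs()
    octaves = np.log2(freqs / freqs[0])
    amps = (depth_dB / 2.0) * np.sin(2 * np.pi * RIPPLE_RATE_CPO * octaves + env_phase)
    return RippleEnvelope(freqs, amps, env_phase)


def _edge_taper_dB(freqs: np.ndarray) -> np.ndarray:
    """Raised-cosine attenuation (in dB) over the outermost half-octave at
    each band edge, so component amplitudes grow in gradually at the bottom
    of the band and fade out at the top."""
    octaves = np.log2(freqs / freqs[0])
    total = octaves[-1]
    half_oct = 0.5
    atten_dB = 40.0  # attenuation reached at the outermost component
    taper = np.zeros_like(octaves)
    lo_zone = octaves < half_oct
    taper[lo_zone] = -atten_dB * 0.5 * (1 + np.cos(np.pi * octaves[lo_zone] / half_oct))
    hi_zone = octaves > total - half_oct
    taper[hi_zone] = -atten_dB * 0.5 * (
        1 + np.cos(np.pi * (total - octaves[hi_zone]) / half_oct)
    )
    return taper


def _speech_shape_dB(freqs: np.ndarray) -> np.ndarray:
    """Long-term-average speech-spectrum weighting: flat to 500 Hz, then
    −9 dB/octave.  A conventional approximation; swap by passing
    ``speech_shape`` to :func:`synthesize_spectral`."""
    shape = np.zeros_like(freqs)
    above = freqs > 500.0
    shape[above] = -9.0 * np.log2(freqs[above] / 500.0)
    return shape


def synthesize_spectral(
    spec: StimulusSpec,
    is_target: bool,
    seed: int,
    speech_shape=None,
    edge_taper=None,
) -> Waveform:
    """One interval of the spectral-modulation task.

    The 800 components get fresh random phases per call (per trial); the
    target additionally carries the ripple envelope with a random envelope
    phase.  Edge tapers and the speech-shaped weighting are then applied to
    both target and standard, followed by onset/offset ramps and RMS
    equalization to the reference.
    """
    if spec.kind != "spectral":
        raise ValueError("synthesize_spectral requires a spectral StimulusSpec")
    rng = np.random.default_rng(seed)
    freqs = _ripple_freqs()
    comp_phase = rng.uniform(0, 2 * np.pi, size=N_RIPPLE_COMPONENTS)
    if is_target:
        env_phase = rng.uniform(0, 2 * np.pi)
        ripple = make_ripple_envelope(spec.depth_dB, env_phase)
        amps_dB = ripple.component_amps_dB.copy()
    else:
        amps_dB = np.zeros(N_RIPPLE_COMPONENTS)
    amps_dB = amps_dB + (edge_taper or _edge_taper_dB)(freqs)
    amps_dB = amps_dB + (speech_shape or _speech_shape_dB)(freqs)
    amps = 10.0 ** (amps_dB / 20.0)

    n = round(spec.duration_s * spec.sample_rate)
    t = np.arange(n) / spec.sample_rate
    # (n_comp, n) outer product is ~280 MB at 44.1 kHz; accumulate in blocks.
    y = np.zeros(n)
    block = 100
    for i in range(0, N_RIPPLE_COMPONENTS, block):
        sl = slice(i, i + block)
        y += (amps[sl, None] * np.sin(2 * np.pi * freqs[sl, None] * t + comp_phase[sl, None])).sum(
            axis=0
        )
    w = apply_ramps(Waveform(y, spec.sample_rate), spec.ramp_ms)
    (w,) = equalize_rms([w])
    return w


def apply_ramps(w: Waveform, ramp_ms: float) -> Waveform:
    """Cosine-squared onset and offset ramps of ``ramp_ms`` milliseconds."""
    n_ramp = round(ramp_ms / 1000.0 * w.sample_rate)
    if 2 * n_ramp > len(w.samples):
        raise ValueError("ramps longer than the stimulus")
    gain = np.ones(len(w.samples))
    # sin^2 rising 0 -> 1 over the ramp (equivalently cos^2 falling at offset)
    ramp = np.sin(0.5 * np.pi * np.arange(n_ramp) / n_ramp) ** 2
    gain[:n_ramp] = ramp
    gain[len(gain) - n_ramp :] = ramp[::-1]
    return Waveform(w.samples * gain, w.sample_rate)


def equalize_rms(waves: Sequence[Waveform], ref_rms: float = REFERENCE_RMS) -> list[Waveform]:
    """Scale each waveform so its RMS equals ``ref_rms``."""
    out = []
    for w in waves:
        r = w.rms()
        if r == 0:
            raise ValueError("cannot RMS-equalize a silent waveform")
        out.append(Waveform(w.samples * (ref_rms / r), w.sample_rate))
    return out


def set_presentation_level(
    w: Waveform, nominal_dB: float, rove_dB: float, rng: np.random.Generator
) -> tuple[Waveform, float]:
    """Apply the per-interval level rove: the realized level is the nominal
    plus a uniform draw on [−rove_dB, +rove_dB].  Returns the scaled waveform
    and the realized level.  With ``rove_dB = 0`` the level is exact."""
    if rove_dB < 0:
        raise ValueError("rove_dB must be >= 0")
    u = rng.uniform(-rove_dB, rove_dB) if rove_dB > 0 else 0.0
    applied = nominal_dB + u
    return Waveform(w.samples * 10.0 ** (u / 20.0), w.sample_rate), applied


def synthesize_interval(
    spec: StimulusSpec,
    is_target: bool,
    seed: int,
    mod_phase: float | None = None,
) -> Waveform:
    """Synthesize one complete interval (pre-rove): carrier/complex,
    modulation if target, ramps, RMS equalization.  Pure function of
    ``(spec, is_target, seed)`` when ``mod_phase`` is fixed."""
    if spec.kind == "spectral":
        return synthesize_spectral(spec, is_target, seed)
    carrier = make_carrier_noise(spec, seed)
    if is_target:
        rng = np.random.default_rng((seed, 0x5EED))
        phase = rng.uniform(0, 2 * np.pi) if mod_phase is None else mod_phase
        carrier = apply_temporal_am(carrier, spec.modulation_rate, db_to_depth(spec.depth_dB), phase)
    w = apply_ramps(carrier, spec.ramp_ms)
    (w,) = equalize_rms([w])
    return w


def load_stimulus_config(path: str | Path) -> StimulusSpec:
    """Read a StimulusSpec from a YAML file whose keys mirror its fields."""
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    return StimulusSpec(**data)


def write_wav(path: str | Path, w: Waveform, meta: dict | None = None) -> None:
    """Write a float32 RIFF WAV plus a JSON metadata sidecar."""
    path = Path(path)
    wavfile.write(path, int(w.sample_rate), w.samples.astype(np.float32))
    if meta is not None:
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))
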