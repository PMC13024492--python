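"""Synthetic acoustic segments from a driven thin-film resonator.

The sensing chain being emulated: a signal generator drives the piezoelectric
film with a periodic waveform; the film vibrates as a second-order resonator
whose resonance sits at the mass-loaded frequency; the emitted sound is
captured by a 48 kHz microphone with additive sensor/room noise.  Each
generated segment is the steady-state acoustic response, peak-normalized,
with noise injected at a prescribed SNR.

The mass dependence enters only through the loaded resonance frequency
(physics.film_shift), so every downstream stage — feature extraction,
classification, calibration — can be exercised without the hardware.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError
from .physics import ResonatorSpec, film_shift, UG_PER_G

__all__ = [
    "ExcitationSpec",
    "NoiseSpec",
    "AcousticSegment",
    "LabeledDataset",
    "loaded_resonance",
    "amplitude_response",
    "synth_segment",
    "build_dataset",
    "default_resonator",
    "harmonic_series",
]

WAVEFORMS = ("sine", "square", "triangle")


def default_resonator() -> ResonatorSpec:
    """The PVDF device studied here: f0 = 8.5 kHz, Q = 27.6, 28 um film,
    5 mm active diameter.  The PVDF density (1.78 g/cm^3) is a literature
    value for the polymer, not a device measurement."""
    return ResonatorSpec(f0_hz=8500.0, q=27.6, diameter_mm=5.0,
                         rho_g_cm3=1.78, thickness_um=28.0)


@dataclass(frozen=True)
class ExcitationSpec:
    """Drive waveform for the signal generator."""

    waveform: str = "sine"
    frequency_hz: float = 8500.0
    amplitude: float = 1.0

    def __post_init__(self):
        if self.waveform not in WAVEFORMS:
            raise ConfigurationError(f"waveform must be one of {WAVEFORMS}")
        if self.frequency_hz <= 0:
            raise DomainError("excitation frequency must be positive")
        if self.amplitude < 0:
            raise DomainError("excitation amplitude must be nonnegative")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive capture noise: target SNR (dB) and the share of 1/f noise."""

    snr_db: float = 30.0
    pink_fraction: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.pink_fraction <= 1.0:
            raise ConfigurationError("pink_fraction must lie in [0, 1]")


@dataclass
class AcousticSegment:
    """One mono waveform with its sampling rate and (optional) mass label."""

    samples: np.ndarray
    fs: float
    duration: float
    label_ug: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples)
        n = int(round(self.fs * self.duration))
        if len(self.samples) != n:
            raise DomainError(
                f"segment length {len(self.samples)} != round(fs*duration) = {n}")


@dataclass
class LabeledDataset:
    """Segments + class labels (+ optional train/val/test split assignment)."""

    segments: List[AcousticSegment]
    labels: np.ndarray                      # mass class per segment, ug
    classes: Sequence[float]                # the declared class set, ug
    seed: int
    split: Optional[np.ndarray] = None      # per-segment "train"/"val"/"test"

    def __len__(self) -> int:
        return len(self.segments)

    def class_index(self) -> np.ndarray:
        """Integer class index per segment (position in ``classes``)."""
        lookup = {c: i for i, c in enumerate(self.classes)}
        return np.array([lookup[l] for l in self.labels], dtype=np.int64)

    def subset(self, which: str) -> "LabeledDataset":
        if self.split is None:
            raise ConfigurationError("dataset has no split assignment yet")
        idx = np.flatnonzero(self.split == which)
        return LabeledDataset(
            segments=[self.segments[i] for i in idx],
            labels=self.labels[idx], classes=self.classes, seed=self.seed,
            split=self.split[idx])

    def manifest_digest(self) -> str:
        """SHA-256 over labels, splits, seeds and sample bytes (determinism checks)."""
        h = hashlib.sha256()
        h.update(json.dumps([float(c) for c in self.classes]).encode())
        h.update(np.asarray(self.labels, dtype=np.float64).tobytes())
        if self.split is not None:
            h.update(",".join(self.split.tolist()).encode())
        for seg in self.segments:
            h.update(np.int64(-1 if seg.seed is None else seg.seed).tobytes())
            h.update(np.asarray(seg.samples, dtype=np.float64).tobytes())
        return h.hexdigest()


def loaded_resonance(spec: ResonatorSpec, delta_m_ug: float,
                     separation_scale: float = 1.0) -> float:
    """Resonant frequency (Hz) under a total mass load in micrograms.

    The shift comes from the thin-film relation with the load spread over the
    active area.  ``separation_scale`` multiplies the physical shift; it is a
    simulator knob for constructing easier or harder synthetic benchmarks and
    is not part of the device physics (1.0 = physical).
    """
    if delta_m_ug < 0:
        raise DomainError("mass load must be nonnegative")
    dmA = delta_m_ug / UG_PER_G / spec.area
    return spec.f0_hz + separation_scale * film_shift(spec, dmA)


def amplitude_response(spec: ResonatorSpec, f, fr: float):
    """Magnitude response |H(f)| of a second-order resonator at resonance fr.

    H(f) = 1 / ((1 - (f/fr)^2) + i (f/fr)/Q), normalized to unit DC gain;
    the peak gain is Q at f = fr and the half-power width is ~ fr/Q for
    Q >> 1.  Vectorized over ``f``.
    """
    if fr <= 0:
        raise DomainError("fr must be positive")
    q = spec.quality
    r = np.asarray(f, dtype=float) / fr
    out = 1.0 / np.sqrt((1.0 - r ** 2) ** 2 + (r / q) ** 2)
    return out if out.ndim else float(out)


def _response_phase(spec: ResonatorSpec, f, fr: float):
    """Phase of H(f) (radians); -pi/2 exactly at resonance."""
    q = spec.quality
    r = np.asarray(f, dtype=float) / fr
    return np.arctan2(-r / q, 1.0 - r ** 2)


def harmonic_series(waveform: str, n_max: int):
    """Fourier sine-series coefficients (k, a_k) of a unit-amplitude waveform,
    for harmonics k <= n_max.  Sine has the single term (1, 1)."""
    if waveform == "sine":
        return [(1, 1.0)] if n_max >= 1 else []
    terms = []
    for k in range(1, n_max + 1, 2):
        if waveform == "square":
            terms.append((k, 4.0 / (np.pi * k)))
        elif waveform == "triangle":
            sign = 1.0 if (k - 1) // 2 % 2 == 0 else -1.0
            terms.append((k, sign * 8.0 / (np.pi ** 2 * k ** 2)))
        else:
            raise ConfigurationError(f"unknown waveform {waveform!r}")
    return terms


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-power 1/f-shaped Gaussian noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n)
    return pink / np.std(pink)


def synth_segment(spec: ResonatorSpec, excitation: ExcitationSpec,
                  delta_m_ug: float, noise: NoiseSpec,
                  fs: float = 48000.0, duration: float = 0.1,
                  seed: Optional[int] = None, separation_scale: float = 1.0,
                  return_components: bool = False) -> AcousticSegment:
    """Steady-state acoustic response of the mass-loaded resonator.

    The drive waveform is expanded in its Fourier harmonics (truncated at
    Nyquist); each harmonic is filtered by the resonator's magnitude and
    phase response at the loaded resonance; the sum is scaled to unit peak;
    Gaussian noise (white/pink mix) is added to realize ``noise.snr_db``
    exactly for the realization; finally the segment is re-normalized to
    peak 1.  Identical arguments and seed give identical samples.

    With ``return_components=True`` the pre-normalization (clean, noise)
    pair is attached as ``segment.components`` for SNR auditing.
    """
    if duration <= 0:
        raise DomainError("duration must be positive")
    if excitation.frequency_hz >= fs / 2:
        raise DomainError(
            f"excitation at {excitation.frequency_hz} Hz violates Nyquist for fs={fs}")
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    fr = loaded_resonance(spec, delta_m_ug, separation_scale)

    clean = np.zeros(n)
    if excitation.amplitude > 0:
        n_max = int(np.floor((fs / 2 - 1e-9) / excitation.frequency_hz))
        for k, a_k in harmonic_series(excitation.waveform, n_max):
            f_k = k * excitation.frequency_hz
            gain = amplitude_response(spec, f_k, fr)
            phase = _response_phase(spec, f_k, fr)
            clean += excitation.amplitude * a_k * gain * np.sin(
                2 * np.pi * f_k * t + phase)
        peak = np.max(np.abs(clean))
        if peak > 0:
            clean = clean / peak

    rng = np.random.default_rng(seed)
    if np.isinf(noise.snr_db):
        noise_part = np.zeros(n)
    else:
        white = rng.standard_normal(n)
        white /= np.std(white)
        mix = np.sqrt(1.0 - noise.pink_fraction) * white
        if noise.pink_fraction > 0:
            mix = mix + np.sqrt(noise.pink_fraction) * _pink_noise(rng, n)
        mix /= np.std(mix)
        sig_power = np.mean(clean ** 2)
        if sig_power == 0:
            sig_power = 1.0  # pure-noise segment: unit noise power
        noise_power = sig_power / 10.0 ** (noise.snr_db / 10.0)
        noise_part = mix * np.sqrt(noise_power)

    samples = clean + noise_part
    peak = np.max(np.abs(samples))
    if peak > 0:
        samples = samples / peak
    seg = AcousticSegment(samples=samples, fs=fs, duration=duration,
                          label_ug=delta_m_ug, seed=seed)
    if return_components:
        seg.components = (clean, noise_part)
    return seg


def segment_seed(master_seed: int, index: int) -> int:
    """Deterministic per-segment seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)


def build_dataset(spec: ResonatorSpec, excitation: ExcitationSpec,
                  classes: Sequence[float], n_per_class: int,
                  noise: NoiseSpec, fs: float = 48000.0, duration: float = 0.1,
                  seed: int = 0, separation_scale: float = 1.0) -> LabeledDataset:
    """Balanced labeled dataset of synthetic segments.

    Segment generation order is randomized (emulating a randomized mass-load
    sequence per acquisition session) but per-segment seeds are derived
    deterministically from the master seed, so the dataset is reproducible
    and any one segment can be regenerated in isolation.
    """
    classes = list(classes)
    if not classes:
        raise ConfigurationError("classes must be nonempty")
    if len(set(classes)) != len(classes):
        raise ConfigurationError("duplicate class labels")
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")

    jobs = [(c, rep) for c in classes for rep in range(n_per_class)]
    order = np.random.default_rng(seed).permutation(len(jobs))
    segments: List[AcousticSegment] = []
    labels = np.empty(len(jobs))
    for pos, j in enumerate(order):
        c, _rep = jobs[j]
        seg = synth_segment(spec, excitation, c, noise, fs=fs, duration=duration,
                            seed=segment_seed(seed, int(j)),
                            separation_scale=separation_scale)
        segments.append(seg)
        labels[pos] = c
    return LabeledDataset(segments=segments, labels=labels, classes=classes,
                          seed=seed)
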