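"""Segment-to-model-input transforms.

Three representations feed the classifiers:

* ``dual_channel_input`` — the raw waveform paired with its FFT magnitude
  resampled to the waveform length, each z-scored: the (N, 2) input of the
  convolutional and recurrent models.
* ``frame_sequence`` — the dual-channel input folded into non-overlapping
  frames, giving the recurrent model a short timestep sequence.
* ``patchify`` — sliding fixed-length windows over the raw waveform: the
  token sequence of the Transformer (C = 1).

``fft_magnitude`` / ``dominant_frequency`` also back the calibration path,
where a resonance is read off a long segment's spectrum with sub-bin
precision via parabolic peak interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .simulator import AcousticSegment

__all__ = [
    "SpectralFeatures",
    "PatchSequence",
    "fft_magnitude",
    "dual_channel_input",
    "frame_sequence",
    "patchify",
    "dominant_frequency",
    "standardize",
]

STD_FLOOR = 1e-12


@dataclass
class SpectralFeatures:
    """One-sided FFT magnitude spectrum of a segment."""

    magnitudes: np.ndarray
    bin_hz: float

    @property
    def n_bins(self) -> int:
        return len(self.magnitudes)

    def frequencies(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_hz


@dataclass
class PatchSequence:
    """Ordered fixed-length windows cut from a segment (tokens)."""

    patches: np.ndarray  # (n_patches, T) or (n_patches, T, C)
    T: int
    stride: int
    C: int = 1

    @property
    def n_patches(self) -> int:
        return len(self.patches)


def _samples(segment) -> np.ndarray:
    if isinstance(segment, AcousticSegment):
        return np.asarray(segment.samples, dtype=float)
    return np.asarray(segment, dtype=float)


def fft_magnitude(segment, zero_pad: int = 1) -> SpectralFeatures:
    """One-sided FFT magnitude.  For N samples at rate fs the spectrum has
    floor(N/2)+1 bins spaced fs/N Hz apart (4800 pts @ 48 kHz -> 2401 bins
    at 10 Hz).  ``zero_pad`` > 1 evaluates a denser grid (fs/(N*zero_pad))
    for sub-bin peak localization; it adds no information, only resolution
    of the interpolation grid."""
    x = _samples(segment)
    if x.size == 0:
        raise DomainError("cannot transform an empty segment")
    if zero_pad < 1:
        raise DomainError("zero_pad must be >= 1")
    fs = segment.fs if isinstance(segment, AcousticSegment) else 1.0
    n = len(x) * int(zero_pad)
    mags = np.abs(np.fft.rfft(x, n=n))
    return SpectralFeatures(magnitudes=mags, bin_hz=fs / n)


def standardize(x: np.ndarray) -> np.ndarray:
    """Z-score with a floor on the denominator so constant inputs map to 0."""
    x = np.asarray(x, dtype=float)
    return (x - x.mean()) / max(x.std(), STD_FLOOR)


def dual_channel_input(segment) -> np.ndarray:
    """(N, 2) model input: standardized raw samples and standardized FFT
    magnitude linearly resampled from floor(N/2)+1 bins up to length N."""
    x = _samples(segment)
    n = len(x)
    spec = fft_magnitude(segment)
    resampled = np.interp(np.linspace(0.0, spec.n_bins - 1.0, n),
                          np.arange(spec.n_bins), spec.magnitudes)
    return np.stack([standardize(x), standardize(resampled)], axis=1)


def frame_sequence(segment, frame: int = 48) -> np.ndarray:
    """Fold the (N, 2) dual-channel input into non-overlapping frames:
    output (N//frame, 2*frame), a timestep sequence for recurrent models."""
    dc = dual_channel_input(segment)
    n = (len(dc) // frame) * frame
    return dc[:n].reshape(-1, frame, 2).reshape(-1, 2 * frame)


def patchify(segment, T: int = 48, stride: int = 48) -> PatchSequence:
    """Sliding-window tokens over the standardized raw waveform.

    n_patches = floor((N - T)/stride) + 1; the trailing remainder that does
    not fill a window is dropped.
    """
    x = standardize(_samples(segment))
    n = len(x)
    if not 1 <= T <= n:
        raise DomainError(f"patch length T={T} invalid for segment length {n}")
    if stride < 1:
        raise DomainError("stride must be >= 1")
    n_patches = (n - T) // stride + 1
    idx = np.arange(T)[None, :] + stride * np.arange(n_patches)[:, None]
    return PatchSequence(patches=x[idx], T=T, stride=stride, C=1)


def dominant_frequency(features: SpectralFeatures) -> tuple[float, bool]:
    """Peak frequency refined by 3-point parabolic interpolation.

    Returns ``(frequency_hz, ok)``.  ``ok`` is False when no reliable
    interior peak exists: a flat spectrum returns (0.0, False), and a peak
    on an edge bin (DC or Nyquist), where the parabola is undefined, is
    returned unrefined and flagged.  The value always lies in [0, fs/2].
    """
    m = np.asarray(features.magnitudes, dtype=float)
    if len(m) < 3:
        raise DomainError("need at least 3 bins for peak interpolation")
    if np.allclose(m, m[0]):
        return 0.0, False
    k = int(np.argmax(m))
    if not 0 < k < len(m) - 1:
        return float(k * features.bin_hz), False
    a, b, c = m[k - 1], m[k], m[k + 1]
    denom = a - 2 * b + c
    delta = 0.0 if denom == 0 else 0.5 * (a - c) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    f = (k + delta) * features.bin_hz
    return float(np.clip(f, 0.0, (len(m) - 1) * features.bin_hz)), True
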