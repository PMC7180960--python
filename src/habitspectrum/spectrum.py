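"""Behavioral-spectrum encoding of activity sequences.

A habit sequence (ordered activity IDs with durations) is turned into a
periodic real signal built from harmonics of a common fundamental: the n-th
observed activity drives harmonic n+1, carrying the activity's duration in
minutes as amplitude and its integer ID as phase offset.  Harmonic 1 — the
signal mean in a Fourier series — is pinned to amplitude 0 so that the
encoding starts at the second harmonic.  The signal is sampled over one
fundamental period, rectified (negative lobes folded up), and passed through
an FFT; the magnitudes of the first ``n_frames`` bins form the
*behavioral spectrum*, a fixed-length non-negative vector regardless of how
many activities the window contained.

Because rectification and the DFT magnitude both commute with positive
scaling, doubling every duration exactly doubles every spectrum value, while
reordering activities changes the interference pattern between harmonics and
hence the spectral shape — the two properties that make the representation
clusterable into habits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .activity import HabitSequence

__all__ = [
    "Harmonic",
    "HarmonicSet",
    "SignalConfig",
    "BehavioralSpectrum",
    "harmonic_parameters",
    "synthesize_signal",
    "behavioral_spectrum",
    "spectra_matrix",
]


@dataclass(frozen=True)
class Harmonic:
    index: int  # harmonic number, >= 1; multiplies the fundamental frequency
    amplitude: float  # activity duration in minutes (0 for harmonic 1)
    phase: float  # activity ID, in ID units (0 for harmonic 1)


@dataclass(frozen=True)
class HarmonicSet:
    """Harmonics 1..j+1 for a j-activity sequence; harmonic 1 is always (0, 0)."""

    harmonics: tuple[Harmonic, ...]

    def __post_init__(self) -> None:
        if not self.harmonics:
            raise ValueError("harmonic set cannot be empty")
        idx = [h.index for h in self.harmonics]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("harmonic indices must be 1..j+1 with no gaps")
        h1 = self.harmonics[0]
        if h1.amplitude != 0 or h1.phase != 0:
            raise ValueError("harmonic 1 must have amplitude 0 and phase 0")

    def __len__(self) -> int:
        return len(self.harmonics)

    def __getitem__(self, index: int) -> Harmonic:
        """Harmonic by its 1-based harmonic number."""
        return self.harmonics[index - 1]


@dataclass(frozen=True)
class SignalConfig:
    """Sampling and transform settings for spectrum synthesis.

    ``n_samples`` points cover one fundamental period; the one-sided FFT
    magnitude is truncated to ``n_frames`` bins (so ``n_frames`` must not
    exceed ``n_samples // 2``).  ``phase_scale`` converts an activity ID to a
    phase in radians; at the default 1.0, integer IDs up to 25 are all
    distinct modulo 2*pi.  ``mode`` selects the harmonic construction:
    ``"positional"`` (normative; harmonic number = sequence position + 1,
    phase = ID) or ``"id_frequency"`` (the ID used directly as angular
    frequency, kept for comparison — it is order-blind because the sum over
    activities commutes).
    """

    n_samples: int = 400
    n_frames: int = 200
    phase_scale: float = 1.0
    rectify: bool = True
    fft_normalization: str = "per-sample"  # or "none"
    mode: str = "positional"  # or "id_frequency"

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_frames < 1:
            raise ValueError("n_samples and n_frames must be >= 1")
        if self.n_frames > self.n_samples // 2:
            raise ValueError("n_frames must be <= n_samples/2 for a one-sided spectrum")
        if self.fft_normalization not in ("per-sample", "none"):
            raise ValueError("fft_normalization must be 'per-sample' or 'none'")
        if self.mode not in ("positional", "id_frequency"):
            raise ValueError("mode must be 'positional' or 'id_frequency'")


@dataclass(frozen=True)
class BehavioralSpectrum:
    """Fixed-length non-negative FFT-magnitude vector for one sequence."""

    values: np.ndarray
    source: HabitSequence | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("spectrum values must be a 1-D vector")
        if np.any(values < 0):
            raise ValueError("spectrum values must be non-negative")
        object.__setattr__(self, "values", values)

    @property
    def m(self) -> int:
        return self.values.size

    def __len__(self) -> int:
        return self.values.size


def harmonic_parameters(seq: HabitSequence) -> HarmonicSet:
    """Map the n-th activity of ``seq`` to harmonic n+1 = (duration, ID).

    Harmonic 1 is always present with amplitude 0 and phase 0, so an empty
    sequence yields the single silent harmonic.
    """
    harmonics = [Harmonic(1, 0.0, 0.0)]
    for n, (id_, dur) in enumerate(zip(seq.ids, seq.durations), start=1):
        harmonics.append(Harmonic(n + 1, float(dur), float(id_)))
    return HarmonicSet(tuple(harmonics))


def synthesize_signal(
    harmonics: HarmonicSet, config: SignalConfig = SignalConfig()
) -> np.ndarray:
    """Sample the harmonic sum over one fundamental period.

    Returns ``g(t_s) = sum_h amplitude_h * cos(index_h * 2*pi*s/n_samples
    + phase_scale * phase_h)`` for s = 0..n_samples-1.  Harmonic 1 has
    amplitude 0 and contributes nothing.
    """
    s = np.arange(config.n_samples)
    t = 2.0 * np.pi * s / config.n_samples
    signal = np.zeros(config.n_samples)
    for h in harmonics.harmonics:
        if h.amplitude == 0.0:
            continue
        freq = h.phase if config.mode == "id_frequency" else h.index
        phase = 0.0 if config.mode == "id_frequency" else config.phase_scale * h.phase
        signal += h.amplitude * np.cos(freq * t + phase)
    return signal


def behavioral_spectrum(
    seq: HabitSequence, config: SignalConfig = SignalConfig()
) -> BehavioralSpectrum:
    """Encode one sequence: harmonics -> signal -> rectify -> FFT magnitude.

    The output always has ``config.n_frames`` entries, all non-negative;
    with ``fft_normalization="per-sample"`` magnitudes are divided by
    ``n_samples`` so they stay on the scale of the input durations.
    """
    signal = synthesize_signal(harmonic_parameters(seq), config)
    if config.rectify:
        signal = np.abs(signal)
    mag = np.abs(np.fft.fft(signal)[: config.n_frames])
    if config.fft_normalization == "per-sample":
        mag = mag / config.n_samples
    return BehavioralSpectrum(values=mag, source=seq)


def spectra_matrix(
    sequences: Sequence[HabitSequence], config: SignalConfig = SignalConfig()
) -> np.ndarray:
    """Stack the spectra of several sequences into an (n, n_frames) array."""
    return np.vstack([behavioral_spectrum(s, config).values for s in sequences])
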