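"""Domain containers for EEG trials and the rhythm-band vocabulary.

An :class:`EEGSegment` is one labeled trial: a ``(channels, samples)`` array of
microvolt-scale values with its sampling rate.  Class-conditional spectral
content is described by a :class:`RhythmProfile`, a non-negative relative power
per conventional EEG rhythm band (delta through gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["BANDS", "RhythmProfile", "SubjectSpec", "EEGSegment"]

#: Conventional EEG rhythm bands, Hz (lower edge, upper edge).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.5, 8.0),
    "alpha": (8.5, 16.0),
    "beta": (16.5, 32.0),
    "gamma": (32.5, 60.0),
}


@dataclass(frozen=True)
class RhythmProfile:
    """Relative power per rhythm band (unitless, non-negative).

    Bands not mentioned get power 0.  At least one band must have positive
    power.
    """

    band_powers: Mapping[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.band_powers) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown rhythm bands: {sorted(unknown)}")
        full = {name: float(self.band_powers.get(name, 0.0)) for name in BANDS}
        if any(p < 0 for p in full.values()):
            raise ValueError("band powers must be non-negative")
        if not any(p > 0 for p in full.values()):
            raise ValueError("at least one band power must be positive")
        object.__setattr__(self, "band_powers", full)

    def normalized(self) -> dict[str, float]:
        """Band powers rescaled to sum to 1."""
        total = sum(self.band_powers.values())
        return {name: p / total for name, p in self.band_powers.items()}


@dataclass(frozen=True)
class SubjectSpec:
    """Recipe for one synthetic subject's recording session.

    Parameters
    ----------
    class_profiles : mapping from emotion label to RhythmProfile
        One spectral profile per class (two classes for the happy/angry task).
    n_segments : int
        Total trials; classes are balanced, so it must be even.
    noise_sd : float
        RMS amplitude (microvolts) of the 1/f + white background noise.
    fs : float
        Sampling rate in Hz; must satisfy the sampling theorem for the
        highest band edge (gamma tops out at 60 Hz, so fs >= 120).
    duration : float
        Seconds per segment; ``duration * fs`` must be at least 256 samples
        so that a four-level wavelet-packet decomposition is well posed.
    """

    subject_id: str
    class_profiles: Mapping[str, RhythmProfile]
    n_segments: int = 80
    noise_sd: float = 8.0
    fs: float = 1000.0
    duration: float = 2.0
    n_channels: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_profiles) < 2:
            raise ValueError("class_profiles must define at least two classes")
        if self.n_segments < 2 or self.n_segments % 2 != 0:
            raise ValueError(
                f"n_segments must be even and >= 2 for balanced classes, got {self.n_segments}"
            )
        highest_edge = max(hi for _, hi in BANDS.values())
        if self.fs < 2 * highest_edge:
            raise ValueError(
                f"fs={self.fs} violates the sampling theorem: need fs >= {2 * highest_edge}"
            )
        if self.duration * self.fs < 256:
            raise ValueError(
                f"duration*fs = {self.duration * self.fs:.0f} samples; need >= 256"
            )
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        object.__setattr__(self, "class_profiles", dict(self.class_profiles))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def labels(self) -> list[str]:
        return sorted(self.class_profiles)

    def replace(self, **changes) -> "SubjectSpec":
        return replace(self, **changes)


@dataclass
class EEGSegment:
    """One labeled EEG trial: ``data`` is ``(channels, samples)`` in microvolts."""

    data: np.ndarray
    fs: float
    label: str | None = None
    subject_id: str | None = None
    segment_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 2:
            raise ValueError("data must be a (channels, samples) array")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("segment needs at least one channel and one sample")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("segment contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.fs = float(self.fs)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray, fs: float | None = None) -> "EEGSegment":
        """Copy of this segment with new samples (metadata preserved)."""
        return EEGSegment(
            data=data,
            fs=self.fs if fs is None else fs,
            label=self.label,
            subject_id=self.subject_id,
            segment_id=self.segment_id,
        )
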