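"""Synthetic two-class EEG generator.

Stands in for undeposited recordings of a subliminal-emotion experiment: each
trial is a sum of band-limited oscillations (random-phase sinusoids with
jittered frequencies inside each of the five conventional rhythm bands) on top
of 1/f background noise.  The two emotion classes differ only in how power is
distributed across bands — happy trials are alpha-weighted, angry trials
beta-weighted — because band energies are the discriminative quantity the
downstream classifiers consume.

A cohort applies per-subject multiplicative jitter to the band powers
(identically to both classes) to emulate individual differences, and a
``separation`` knob in [0, 1] scales the distance between the two class
profiles; ``separation=0`` makes the classes identically distributed, which is
the null condition used to calibrate classifiers against chance.
"""

from __future__ import annotations

import numpy as np

from .segments import BANDS, EEGSegment, RhythmProfile, SubjectSpec

__all__ = [
    "DEFAULT_CLASS_PROFILES",
    "default_subject_spec",
    "generate_segment",
    "generate_subject",
    "generate_cohort",
]

#: Default class-conditional rhythm profiles.  Both classes share the slow
#: rhythms; happy is alpha-dominant, angry beta-dominant.
DEFAULT_CLASS_PROFILES: dict[str, RhythmProfile] = {
    "happy": RhythmProfile(
        {"delta": 0.30, "theta": 0.20, "alpha": 0.30, "beta": 0.15, "gamma": 0.05}
    ),
    "angry": RhythmProfile(
        {"delta": 0.30, "theta": 0.20, "alpha": 0.15, "beta": 0.30, "gamma": 0.05}
    ),
}

#: Total RMS amplitude of the oscillatory part, microvolts.
SIGNAL_RMS_UV = 20.0

#: Sinusoids synthesized per rhythm band.
SINUSOIDS_PER_BAND = 8

#: Frequencies are drawn this far inside the band edges (Hz) so that spectral
#: leakage stays within the band for finite-length periodograms.
_EDGE_MARGIN_HZ = 0.25

#: Log-SD of the per-subject multiplicative band-power jitter.
SUBJECT_JITTER_SD = 0.15


def default_subject_spec(
    subject_id: str = "S01", seed: int = 0, **overrides
) -> SubjectSpec:
    """A :class:`SubjectSpec` with the package's default study conditions."""
    kwargs = dict(
        subject_id=subject_id,
        class_profiles=DEFAULT_CLASS_PROFILES,
        seed=seed,
    )
    kwargs.update(overrides)
    return SubjectSpec(**kwargs)


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise by spectral shaping of white noise (exponent 1.0)."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^-1/2 => power ~ 1/f
    shaped = np.fft.irfft(spectrum * scale, n)
    rms = np.sqrt(np.mean(shaped**2))
    return shaped / rms if rms > 0 else shaped


def generate_segment(spec: SubjectSpec, label: str, rng_state) -> EEGSegment:
    """Synthesize one labeled trial for ``spec``.

    Each band with positive relative power contributes
    :data:`SINUSOIDS_PER_BAND` sinusoids with frequencies drawn uniformly
    inside the band and uniform random phases, with amplitudes chosen so the
    band's share of oscillatory power matches the class profile.  Deterministic
    given ``rng_state``.
    """
    if label not in spec.class_profiles:
        raise ValueError(f"label {label!r} not in spec.class_profiles {spec.labels}")
    rng = _as_rng(rng_state)
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    powers = spec.class_profiles[label].normalized()

    data = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        signal = np.zeros(n)
        for band, (lo, hi) in BANDS.items():
            p = powers[band]
            if p <= 0:
                continue
            k = SINUSOIDS_PER_BAND
            # evenly spaced centers with +-40% spacing jitter: covers the band
            # while avoiding near-coincident frequencies, whose slowly-beating
            # cross terms would inflate trial-to-trial band-energy variance
            low, high = lo + _EDGE_MARGIN_HZ, hi - _EDGE_MARGIN_HZ
            spacing = (high - low) / k
            centers = low + (np.arange(k) + 0.5) * spacing
            freqs = centers + rng.uniform(-0.4, 0.4, k) * spacing
            phases = rng.uniform(0.0, 2 * np.pi, k)
            band_rms = SIGNAL_RMS_UV * np.sqrt(p)
            amp = band_rms * np.sqrt(2.0 / k)
            signal += amp * np.sin(2 * np.pi * freqs[:, None] * t + phases[:, None]).sum(
                axis=0
            )
        if spec.noise_sd > 0:
            signal = signal + spec.noise_sd * _pink_noise(n, rng)
        data[ch] = signal

    return EEGSegment(
        data=data, fs=spec.fs, label=label, subject_id=spec.subject_id
    )


def generate_subject(spec: SubjectSpec) -> list[EEGSegment]:
    """Balanced, shuffled list of ``spec.n_segments`` trials for one subject."""
    rng = np.random.default_rng(spec.seed)
    per_class = spec.n_segments // len(spec.labels)
    if per_class * len(spec.labels) != spec.n_segments:
        raise ValueError(
            f"n_segments={spec.n_segments} not divisible by {len(spec.labels)} classes"
        )
    segments: list[EEGSegment] = []
    for label in spec.labels:
        for _ in range(per_class):
            segments.append(generate_segment(spec, label, rng))
    order = rng.permutation(len(segments))
    shuffled = [segments[i] for i in order]
    for i, seg in enumerate(shuffled):
        seg.segment_id = f"{spec.subject_id}-{i:03d}"
    return shuffled


def _blend_profiles(
    profiles: dict[str, RhythmProfile], separation: float, jitter: dict[str, float]
) -> dict[str, RhythmProfile]:
    """Shrink class profiles toward their mean by ``1 - separation``, then
    apply the subject's band jitter identically to every class."""
    labels = sorted(profiles)
    normed = {lab: profiles[lab].normalized() for lab in labels}
    mean = {
        band: float(np.mean([normed[lab][band] for lab in labels])) for band in BANDS
    }
    out = {}
    for lab in labels:
        powers = {
            band: (mean[band] + separation * (normed[lab][band] - mean[band]))
            * jitter[band]
            for band in BANDS
        }
        out[lab] = RhythmProfile(powers)
    return out


def generate_cohort(
    n_subjects: int,
    base_spec: SubjectSpec | None = None,
    separation: float = 1.0,
) -> list[list[EEGSegment]]:
    """Simulate ``n_subjects`` independent subjects.

    ``separation`` in [0, 1] scales the distance between the two class
    profiles around their common mean; 0 yields identically distributed
    classes (chance-level task), 1 the full default contrast.  Each subject
    gets its own multiplicative band-power jitter, applied to both classes
    alike, and its own RNG stream derived from ``base_spec.seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not 0.0 <= separation <= 1.0:
        raise ValueError(f"separation must be in [0, 1], got {separation}")
    if base_spec is None:
        base_spec = default_subject_spec()

    root = np.random.SeedSequence(base_spec.seed)
    children = root.spawn(n_subjects)
    cohort = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        jitter = {
            band: float(np.exp(rng.normal(0.0, SUBJECT_JITTER_SD))) for band in BANDS
        }
        profiles = _blend_profiles(dict(base_spec.class_profiles), separation, jitter)
        subject_seed = int(child.generate_state(1)[0] & 0x7FFFFFFF)
        spec = base_spec.replace(
            subject_id=f"S{i + 1:02d}",
            class_profiles=profiles,
            seed=subject_seed,
        )
        cohort.append(generate_subject(spec))
    return cohort
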