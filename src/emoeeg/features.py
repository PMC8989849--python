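"""Feature extraction: the three feature families and the sklearn transformer.

Families (per channel):

- ``mspen`` — one attribute: multi-scale sample entropy (scale-t SampEn) of the
  preprocessed series.
- ``ei`` — four attributes: wavelet-packet energies of the first four
  frequency-ordered terminal nodes, which at 512 Hz / 4 levels cover 0-64 Hz
  and hence the whole conventional EEG rhythm range.
- ``wpen`` — one attribute: Shannon entropy of the full 16-node energy
  distribution.

Attributes are named ``<family>_<channel>_<index>``.  Trials whose sample
entropy is undefined (no template matches) are dropped from feature tables
with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .entropy import SampleEntropyParams, is_undefined, mspen
from .segments import EEGSegment
from .wavelet import (
    WaveletPacketConfig,
    lowpass_filter,
    packet_energies,
    resample_for_wpt,
    wpen,
)

__all__ = [
    "FEATURE_SETS",
    "N_ENERGY_NODES",
    "FeatureVector",
    "UndefinedFeatureError",
    "preprocess",
    "extract_features",
    "extract_feature_table",
    "extract_feature_tables",
    "EEGFeatureExtractor",
]

logger = logging.getLogger(__name__)

FEATURE_SETS = ("mspen", "ei", "wpen")

#: How many frequency-ordered terminal nodes the ``ei`` family keeps; the
#: first four 16-Hz bands cover 0-64 Hz, i.e. delta through gamma.
N_ENERGY_NODES = 4


class UndefinedFeatureError(ValueError):
    """A feature value came out non-finite (e.g. SampEn with no matches)."""


@dataclass
class FeatureVector:
    """Named numeric attributes for one trial."""

    values: dict[str, float]
    label: str | None = None
    subject_id: str | None = None
    segment_id: str | None = None

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise UndefinedFeatureError(
                    f"attribute {name!r} is non-finite for segment "
                    f"{self.segment_id!r}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def preprocess(
    segment: EEGSegment, cutoff_hz: float = 256.0, target_fs: float = 512.0
) -> EEGSegment:
    """Low-pass below ``cutoff_hz`` then resample to ``target_fs``.

    The filter stage is skipped when the cutoff is at or above Nyquist (the
    signal is then already band-limited by acquisition).
    """
    if cutoff_hz < segment.fs / 2:
        segment = lowpass_filter(segment, cutoff_hz)
    return resample_for_wpt(segment, target_fs)


def _family_values(
    segment: EEGSegment,
    feature_set: str,
    wp_config: WaveletPacketConfig,
    entropy_params: SampleEntropyParams,
) -> dict[str, float]:
    values: dict[str, float] = {}
    for ch in range(segment.n_channels):
        series = segment.data[ch]
        if feature_set == "mspen":
            values[f"mspen_{ch}_0"] = mspen(series, entropy_params)
        elif feature_set == "ei":
            spectrum = packet_energies(series, segment.fs, wp_config)
            for i in range(N_ENERGY_NODES):
                values[f"ei_{ch}_{i}"] = float(spectrum.node_energies[i])
        elif feature_set == "wpen":
            spectrum = packet_energies(series, segment.fs, wp_config)
            values[f"wpen_{ch}_0"] = wpen(spectrum)
        else:
            raise ValueError(
                f"unknown feature_set {feature_set!r}; expected one of {FEATURE_SETS}"
            )
    return values


def extract_features(
    segment: EEGSegment,
    feature_set: str,
    wp_config: WaveletPacketConfig | None = None,
    entropy_params: SampleEntropyParams | None = None,
    *,
    cutoff_hz: float = 256.0,
    target_fs: float = 512.0,
    preprocessed: bool = False,
) -> FeatureVector:
    """Feature vector of one family for one segment.

    Raises :class:`UndefinedFeatureError` if any value is non-finite.
    """
    wp_config = wp_config or WaveletPacketConfig()
    entropy_params = entropy_params or SampleEntropyParams()
    if not preprocessed:
        segment = preprocess(segment, cutoff_hz, target_fs)
    values = _family_values(segment, feature_set, wp_config, entropy_params)
    return FeatureVector(
        values=values,
        label=segment.label,
        subject_id=segment.subject_id,
        segment_id=segment.segment_id,
    )


def extract_feature_tables(
    segments: Iterable[EEGSegment],
    feature_sets: Sequence[str] = FEATURE_SETS,
    wp_config: WaveletPacketConfig | None = None,
    entropy_params: SampleEntropyParams | None = None,
    *,
    cutoff_hz: float = 256.0,
    target_fs: float = 512.0,
) -> dict[str, pd.DataFrame]:
    """One feature table per family, sharing a single preprocessing pass.

    Each table has one row per segment: the family's attributes plus
    ``label``, ``subject_id``, ``segment_id``.  Segments with undefined
    entropy values are excluded with a logged warning.
    """
    wp_config = wp_config or WaveletPacketConfig()
    entropy_params = entropy_params or SampleEntropyParams()
    rows: dict[str, list[dict]] = {fs_name: [] for fs_name in feature_sets}
    for segment in segments:
        pre = preprocess(segment, cutoff_hz, target_fs)
        for fs_name in feature_sets:
            try:
                vec = extract_features(
                    pre, fs_name, wp_config, entropy_params, preprocessed=True
                )
            except UndefinedFeatureError as exc:
                logger.warning("dropping segment from %s table: %s", fs_name, exc)
                continue
            row = dict(vec.values)
            row["label"] = vec.label
            row["subject_id"] = vec.subject_id
            row["segment_id"] = vec.segment_id
            rows[fs_name].append(row)
    return {fs_name: pd.DataFrame(rows[fs_name]) for fs_name in feature_sets}


def extract_feature_table(
    segments: Iterable[EEGSegment], feature_set: str, **kwargs
) -> pd.DataFrame:
    """Feature table for a single family (see :func:`extract_feature_tables`)."""
    return extract_feature_tables(segments, (feature_set,), **kwargs)[feature_set]


def split_feature_frame(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Split a feature table into its attribute matrix X and label vector y."""
    meta = [c for c in ("label", "subject_id", "segment_id") if c in table.columns]
    X = table.drop(columns=meta)
    y = table["label"] if "label" in table.columns else pd.Series(dtype=object)
    return X, y


@dataclass
class EEGFeatureExtractor:
    """Stateless sklearn-style transformer: list of segments -> feature table.

    Composes with sklearn pipelines; ``transform`` returns a DataFrame whose
    columns are the family's attributes (metadata columns are excluded so the
    output can feed a classifier directly).
    """

    feature_set: str = "ei"
    wavelet_name: str = "db4"
    levels: int = 4
    cutoff_hz: float = 256.0
    target_fs: float = 512.0
    m: int = 2
    r_factor: float = 0.2
    scale: int = 2

    def get_params(self, deep: bool = True) -> dict:
        return {
            "feature_set": self.feature_set,
            "wavelet_name": self.wavelet_name,
            "levels": self.levels,
            "cutoff_hz": self.cutoff_hz,
            "target_fs": self.target_fs,
            "m": self.m,
            "r_factor": self.r_factor,
            "scale": self.scale,
        }

    def set_params(self, **params) -> "EEGFeatureExtractor":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: Iterable[EEGSegment], y=None) -> "EEGFeatureExtractor":
        self.n_features_in_ = None  # input is a segment list, not a matrix
        return self

    def transform(self, X: Iterable[EEGSegment]) -> pd.DataFrame:
        table = extract_feature_table(
            X,
            self.feature_set,
            wp_config=WaveletPacketConfig(self.wavelet_name, self.levels),
            entropy_params=SampleEntropyParams(self.m, self.r_factor, self.scale),
            cutoff_hz=self.cutoff_hz,
            target_fs=self.target_fs,
        )
        attrs, _ = split_feature_frame(table)
        return attrs

    def fit_transform(self, X: Iterable[EEGSegment], y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
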