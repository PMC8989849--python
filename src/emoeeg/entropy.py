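"""Sample entropy and its multi-scale extension.

SampEn(m, r) is the negative log of the conditional probability that two
subsequences matching for m points (Chebyshev distance <= r, self-matches
excluded) also match at m+1 points.  Multi-scale sample entropy (MSpEn)
coarse-grains the series by non-overlapping window means at scale factor t
before computing SampEn; scale 1 reduces to plain SampEn.

Undefined values (no template matches at either length, or zero tolerance on
a constant series) are reported as ``math.inf`` and flagged by
:func:`is_undefined` rather than raising, so callers can drop the affected
trials with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SampleEntropyParams",
    "coarse_grain",
    "sample_entropy",
    "mspen",
    "is_undefined",
]


@dataclass(frozen=True)
class SampleEntropyParams:
    """Embedding dimension m, tolerance r as a multiple of the series SD, and
    coarse-graining scale factor t."""

    m: int = 2
    r_factor: float = 0.2
    scale: int = 2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if not self.r_factor > 0:
            raise ValueError("r_factor must be > 0")
        if self.scale < 1:
            raise ValueError("scale must be >= 1")


def is_undefined(value: float) -> bool:
    """True for the sentinel returned when SampEn has no defined value."""
    return not math.isfinite(value)


def coarse_grain(series, scale: int) -> np.ndarray:
    """Non-overlapping window means; output length is ``floor(N / scale)``.

    Scale 1 returns the series unchanged (as a float array).
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot coarse-grain an empty series")
    if scale < 1:
        raise ValueError("scale must be >= 1")
    if x.size < scale:
        raise ValueError(f"series length {x.size} < scale {scale}")
    n_windows = x.size // scale
    return x[: n_windows * scale].reshape(n_windows, scale).mean(axis=1)


def _match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Counts (A, B) of template pairs within r at lengths m+1 and m.

    Both counts run over the N-m templates that have room for an (m+1)-length
    extension, i < j, Chebyshev distance.
    """
    n_templates = x.size - m
    close = np.ones((n_templates, n_templates), dtype=bool)
    for k in range(m):
        col = x[k : k + n_templates]
        close &= np.abs(col[:, None] - col[None, :]) <= r
    iu = np.triu_indices(n_templates, k=1)
    b = int(np.count_nonzero(close[iu]))
    col = x[m : m + n_templates]
    close &= np.abs(col[:, None] - col[None, :]) <= r
    a = int(np.count_nonzero(close[iu]))
    return a, b


def sample_entropy(
    series,
    params: SampleEntropyParams | None = None,
    *,
    m: int | None = None,
    r: float | None = None,
    r_factor: float | None = None,
) -> float:
    """SampEn(m, r) = -ln(A/B) with self-matches excluded.

    The tolerance is ``r`` if given absolutely, else ``r_factor * SD`` of the
    series (population SD).  Returns ``inf`` (see :func:`is_undefined`) when
    no pairs match at either template length or when the tolerance is zero.
    """
    if params is None:
        params = SampleEntropyParams()
    m = params.m if m is None else m
    x = np.asarray(series, dtype=float).ravel()
    if x.size <= m + 1:
        raise ValueError(f"series length {x.size} must exceed m+1 = {m + 1}")
    if r is None:
        factor = params.r_factor if r_factor is None else r_factor
        r = factor * float(np.std(x))
    if r <= 0:
        warnings.warn(
            "sample_entropy tolerance is zero (constant series?); value undefined",
            stacklevel=2,
        )
        return math.inf
    a, b = _match_counts(x, m, float(r))
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def mspen(series, params: SampleEntropyParams | None = None) -> float:
    """Multi-scale sample entropy: coarse-grain at ``params.scale`` then SampEn."""
    if params is None:
        params = SampleEntropyParams()
    coarse = coarse_grain(series, params.scale)
    return sample_entropy(coarse, params)
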