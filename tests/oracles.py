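"""Independent brute-force reference implementations used only by tests.

These are deliberately naive (explicit loops, direct formula transcription)
so they cannot share bugs with the vectorized library code they check.
"""

from __future__ import annotations

import math
from itertools import product


def sampen_counts_bruteforce(x, m: int, r: float) -> tuple[int, int]:
    """Template-pair counts (A, B) by explicit O(N^2) enumeration.

    Both counts run over templates i = 0..N-m-1 (room for the m+1 extension),
    pairs i < j, Chebyshev distance, self-matches excluded.
    """
    x = list(map(float, x))
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def sampen_bruteforce(x, m: int, r: float) -> float:
    a, b = sampen_counts_bruteforce(x, m, r)
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def entropy_bits(labels) -> float:
    labels = list(labels)
    n = len(labels)
    out = 0.0
    for c in set(labels):
        p = labels.count(c) / n
        out -= p * math.log2(p)
    return out


def gain_stats(values, labels, threshold):
    """(gain, split_info, gain_ratio or None) by direct formula transcription."""
    values = list(map(float, values))
    labels = list(labels)
    n = len(values)
    left = [lab for v, lab in zip(values, labels) if v <= threshold]
    right = [lab for v, lab in zip(values, labels) if v > threshold]
    part = 0.0
    si = 0.0
    for side in (left, right):
        if side:
            w = len(side) / n
            part += w * entropy_bits(side)
            si -= w * math.log2(w)
    gain = entropy_bits(labels) - part
    ratio = gain / si if si > 1e-12 else None
    return gain, si, ratio


def best_split_bruteforce(X, y, names):
    """Exhaustive argmax of the gain ratio over every (attribute, threshold).

    Same deterministic tie rule as the library: lexicographic attribute name,
    then smaller threshold; returns None when no valid candidate has
    positive gain.
    """
    n_features = len(X[0])
    best = None  # (ratio, name, threshold, gain)
    for j in sorted(range(n_features), key=lambda j: names[j]):
        vals = sorted(set(row[j] for row in X))
        for lo, hi in zip(vals[:-1], vals[1:]):
            thr = (lo + hi) / 2.0
            gain, si, ratio = gain_stats([row[j] for row in X], y, thr)
            if ratio is None:
                continue
            if best is None or ratio > best[0] + 1e-12:
                best = (ratio, names[j], thr, gain)
    if best is None or best[3] <= 1e-12:
        return None
    return best


def majority_vote(predictions):
    """Plain majority with lexicographic tie-break."""
    counts = {}
    for p in predictions:
        counts[p] = counts.get(p, 0) + 1
    top = max(counts.values())
    return min(p for p, c in counts.items() if c == top)


def all_vote_profiles(labels, max_trees):
    """Every prediction profile over ``labels`` with 1..max_trees trees."""
    for t in range(1, max_trees + 1):
        yield from product(labels, repeat=t)
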