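"""Shared fixtures and independent brute-force oracles.

The oracles below restate the visibility criteria and the mutual-information
definition as literal triple/double loops, independent of the package's
implementations, so tests can compare both construction paths against them.
"""

import math

import numpy as np
import pytest


def brute_nvg_edges(y) -> set[tuple[int, int]]:
    """Literal natural-visibility criterion: check every (i, j, k) triple."""
    y = list(map(float, y))
    n = len(y)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if all(y[k] < y[i] + (y[j] - y[i]) * (k - i) / (j - i)
                   for k in range(i + 1, j)):
                edges.add((i, j))
    return edges


def brute_hvg_edges(y) -> set[tuple[int, int]]:
    """Literal horizontal-visibility criterion."""
    y = list(map(float, y))
    n = len(y)
    return {(i, j) for i in range(n) for j in range(i + 1, n)
            if all(y[k] < min(y[i], y[j]) for k in range(i + 1, j))}


def brute_mi(ka, kb) -> float:
    """Plug-in mutual information of two paired integer sequences, in nats."""
    n = len(ka)
    joint: dict[tuple[int, int], float] = {}
    pa: dict[int, float] = {}
    pb: dict[int, float] = {}
    for a, b in zip(ka, kb):
        joint[(a, b)] = joint.get((a, b), 0) + 1 / n
        pa[a] = pa.get(a, 0) + 1 / n
        pb[b] = pb.get(b, 0) + 1 / n
    return sum(p * math.log(p / (pa[a] * pb[b]))
               for (a, b), p in joint.items())


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_series_suite(rng, n, count):
    """Mixed random/structured series of length n for equivalence testing."""
    out = []
    for _ in range(count):
        kind = rng.integers(5)
        if kind == 0:
            y = rng.standard_normal(n)
        elif kind == 1:
            y = rng.random(n)
        elif kind == 2:
            y = np.full(n, float(rng.standard_normal()))
        elif kind == 3:
            y = np.sort(rng.standard_normal(n))
            if rng.random() < 0.5:
                y = y[::-1].copy()
        else:  # heavy ties
            y = rng.integers(0, max(2, n // 4), size=n).astype(float)
        out.append(y)
    return out
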