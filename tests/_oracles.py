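"""Independent brute-force oracles, written from the feature definitions using
only the standard library (plus cmath for the direct DFT). They deliberately
share no code with the package."""
from __future__ import annotations

import cmath
import math
import statistics


def mean(v):
    return sum(v) / len(v)


def median(v):
    return statistics.median(v)


def variance_pop(v):
    m = mean(v)
    return sum((x - m) ** 2 for x in v) / len(v)


def std_pop(v):
    return math.sqrt(variance_pop(v))


def quantile_linear(v, q):
    """Linear-interpolation quantile on the sorted sample."""
    s = sorted(v)
    h = (len(s) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    if lo == hi:
        return s[lo]
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def iqr(v):
    return quantile_linear(v, 0.75) - quantile_linear(v, 0.25)


def mad(v):
    m = median(v)
    return median([abs(x - m) for x in v])


def kurtosis_excess(v):
    m = mean(v)
    m2 = sum((x - m) ** 2 for x in v) / len(v)
    if m2 == 0:
        return 0.0
    m4 = sum((x - m) ** 4 for x in v) / len(v)
    return m4 / m2**2 - 3.0


def entropy_time(v, bins=10):
    vmin, vmax = min(v), max(v)
    if vmin == vmax:
        return 0.0
    width = (vmax - vmin) / bins
    counts = [0] * bins
    for x in v:
        i = min(int((x - vmin) / width), bins - 1)
        counts[i] += 1
    n = len(v)
    return -sum((c / n) * math.log(c / n) for c in counts if c)


def pearson(x, y):
    mx, my = mean(x), mean(y)
    sx, sy = std_pop(x), std_pop(y)
    if sx == 0 or sy == 0:
        return 0.0
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / len(x)
    return cov / (sx * sy)


def gravity_lowpass(rows, alpha=0.9):
    g = list(rows[0])
    for row in rows[1:]:
        g = [alpha * gi + (1 - alpha) * ai for gi, ai in zip(g, row)]
    return g


def orientation(g):
    norm = math.sqrt(sum(c * c for c in g))
    if norm == 0:
        return [0.0, 0.0, 0.0]
    return [math.acos(max(-1.0, min(1.0, c / norm))) for c in g]


def dft(v):
    """Direct O(N^2) discrete Fourier transform."""
    n = len(v)
    return [
        sum(v[t] * cmath.exp(-2j * math.pi * k * t / n) for t in range(n))
        for k in range(n)
    ]


def spectral_features(v):
    """(mean_dc, energy, entropy_freq) from the direct DFT."""
    X = dft(v)
    n = len(v)
    mean_dc = X[0].real / n
    powers = [abs(x) ** 2 for x in X[1:]]
    total = sum(powers)
    energy = total / n
    if total == 0:
        ent = 0.0
    else:
        ent = -sum((p / total) * math.log(p / total) for p in powers if p > 0)
    return mean_dc, energy, ent


def box_overlap_raster(hand, obj, scale=1):
    """Pixel-rasterization overlap oracle on integer-coordinate boxes.

    Counts unit pixels (half-open intervals) inside the object box that also
    fall inside the hand box; returns count / object pixel count.
    """
    hx0, hy0, hx1, hy1 = (int(c * scale) for c in hand)
    ox0, oy0, ox1, oy1 = (int(c * scale) for c in obj)
    inside = 0
    total = 0
    for x in range(ox0, ox1):
        for y in range(oy0, oy1):
            total += 1
            if hx0 <= x < hx1 and hy0 <= y < hy1:
                inside += 1
    return inside / total if total else 0.0
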