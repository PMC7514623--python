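"""Independent brute-force oracles for the window feature definitions.

Every function here is written as plain loops over the signal, independent
of the package's vectorised implementations, and is used to pin the feature
values on short vectors.
"""

from __future__ import annotations

import cmath
import math


def jerk(x, fs):
    if len(x) < 2:
        return 0.0
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1)) / (len(x) - 1) * fs


def peak_to_peak(x):
    return max(x) - min(x)


def mean_amplitude(x):
    return sum(abs(v) for v in x) / len(x)


def sd_amplitude(x):
    m = sum(x) / len(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / len(x))


def skewness(x):
    m = sum(x) / len(x)
    m2 = sum((v - m) ** 2 for v in x) / len(x)
    if m2 == 0:
        return 0.0
    m3 = sum((v - m) ** 3 for v in x) / len(x)
    return m3 / m2**1.5


def kurtosis(x):
    m = sum(x) / len(x)
    m2 = sum((v - m) ** 2 for v in x) / len(x)
    if m2 == 0:
        return 0.0
    m4 = sum((v - m) ** 4 for v in x) / len(x)
    return m4 / m2**2


def sample_entropy(x, m=2, r=None):
    n = len(x)
    if n <= m + 1:
        return 0.0
    sd = sd_amplitude(x)
    if sd == 0:
        return 0.0
    if r is None:
        r = 0.2 * sd

    def count(length):
        c = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + k] - x[j + k]) for k in range(length)) <= r:
                    c += 1
        return c

    b = count(m)
    if b == 0:
        return 0.0
    a = count(m + 1)
    if a == 0:
        return -math.log(2.0 / ((n - m - 1) * (n - m)))
    return -math.log(a / b)


def shannon_entropy(x, bins=16):
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    width = (hi - lo) / bins
    counts = [0] * bins
    for v in x:
        idx = min(int((v - lo) / width), bins - 1)
        counts[idx] += 1
    h = 0.0
    for c in counts:
        if c:
            p = c / len(x)
            h -= p * math.log(p)
    return h


def gini_index(x):
    a = sorted(abs(v) for v in x)
    n = len(a)
    total = sum(a)
    if total == 0:
        return 0.0
    return sum((2 * (i + 1) - n - 1) * a[i] for i in range(n)) / (n * total)


def gini_pairwise(x):
    """Equivalent pairwise-difference form: sum|xi-xj| / (2 n^2 mean|x|)."""
    a = [abs(v) for v in x]
    n = len(a)
    mean = sum(a) / n
    if mean == 0:
        return 0.0
    s = sum(abs(a[i] - a[j]) for i in range(n) for j in range(n))
    return s / (2 * n * n * mean)


def _acf(x):
    n = len(x)
    m = sum(x) / n
    denom = sum((v - m) ** 2 for v in x)
    if denom == 0:
        return None
    return [
        sum((x[t] - m) * (x[t + lag] - m) for t in range(n - lag)) / denom
        for lag in range(n)
    ]


def autocorrelation_features(x):
    rho = _acf(x)
    if rho is None:
        return 1.0, 0.0, 0.0
    total = sum(rho[1:])
    for lag in range(1, len(rho) - 1):
        if rho[lag] > rho[lag - 1] and rho[lag] > rho[lag + 1]:
            return rho[lag], float(lag), total
    return 0.0, 0.0, total


def cross_correlation(a, b):
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    va = sum((v - ma) ** 2 for v in a)
    vb = sum((v - mb) ** 2 for v in b)
    if va == 0 or vb == 0:
        return 0.0
    best = 0.0
    for lag in range(-(n - 1), n):
        s = 0.0
        for t in range(n):
            u = t + lag
            if 0 <= u < n:
                s += (a[t] - ma) * (b[u] - mb)
        rho = s / math.sqrt(va * vb)
        if abs(rho) > abs(best):
            best = rho
    return best


def periodogram(x, fs):
    """One-sided periodogram of the mean-removed signal.

    Scaled so the bin sum equals the signal's mean square (boxcar window):
    P_k = |X_k|^2 / n^2, doubled for interior bins.
    """
    n = len(x)
    m = sum(x) / n
    xc = [v - m for v in x]
    n_bins = n // 2 + 1
    freqs, power = [], []
    for k in range(n_bins):
        c = sum(xc[t] * cmath.exp(-2j * math.pi * k * t / n) for t in range(n))
        p = abs(c) ** 2 / n**2
        if 0 < k and not (n % 2 == 0 and k == n // 2):
            p *= 2
        freqs.append(k * fs / n)
        power.append(p)
    return freqs, power


def band_power(x, fs, lo, hi):
    f, p = periodogram(x, fs)
    return sum(pv for fv, pv in zip(f, p) if lo <= fv <= hi)


def spectral_entropy(x, fs):
    _, p = periodogram(x, fs)
    total = sum(p)
    if total == 0:
        return 0.0
    h = 0.0
    for pv in p:
        if pv > 0:
            q = pv / total
            h -= q * math.log(q)
    return h


def spectral_peaks(x, fs):
    f, p = periodogram(x, fs)
    if len(p) < 3 or sum(p) == 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    floor = max(p) * 1e-12  # shared convention: rounding-floor bins are zero
    p = [0.0 if v < floor else v for v in p]
    peaks = [
        i for i in range(1, len(p) - 1) if p[i] > p[i - 1] and p[i] > p[i + 1]
    ]
    if not peaks:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    order = sorted(peaks, key=lambda i: (-p[i], f[i]))
    f1, p1 = f[order[0]], p[order[0]]
    f2, p2 = (f[order[1]], p[order[1]]) if len(order) > 1 else (0.0, 0.0)
    pct = 100.0 * sum(1 for i in peaks if f[i] > 4.0) / len(peaks)
    return f1, p1, f2, p2, pct
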