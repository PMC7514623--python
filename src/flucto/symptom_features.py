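"""Symptom-based signal features from 5-s gyroscope windows.

Each window of a tri-axial angular-velocity signal is summarised by 66
features chosen to reflect the two cardinal parkinsonian motor signs:

* bradykinesia — reduced speed/amplitude of movement: jerk, amplitude
  statistics, signal regularity (entropies, Gini index) and 1–4 Hz power;
* tremor — 4–6 Hz oscillation: autocorrelation peak structure, inter-axis
  cross-correlation, 4–6 Hz power and spectral peak locations;
* shared descriptors: autocorrelation sum, broadband 0.5–15 Hz power,
  spectral entropy and the dominant spectral peak.

All features except the three cross-correlations are computed per axis
(X, Y, Z), giving 21 × 3 + 3 = 66 values.  Spectral quantities come from the
one-sided periodogram of the mean-removed axis, scaled so that the sum over
all bins equals the signal's mean-square (Parseval); "power in [lo, hi] Hz"
is the sum of periodogram bins with lo ≤ f ≤ hi.

Degenerate inputs never produce NaN: a constant axis has zero entropies,
zero Gini index and zero correlation-based features by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "FEATURE_REGISTRY",
    "FeatureEntry",
    "feature_names",
    "extract_symptom_features",
    "average_jerk",
    "band_power",
    "sample_entropy",
    "shannon_entropy",
    "gini_index",
    "skewness",
    "kurtosis",
    "autocorrelation_features",
    "spectral_peaks",
    "spectral_entropy",
    "cross_correlation",
]


@dataclass(frozen=True)
class FeatureEntry:
    """One registry row: a named feature, its domain, and axis handling."""

    name: str
    symptom: str  # "bradykinesia" | "tremor" | "shared"
    domain: str  # "time" | "spectral"
    per_axis: bool


#: Canonical feature order: bradykinesia block, tremor block, shared block.
#: Per-axis entries contribute three values (X, Y, Z) in sequence.
FEATURE_REGISTRY: tuple[FeatureEntry, ...] = (
    FeatureEntry("average_jerk", "bradykinesia", "time", True),
    FeatureEntry("peak_to_peak", "bradykinesia", "time", True),
    FeatureEntry("mean_amplitude", "bradykinesia", "time", True),
    FeatureEntry("sd_amplitude", "bradykinesia", "time", True),
    FeatureEntry("skewness", "bradykinesia", "time", True),
    FeatureEntry("kurtosis", "bradykinesia", "time", True),
    FeatureEntry("sample_entropy", "bradykinesia", "time", True),
    FeatureEntry("shannon_entropy", "bradykinesia", "time", True),
    FeatureEntry("gini_index", "bradykinesia", "time", True),
    FeatureEntry("power_1_4hz", "bradykinesia", "spectral", True),
    FeatureEntry("acorr_first_peak_amp", "tremor", "time", True),
    FeatureEntry("acorr_first_peak_lag", "tremor", "time", True),
    FeatureEntry("cross_corr_xy", "tremor", "time", False),
    FeatureEntry("cross_corr_xz", "tremor", "time", False),
    FeatureEntry("cross_corr_yz", "tremor", "time", False),
    FeatureEntry("power_4_6hz", "tremor", "spectral", True),
    FeatureEntry("pct_peaks_gt4hz", "tremor", "spectral", True),
    FeatureEntry("spec_peak2_freq", "tremor", "spectral", True),
    FeatureEntry("spec_peak2_power", "tremor", "spectral", True),
    FeatureEntry("acorr_sum", "shared", "time", True),
    FeatureEntry("power_0p5_15hz", "shared", "spectral", True),
    FeatureEntry("spectral_entropy", "shared", "spectral", True),
    FeatureEntry("spec_peak1_freq", "shared", "spectral", True),
    FeatureEntry("spec_peak1_power", "shared", "spectral", True),
)

_AXES = ("x", "y", "z")

N_FEATURES = sum(3 if e.per_axis else 1 for e in FEATURE_REGISTRY)
assert N_FEATURES == 66


def feature_names(prefix: str = "") -> list[str]:
    """The 66 column names in canonical registry order."""
    names = []
    for entry in FEATURE_REGISTRY:
        if entry.per_axis:
            names.extend(f"{prefix}{entry.name}_{ax}" for ax in _AXES)
        else:
            names.append(f"{prefix}{entry.name}")
    return names


# ---------------------------------------------------------------------------
# Time-domain features


def average_jerk(x: np.ndarray, fs: float) -> float:
    """Mean absolute first difference scaled by fs (deg/s^2)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return 0.0
    return float(np.mean(np.abs(np.diff(x))) * fs)


def skewness(x: np.ndarray) -> float:
    """Third standardised moment (population form); 0 for a constant signal."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((x - m) ** 3) / m2**1.5)


def kurtosis(x: np.ndarray) -> float:
    """Fourth standardised moment (population form, not excess); 0 if constant."""
    x = np.asarray(x, dtype=float)
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean((x - m) ** 4) / m2**2)


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy −ln(A/B) with template length m and tolerance r.

    Matching uses the Chebyshev distance over the n−m templates common to
    both lengths; self-matches are excluded.  r defaults to 0.2·SD of the
    signal.  A constant signal (or one with no length-m matches) returns 0;
    when no length-(m+1) match exists the value is capped at
    −ln(2 / ((n−m−1)(n−m))), the largest resolvable entropy.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n <= m + 1:
        return 0.0
    sd = float(np.std(x))
    if r is None:
        r = 0.2 * sd
    if sd == 0:
        return 0.0
    close = np.abs(x[:, None] - x[None, :]) <= r
    limit = n - m

    # Chebyshev template matches as conjunctions of shifted point matches;
    # the matrix is symmetric with an all-True diagonal (self-matches).
    match = close[:limit, :limit].copy()
    for k in range(1, m):
        match &= close[k : k + limit, k : k + limit]
    b = (int(match.sum()) - limit) // 2
    if b == 0:
        return 0.0
    match &= close[m : m + limit, m : m + limit]
    a = (int(match.sum()) - limit) // 2
    if a == 0:
        return float(-math.log(2.0 / ((n - m - 1) * (n - m))))
    return float(-math.log(a / b))


def shannon_entropy(x: np.ndarray, bins: int = 16) -> float:
    """Shannon entropy (nats) of the binned amplitude histogram; 0 if constant."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    p = counts[counts > 0] / len(x)
    return float(-np.sum(p * np.log(p)))


def gini_index(x: np.ndarray) -> float:
    """Gini coefficient of the absolute-amplitude distribution, in [0, 1).

    With |x| sorted ascending, G = Σ_i (2i − n − 1)|x|_(i) / (n Σ|x|);
    an all-zero signal returns 0 by convention.
    """
    a = np.sort(np.abs(np.asarray(x, dtype=float)))
    n = len(a)
    if n == 0:
        raise ValueError("gini_index requires a non-empty signal")
    total = a.sum()
    if total == 0:
        return 0.0
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * a) / (n * total))


def _normalized_acf(x: np.ndarray) -> np.ndarray | None:
    """Biased normalized autocorrelation, rho[0] = 1; None if zero variance."""
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0:
        return None
    full = sps.fftconvolve(xc, xc[::-1])
    return full[len(x) - 1 :] / denom


def autocorrelation_features(x: np.ndarray) -> tuple[float, float, float]:
    """(first peak amplitude, first peak lag in samples, autocorrelation sum).

    The first peak is the first strict local maximum of the normalized
    autocorrelation at lag > 0; the sum runs over all positive lags.  A
    constant signal yields (1, 0, 0); a peak-free autocorrelation yields
    amplitude and lag 0.
    """
    rho = _normalized_acf(x)
    if rho is None:
        return 1.0, 0.0, 0.0
    total = float(rho[1:].sum())
    if len(rho) < 3:
        return 0.0, 0.0, total
    interior = rho[1:-1]
    is_peak = (interior > rho[:-2]) & (interior > rho[2:])
    idx = np.flatnonzero(is_peak)
    if len(idx) == 0:
        return 0.0, 0.0, total
    lag = int(idx[0] + 1)
    return float(rho[lag]), float(lag), total


def cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Extremal normalized cross-correlation over all lags, in [−1, 1].

    The value at the lag maximising |rho| is returned with its sign, so an
    axis against its negation gives −1.  A constant axis returns 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ValueError("axes must have equal length")
    ac = a - a.mean()
    bc = b - b.mean()
    va = float(np.dot(ac, ac))
    vb = float(np.dot(bc, bc))
    if va == 0 or vb == 0:
        return 0.0
    rho = sps.fftconvolve(ac, bc[::-1]) / math.sqrt(va * vb)
    return float(rho[np.argmax(np.abs(rho))])


# ---------------------------------------------------------------------------
# Spectral features


def _periodogram(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram scaled so the bin sum equals the mean square."""
    f, p = sps.periodogram(x, fs=fs, detrend="constant", scaling="spectrum")
    return f, p


def _band_power_from(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    return float(p[(f >= lo) & (f <= hi)].sum())


def band_power(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    """Signal power in [lo, hi] Hz: periodogram bin sum over the band."""
    if not 0 <= lo < hi:
        raise ValueError("require 0 <= lo < hi")
    if hi > fs / 2:
        raise ValueError(f"band edge {hi} Hz beyond Nyquist {fs / 2} Hz")
    f, p = _periodogram(np.asarray(x, dtype=float), fs)
    return _band_power_from(f, p, lo, hi)


def _spectral_entropy_from(p: np.ndarray) -> float:
    total = p.sum()
    if total == 0:
        return 0.0
    q = p[p > 0] / total
    return float(-np.sum(q * np.log(q)))


def spectral_entropy(x: np.ndarray, fs: float) -> float:
    """Shannon entropy (nats) of the normalized periodogram; 0 if flat-zero."""
    _, p = _periodogram(np.asarray(x, dtype=float), fs)
    return _spectral_entropy_from(p)


def _spectral_peaks_from(
    f: np.ndarray, p: np.ndarray
) -> tuple[float, float, float, float, float]:
    if len(p) < 3 or p.sum() == 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    # bins at the FFT rounding floor are numerically zero, not structure
    p = np.where(p < p.max() * 1e-12, 0.0, p)
    interior = p[1:-1]
    is_peak = (interior > p[:-2]) & (interior > p[2:])
    idx = np.flatnonzero(is_peak) + 1
    if len(idx) == 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    order = sorted(idx, key=lambda i: (-p[i], f[i]))
    f1, p1 = float(f[order[0]]), float(p[order[0]])
    if len(order) >= 2:
        f2, p2 = float(f[order[1]]), float(p[order[1]])
    else:
        f2, p2 = 0.0, 0.0
    pct = 100.0 * float(np.count_nonzero(f[idx] > 4.0)) / len(idx)
    return f1, p1, f2, p2, pct


def spectral_peaks(
    x: np.ndarray, fs: float
) -> tuple[float, float, float, float, float]:
    """Dominant periodogram peaks: (f1, p1, f2, p2, pct of peaks above 4 Hz).

    Peaks are strict local maxima of the raw one-sided periodogram (bins
    below 1e-12 of the maximum are treated as zero — FFT rounding noise,
    not structure), sorted by descending power with frequency ties broken
    toward the lower frequency.  Fewer than two peaks report the second as
    (0, 0); a zero signal reports all five values as 0.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("spectral_peaks requires at least two samples")
    f, p = _periodogram(x, fs)
    return _spectral_peaks_from(f, p)


# ---------------------------------------------------------------------------
# Window-level extraction


def _axis_features(x: np.ndarray, fs: float) -> dict[str, float]:
    f, p = _periodogram(x, fs)  # shared by all spectral features of the axis
    f1, p1, f2, p2, pct = _spectral_peaks_from(f, p)
    peak_amp, peak_lag, acf_sum = autocorrelation_features(x)
    return {
        "average_jerk": average_jerk(x, fs),
        "peak_to_peak": float(np.ptp(x)),
        "mean_amplitude": float(np.mean(np.abs(x))),
        "sd_amplitude": float(np.std(x)),
        "skewness": skewness(x),
        "kurtosis": kurtosis(x),
        "sample_entropy": sample_entropy(x),
        "shannon_entropy": shannon_entropy(x),
        "gini_index": gini_index(x),
        "power_1_4hz": _band_power_from(f, p, 1.0, 4.0),
        "acorr_first_peak_amp": peak_amp,
        "acorr_first_peak_lag": peak_lag,
        "power_4_6hz": _band_power_from(f, p, 4.0, 6.0),
        "pct_peaks_gt4hz": pct,
        "spec_peak2_freq": f2,
        "spec_peak2_power": p2,
        "acorr_sum": acf_sum,
        "power_0p5_15hz": _band_power_from(f, p, 0.5, min(15.0, fs / 2)),
        "spectral_entropy": _spectral_entropy_from(p),
        "spec_peak1_freq": f1,
        "spec_peak1_power": p1,
    }


def extract_symptom_features(window: np.ndarray, fs: float) -> np.ndarray:
    """The 66-element symptom feature vector of one tri-axial window.

    window has shape (n_samples, 3); values are returned in canonical
    registry order, per-axis features as consecutive (X, Y, Z) triples.
    Raises on NaN input; degenerate (constant) axes follow the conventions
    documented on the individual feature functions.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[1] != 3:
        raise ValueError("window must have shape (n_samples, 3)")
    if not np.all(np.isfinite(w)):
        raise ValueError("window contains NaN or infinite samples")
    per_axis = [_axis_features(w[:, i], fs) for i in range(3)]
    cross = {
        "cross_corr_xy": cross_correlation(w[:, 0], w[:, 1]),
        "cross_corr_xz": cross_correlation(w[:, 0], w[:, 2]),
        "cross_corr_yz": cross_correlation(w[:, 1], w[:, 2]),
    }
    values: list[float] = []
    for entry in FEATURE_REGISTRY:
        if entry.per_axis:
            values.extend(ax[entry.name] for ax in per_axis)
        else:
            values.append(cross[entry.name])
    out = np.asarray(values, dtype=float)
    assert out.shape == (N_FEATURES,)
    return out


def extract_feature_matrix(windows: np.ndarray, fs: float) -> np.ndarray:
    """Stack ``extract_symptom_features`` over (n_windows, n_samples, 3)."""
    if len(windows) == 0:
        return np.empty((0, N_FEATURES))
    return np.stack([extract_symptom_features(w, fs) for w in windows])
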