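import numpy as np
import pytest
from scipy.stats import spearmanr

import _oracles as oracle
from flucto.symptom_features import (
    FEATURE_REGISTRY,
    autocorrelation_features,
    average_jerk,
    band_power,
    cross_correlation,
    extract_symptom_features,
    feature_names,
    gini_index,
    kurtosis,
    sample_entropy,
    shannon_entropy,
    skewness,
    spectral_entropy,
    spectral_peaks,
)
from flucto.synthetic_data import SeverityProfile, simulate_recording
from flucto.io_preproc import PreprocConfig, segment_windows

FS = 64.0


def _sine(freq, n=320, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


# ---------------------------------------------------------------------------
# brute-force oracle agreement on short vectors

VEC10 = [0.3, -1.2, 2.5, 0.0, 1.1, -0.7, 3.3, -2.4, 0.9, 1.6]

ORACLE_CASES = [
    ("average_jerk", lambda x: average_jerk(x, 10.0), lambda x: oracle.jerk(x, 10.0)),
    ("peak_to_peak", lambda x: np.ptp(np.asarray(x)), oracle.peak_to_peak),
    ("mean_amplitude", lambda x: np.mean(np.abs(x)), oracle.mean_amplitude),
    ("sd_amplitude", lambda x: np.std(x), oracle.sd_amplitude),
    ("skewness", skewness, oracle.skewness),
    ("kurtosis", kurtosis, oracle.kurtosis),
    ("sample_entropy", sample_entropy, oracle.sample_entropy),
    ("shannon_entropy", shannon_entropy, oracle.shannon_entropy),
    ("gini_index", gini_index, oracle.gini_index),
    (
        "power_1_4hz",
        lambda x: band_power(x, 10.0, 1, 4),
        lambda x: oracle.band_power(x, 10.0, 1, 4),
    ),
    (
        "spectral_entropy",
        lambda x: spectral_entropy(x, 10.0),
        lambda x: oracle.spectral_entropy(x, 10.0),
    ),
]


@pytest.mark.parametrize("name,impl,brute", ORACLE_CASES, ids=[c[0] for c in ORACLE_CASES])
def test_feature_matches_brute_force_oracle(name, impl, brute):
    """Every scalar feature agrees with an independent loop implementation."""
    got = impl(np.asarray(VEC10))
    want = brute(VEC10)
    assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


def test_autocorrelation_matches_oracle():
    got = autocorrelation_features(np.asarray(VEC10))
    want = oracle.autocorrelation_features(VEC10)
    assert got == pytest.approx(want, rel=1e-9)


def test_cross_correlation_matches_oracle():
    a = VEC10
    b = [1.0, 0.4, -0.3, 2.2, -1.0, 0.8, 0.1, -0.6, 1.9, -2.2]
    assert cross_correlation(np.asarray(a), np.asarray(b)) == pytest.approx(
        oracle.cross_correlation(a, b), rel=1e-9
    )


def test_spectral_peaks_match_oracle():
    got = spectral_peaks(np.asarray(VEC10), 10.0)
    want = oracle.spectral_peaks(VEC10, 10.0)
    assert got == pytest.approx(want, rel=1e-9)


def test_gini_closed_forms():
    n = 8
    one_hot = np.zeros(n)
    one_hot[3] = 5.0
    assert gini_index(one_hot) == pytest.approx((n - 1) / n, rel=1e-12)
    assert gini_index(np.full(6, 2.2)) == 0.0
    x = [1.0, 2.0, 3.0, 4.0]
    assert gini_index(np.asarray(x)) == pytest.approx(oracle.gini_pairwise(x), rel=1e-12)


def test_sample_entropy_cases():
    pattern = np.array([1, 2, 3, 1, 2, 3, 1, 2, 3, 1.0])
    assert sample_entropy(pattern, m=2, r=0.2 * np.std(pattern)) == pytest.approx(
        oracle.sample_entropy(list(pattern)), abs=1e-12
    )
    assert sample_entropy(np.full(50, 3.0)) == 0.0
    rng = np.random.default_rng(7)
    noise = rng.uniform(-1, 1, 320)
    assert sample_entropy(noise) > sample_entropy(_sine(5))


# ---------------------------------------------------------------------------
# band power and spectral behaviour on constructed signals


def test_band_power_of_pure_sine():
    x = _sine(5)
    # unit sine mean square = 1/2, concentrated in the 4-6 Hz band
    assert band_power(x, FS, 4, 6) == pytest.approx(0.5, rel=0.05)
    total = band_power(x, FS, 0.5, 15)
    assert band_power(x, FS, 1, 4) < 0.01 * total

    assert band_power(np.zeros(320), FS, 4, 6) == 0.0
    with pytest.raises(ValueError):
        band_power(x, FS, 4, 40)


def test_spectral_peaks_on_mixtures():
    f1, p1, *_ = spectral_peaks(_sine(5), FS)
    assert abs(f1 - 5.0) <= FS / 320  # within one bin
    mix = _sine(2, amp=1.0) + _sine(6, amp=0.4)
    f1, p1, f2, p2, pct = spectral_peaks(mix, FS)
    assert f1 == pytest.approx(2.0, abs=0.2)
    assert f2 == pytest.approx(6.0, abs=0.2)
    assert spectral_peaks(np.zeros(320), FS) == (0, 0, 0, 0, 0)


def test_autocorrelation_of_periodic_and_noise_signals():
    amp, lag, _ = autocorrelation_features(_sine(5))
    assert abs(lag - FS / 5) <= 1  # period of 12.8 samples
    assert amp > 0.9
    rng = np.random.default_rng(42)
    amps = [autocorrelation_features(rng.standard_normal(320))[0] for _ in range(20)]
    assert max(amps) < 0.3


def test_cross_correlation_limits():
    x = _sine(3) + 0.1 * np.random.default_rng(0).standard_normal(320)
    assert cross_correlation(x, x) == pytest.approx(1.0, abs=1e-9)
    assert cross_correlation(x, -x) == pytest.approx(-1.0, abs=1e-9)
    rng = np.random.default_rng(5)
    vals = [
        cross_correlation(rng.standard_normal(320), rng.standard_normal(320))
        for _ in range(10)
    ]
    assert max(abs(v) for v in vals) < 0.4
    assert cross_correlation(np.full(320, 2.0), x) == 0.0


# ---------------------------------------------------------------------------
# window-level extraction


def test_vector_has_66_values_in_registry_order():
    assert len(feature_names()) == 66
    rng = np.random.default_rng(0)
    vec = extract_symptom_features(rng.standard_normal((320, 3)), FS)
    assert vec.shape == (66,)
    assert np.all(np.isfinite(vec))


def test_all_zero_window_conventions():
    vec = extract_symptom_features(np.zeros((320, 3)), FS)
    names = feature_names()
    # every amplitude, power, entropy and correlation feature collapses to 0
    nonzero = {n for n, v in zip(names, vec) if v != 0}
    assert nonzero == {
        "acorr_first_peak_amp_x",
        "acorr_first_peak_amp_y",
        "acorr_first_peak_amp_z",
    }  # constant signal: peak amplitude 1 at lag 0 by convention


def test_nan_window_rejected():
    w = np.zeros((320, 3))
    w[5, 1] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        extract_symptom_features(w, FS)


def test_pure_sine_window_band_concentration():
    w = np.zeros((320, 3))
    w[:, 0] = _sine(5)
    vec = dict(zip(feature_names(), extract_symptom_features(w, FS)))
    assert vec["power_4_6hz_x"] == pytest.approx(
        vec["power_0p5_15hz_x"], rel=0.10
    )
    assert vec["pct_peaks_gt4hz_x"] == 100.0


def test_scaling_behaviour_by_feature_class():
    rng = np.random.default_rng(2)
    w = rng.standard_normal((320, 3))
    c = 3.7
    names = feature_names()
    base = dict(zip(names, extract_symptom_features(w, FS)))
    scaled = dict(zip(names, extract_symptom_features(c * w, FS)))
    linear = ("average_jerk", "peak_to_peak", "mean_amplitude", "sd_amplitude")
    quadratic = ("power_1_4hz", "power_4_6hz", "power_0p5_15hz", "spec_peak1_power",
                 "spec_peak2_power")
    invariant = ("skewness", "kurtosis", "sample_entropy", "shannon_entropy",
                 "gini_index", "spectral_entropy", "acorr_first_peak_amp",
                 "acorr_first_peak_lag", "acorr_sum", "pct_peaks_gt4hz",
                 "spec_peak1_freq", "spec_peak2_freq", "cross_corr")
    for name in names:
        stem = name.rsplit("_", 1)[0] if name[-2:] in ("_x", "_y", "_z") else name
        if stem in linear:
            assert scaled[name] == pytest.approx(c * base[name], rel=1e-9), name
        elif stem in quadratic:
            assert scaled[name] == pytest.approx(c**2 * base[name], rel=1e-9), name
        else:
            assert any(stem.startswith(p) for p in invariant), name
            assert scaled[name] == pytest.approx(base[name], rel=1e-9, abs=1e-12), name


def test_tremor_band_power_tracks_simulator_severity():
    """4-6 Hz power rises strictly with the simulated tremor level."""
    cfg = PreprocConfig()
    levels = np.linspace(0.1, 1.0, 10)
    means = []
    for level in levels:
        rec = simulate_recording(
            SeverityProfile(tremor_level=float(level), brady_level=0.5),
            duration_s=40.0,
            seed=99,
        )
        windows = segment_windows(rec, cfg)
        powers = [
            sum(band_power(w[:, ax], rec.fs, 4, 6) for ax in range(3))
            for w in windows
        ]
        means.append(np.mean(powers))
    rho, _ = spearmanr(levels, means)
    assert rho > 0.9
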