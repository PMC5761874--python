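"""Feature extraction: dual-implementation oracle, closed forms, invariances.

The oracle below recomputes every feature from scratch — explicit loops over
hand-rolled segment periodograms — sharing no code with the package
implementation.
"""

import numpy as np
import pytest
from scipy.signal import get_window

import dynconn as dc
from dynconn.features import (FeatureSettings, SegmentSpectra, Spectrum,
                              spectral_moment_features,
                              spectral_shape_features, temporal_features,
                              welch_spectrum)


# ---------------------------------------------------------------------------
# independent oracle
# ---------------------------------------------------------------------------

def oracle_segment_psds(x, fs, nperseg, noverlap, window="hann"):
    w = get_window(window, nperseg)
    step = nperseg - noverlap
    nseg = (len(x) - nperseg) // step + 1
    scale = 1.0 / (fs * np.sum(w ** 2))
    psds = []
    for s in range(nseg):
        seg = x[s * step:s * step + nperseg]
        spec = np.abs(np.fft.rfft(w * seg)) ** 2 * scale
        spec[1:-1] *= 2.0  # one-sided, even nperseg: DC and Nyquist not doubled
        psds.append(spec)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, np.array(psds)


def oracle_features(rho, tr=2.0, c=0.001, nperseg=None, band=(0.01, 0.08),
                    n_bins=8):
    rho = np.asarray(rho, float)
    T = len(rho)
    fs = 1.0 / tr
    nperseg = nperseg or min(T, 128)
    noverlap = int(nperseg * 0.5)

    mv = sum(rho) / T
    var = sum((r - mv) ** 2 for r in rho) / (T - 1)
    pav = sum(1 for r in rho if r < 0) / T
    zc = sum(1 for t in range(T - 1)
             if rho[t] * rho[t + 1] < 0 and abs(rho[t + 1] - rho[t]) >= c) / (T - 1)

    f, psds = oracle_segment_psds(rho, fs, nperseg, noverlap)
    psd = psds.mean(axis=0)
    m = np.sqrt(psd)

    tot = m.sum()
    sco = sum(fk * mk for fk, mk in zip(f, m)) / tot
    spr = sum((fk - sco) ** 2 * mk for fk, mk in zip(f, m)) / tot
    skw = sum((fk - sco) ** 3 * mk for fk, mk in zip(f, m)) / tot / spr ** 1.5
    kurt = sum((fk - sco) ** 4 * mk for fk, mk in zip(f, m)) / tot / spr ** 2 - 3

    acc, smed, sro = 0.0, None, None
    for fk, mk in zip(f, m):
        acc += mk
        if smed is None and acc >= 0.5 * tot:
            smed = fk
        if sro is None and acc >= 0.85 * tot:
            sro = fk

    crest = m.max() / m.mean()
    flat = 0.0 if np.any(m <= 0) else np.exp(np.mean(np.log(m))) / m.mean()
    p = psd / psd.sum()
    pse = -sum(pk * np.log2(pk) for pk in p if pk > 0)
    slope = np.polyfit(f, m, 1)[0]

    seg_m = np.sqrt(psds)
    seg_n = seg_m / seg_m.sum(axis=1, keepdims=True)
    flux = np.mean([np.sqrt(np.sum((seg_n[s + 1] - seg_n[s]) ** 2))
                    for s in range(len(seg_n) - 1)])

    xd = rho - rho.mean()
    fd, dpsds = oracle_segment_psds(xd, fs, nperseg, noverlap)
    dpsd = dpsds.mean(axis=0)
    nyq = fd[-1]
    edges = np.linspace(0.0, nyq, n_bins + 1)
    best, best_mean = None, -np.inf
    for b in range(n_bins):
        sel = (fd > edges[b]) & (fd <= edges[b + 1])
        if sel.any() and dpsd[sel].mean() > best_mean:
            best_mean, best = dpsd[sel].mean(), b
    sel = (fd > edges[best]) & (fd <= edges[best + 1])
    peak = fd[sel][np.argmax(dpsd[sel])]

    inband = (fd >= band[0]) & (fd <= band[1]) & (fd > 0)
    alff = np.mean(np.sqrt(dpsd[inband]))

    return dict(MV=mv, VAR=var, ZC=zc, PAV=pav, SCO=sco, SPR=spr, SKW=skw,
                KURT=kurt, SMED=smed, SRO=sro, PEAK=peak, CREST=crest,
                FLUX=flux, SLOPE=slope, FLAT=flat, PSE=pse, ALFF_dFC=alff)


def test_feature_vector_matches_oracle(random_dfc_series):
    for dfc in random_dfc_series:
        got = dc.extract_feature_vector(dfc)
        want = oracle_features(dfc.rho, tr=dfc.tr)
        for name in dc.FEATURE_NAMES:
            assert got[name] == pytest.approx(want[name], abs=1e-10), name


# ---------------------------------------------------------------------------
# temporal features
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rho,c,expected", [
    ([0.5, 0.5, 0.5, 0.5], 0.001, (0.5, 0.0, 0.0, 0.0)),
    ([0.4, -0.4, 0.4, -0.4], 0.001, (0.0, None, 0.5, 1.0)),
    # |delta| = 0.0008 < c suppresses both crossings
    ([0.0004, -0.0004, 0.0004], 0.001, (None, None, 1 / 3, 0.0)),
])
def test_temporal_examples(rho, c, expected):
    mv, var, pav, zc = temporal_features(np.array(rho), c=c)
    e_mv, e_var, e_pav, e_zc = expected
    if e_mv is not None:
        assert mv == pytest.approx(e_mv)
    if e_var is not None:
        assert var == pytest.approx(e_var)
    assert pav == pytest.approx(e_pav)
    assert zc == pytest.approx(e_zc)


def test_temporal_too_short():
    with pytest.raises(ValueError):
        temporal_features(np.array([0.5]))


# ---------------------------------------------------------------------------
# Welch spectrum
# ---------------------------------------------------------------------------

def test_parseval_white_noise(rng):
    x = rng.standard_normal(1024)
    spec, _ = welch_spectrum(x, tr=2.0)
    assert spec.psd.sum() * spec.df == pytest.approx(np.var(x), rel=0.10)


def test_sinusoid_peak_bin():
    tr, T = 2.0, 512
    t = np.arange(T) * tr
    x = 0.5 * np.sin(2 * np.pi * 0.10 * t)
    spec, _ = welch_spectrum(x - x.mean(), tr=tr)
    fmax = spec.freqs[np.argmax(spec.psd)]
    assert abs(fmax - 0.10) <= spec.df


def test_constant_series_zero_spectrum():
    spec, _ = welch_spectrum(np.full(300, 0.7) - 0.7, tr=2.0)
    assert np.allclose(spec.psd, 0.0)


def test_too_short_for_segment():
    with pytest.raises(ValueError, match="nperseg"):
        welch_spectrum(np.zeros(50), tr=2.0, settings=FeatureSettings(nperseg=128))


# ---------------------------------------------------------------------------
# closed-form spectral cases
# ---------------------------------------------------------------------------

def _delta_spectrum(K=64, f_peak=0.125, nyq=0.25):
    freqs = np.linspace(0, nyq, K)
    psd = np.zeros(K)
    psd[np.argmin(np.abs(freqs - f_peak))] = 4.0
    return Spectrum(freqs=freqs, psd=psd, df=freqs[1] - freqs[0])


def test_delta_spectrum_moments():
    spec = _delta_spectrum()
    f_peak = spec.freqs[np.argmax(spec.psd)]
    sco, spr, skw, kurt, smed, sro = spectral_moment_features(spec)
    assert sco == pytest.approx(f_peak)
    assert spr == 0.0
    assert np.isnan(skw) and np.isnan(kurt)
    assert smed == sro == pytest.approx(f_peak)


def test_flat_spectrum_moments():
    K = 64
    freqs = np.linspace(0, 0.25, K)
    spec = Spectrum(freqs=freqs, psd=np.ones(K), df=freqs[1] - freqs[0])
    sco, spr, skw, kurt, smed, sro = spectral_moment_features(spec)
    assert sco == pytest.approx(freqs.mean())
    assert skw == pytest.approx(0.0, abs=1e-10)
    # discrete uniform on K points: excess kurtosis -(6/5)(K^2+1)/(K^2-1)
    assert kurt == pytest.approx(-(6 / 5) * (K ** 2 + 1) / (K ** 2 - 1))


def test_flat_spectrum_rolloff_bin():
    K = 100
    freqs = np.linspace(0, 0.25, K)
    spec = Spectrum(freqs=freqs, psd=np.ones(K), df=freqs[1] - freqs[0])
    *_, smed, sro = spectral_moment_features(spec)
    assert smed == pytest.approx(freqs[49])   # cumulative first reaches 50%
    assert sro == pytest.approx(freqs[84])    # cumulative first reaches 85%


def _shape(spec, seg_psd):
    segs = SegmentSpectra(freqs=spec.freqs, psd=seg_psd)
    return spectral_shape_features(spec, segs, spec,
                                   FeatureSettings(band=(0.01, 0.08)))


def test_flat_spectrum_shape():
    K = 64
    freqs = np.linspace(0, 0.25, K)
    spec = Spectrum(freqs=freqs, psd=np.ones(K), df=freqs[1] - freqs[0])
    seg_psd = np.ones((K, 3))
    peak, crest, flux, slope, flat, pse, alff = _shape(spec, seg_psd)
    assert crest == pytest.approx(1.0)
    assert flat == pytest.approx(1.0)
    assert pse == pytest.approx(np.log2(K))
    assert slope == pytest.approx(0.0, abs=1e-10)
    assert flux == pytest.approx(0.0)


def test_delta_spectrum_shape():
    spec = _delta_spectrum(K=64)
    seg_psd = np.tile(spec.psd[:, None], (1, 3))
    peak, crest, flux, slope, flat, pse, alff = _shape(spec, seg_psd)
    assert crest == pytest.approx(64.0)
    assert flat == 0.0
    assert pse == pytest.approx(0.0)


def test_alff_band_selectivity():
    # in-band (0.05 Hz) sinusoidal dFC carries far more ALFF than out-of-band
    tr, T = 2.0, 450
    t = np.arange(T) * tr
    alffs = {}
    for f0 in (0.05, 0.20):
        rho = 0.5 * np.sin(2 * np.pi * f0 * t)
        alffs[f0] = dc.extract_feature_vector(rho, tr=tr)["ALFF_dFC"]
    assert alffs[0.05] > 5 * alffs[0.20]


# ---------------------------------------------------------------------------
# full-vector contract and invariances
# ---------------------------------------------------------------------------

def test_constant_trajectory_vector():
    fv = dc.extract_feature_vector(np.full(300, 0.3), tr=2.0)
    assert fv["MV"] == pytest.approx(0.3)
    assert fv["VAR"] == 0.0
    assert fv["PAV"] == fv["ZC"] == 0.0
    # pure DC spectrum up to Hann-window leakage into the first bin
    assert 0 <= fv["SCO"] < 2 * 0.5 / 128
    assert fv["SMED"] == 0.0
    assert fv["PSE"] <= 1.0
    assert fv["ALFF_dFC"] == 0.0     # demeaned signal is identically zero
    assert np.isnan(fv["PEAK"])


def test_vector_is_complete(random_dfc_series):
    fv = dc.extract_feature_vector(random_dfc_series[0])
    assert set(fv.values) == set(dc.FEATURE_NAMES)
    assert len(dc.FEATURE_NAMES) == 17
    assert fv.provenance["c"] == 0.001
    assert fv.provenance["band"] == (0.01, 0.08)


def test_bounds(random_dfc_series):
    for dfc in random_dfc_series[:8]:
        fv = dc.extract_feature_vector(dfc)
        nyq = dfc.nyquist
        K = len(welch_spectrum(dfc)[0].freqs)
        assert 0 <= fv["PAV"] <= 1 and 0 <= fv["ZC"] <= 1
        assert 0 <= fv["FLAT"] <= 1
        assert 0 <= fv["PSE"] <= np.log2(K) + 1e-9
        assert 1 <= fv["CREST"] <= K
        for name in ("SCO", "SMED", "SRO", "PEAK"):
            assert 0 <= fv[name] <= nyq + 1e-12


@pytest.mark.parametrize("a", [0.5, 2.0])
def test_amplitude_equivariance(random_dfc_series, a):
    base = dc.DFCSeries(random_dfc_series[1].rho * 0.4, tr=2.0)
    scaled = dc.DFCSeries(base.rho * a, tr=2.0)
    f0 = dc.extract_feature_vector(base)
    f1 = dc.extract_feature_vector(scaled)
    invariant = ("PAV", "ZC", "SCO", "SPR", "SKW", "KURT", "SMED", "SRO",
                 "FLAT", "PSE", "CREST", "PEAK")
    for name in invariant:
        assert f1[name] == pytest.approx(f0[name], rel=1e-8), name
    assert f1["MV"] == pytest.approx(a * f0["MV"], rel=1e-8)
    assert f1["VAR"] == pytest.approx(a ** 2 * f0["VAR"], rel=1e-8)
    assert f1["ALFF_dFC"] == pytest.approx(a * f0["ALFF_dFC"], rel=1e-8)
    assert f1["SLOPE"] == pytest.approx(a * f0["SLOPE"], rel=1e-8)


def test_time_reversal_invariance(rng):
    # boxcar taper + segment-aligned length make reversal an exact segment
    # permutation, isolating the mathematical invariance of the features
    settings = dict(nperseg=128, window="boxcar")
    x = np.tanh(np.cumsum(rng.standard_normal(384)) * 0.05)
    f0 = dc.extract_feature_vector(x, tr=2.0,
                                   settings=FeatureSettings(**settings))
    f1 = dc.extract_feature_vector(x[::-1].copy(), tr=2.0,
                                   settings=FeatureSettings(**settings))
    for name in set(dc.FEATURE_NAMES) - {"FLUX"}:
        assert f1[name] == pytest.approx(f0[name], rel=1e-9, abs=1e-12), name


def test_transformer_shape(random_dfc_series):
    df = dc.DFCFeatureExtractor().fit_transform(random_dfc_series[:3])
    assert df.shape == (3, 17)
    assert list(df.columns) == list(dc.FEATURE_NAMES)
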