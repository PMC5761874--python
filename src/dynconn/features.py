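"""Temporal and spectral features of a dFC trajectory.

A dFC trajectory rho_t is summarized by 17 features: four time-domain
statistics (mean MV, unbiased variance VAR, proportion of anticorrelated
volumes PAV, thresholded zero-crossing rate ZC) and thirteen spectral
descriptors of its Welch power spectral density (centroid SCO, spread SPR,
skewness SKW, excess kurtosis KURT, median frequency SMED, 85% rolloff SRO,
dominant frequency PEAK, crest CREST, flux FLUX, slope SLOPE, flatness FLAT,
power spectral entropy PSE, and the low-frequency fluctuation amplitude
ALFF_dFC over 0.01-0.08 Hz).

Conventions (all configurable through :class:`FeatureSettings`):

* Welch uses a Hann taper, segment length min(T, 128), 50% overlap,
  one-sided spectrum, no detrending (so the DC bin carries the mean).
* Moment/ordering features (SCO...SRO) and CREST/FLAT/SLOPE weight by the
  *magnitude* spectrum M_k = sqrt(PSD_k); PSE uses normalized power;
  ALFF_dFC averages sqrt(PSD) in band.
* PEAK and ALFF_dFC are computed on the mean-removed trajectory with the DC
  bin excluded; all other spectral features retain the DC bin.
* FLUX is the mean L2 distance between unit-sum-normalized magnitude
  spectra of consecutive Welch segments (amplitude-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .series import DFCSeries

FEATURE_NAMES = (
    "MV", "VAR", "ZC", "PAV", "SCO", "SPR", "SKW", "KURT", "SMED", "SRO",
    "PEAK", "CREST", "FLUX", "SLOPE", "FLAT", "PSE", "ALFF_dFC",
)


@dataclass(frozen=True)
class FeatureSettings:
    """All tunable knobs of the feature extractor."""

    c: float = 0.001                 # zero-crossing noise threshold
    nperseg: int | None = None       # Welch segment length; None -> min(T, 128)
    overlap: float = 0.5             # Welch segment overlap fraction
    window: str = "hann"
    band: tuple = (0.01, 0.08)       # ALFF band, Hz
    n_peak_bins: int = 8             # equal-width bins for the PEAK search


@dataclass
class Spectrum:
    """One-sided Welch spectrum: frequencies (Hz), PSD, and bin width."""

    freqs: np.ndarray
    psd: np.ndarray
    df: float

    def __post_init__(self):
        if len(self.freqs) != len(self.psd):
            raise ValueError("freqs and psd lengths differ")
        if np.any(self.psd < -1e-15):
            raise ValueError("negative spectral power")
        self.psd = np.maximum(self.psd, 0.0)

    @property
    def mags(self) -> np.ndarray:
        """Magnitude spectrum M_k = sqrt(PSD_k)."""
        return np.sqrt(self.psd)


@dataclass
class SegmentSpectra:
    """Per-segment PSDs (S segments x K bins) on the Spectrum's grid."""

    freqs: np.ndarray
    psd: np.ndarray  # (K, S)

    @property
    def n_segments(self) -> int:
        return self.psd.shape[1]


# ---------------------------------------------------------------------------
# temporal features
# ---------------------------------------------------------------------------

def temporal_features(rho, c: float = 0.001):
    """MV, VAR, PAV, ZC of a dFC trajectory.

    ZC counts consecutive pairs that change sign AND jump by at least ``c``
    (suppressing crossings driven by low-level noise), normalized by T-1.
    """
    rho = rho.rho if isinstance(rho, DFCSeries) else np.asarray(rho, dtype=float)
    if c < 0:
        raise ValueError("c must be >= 0")
    T = len(rho)
    if T < 2:
        raise ValueError("need at least 2 time points for VAR and ZC")
    mv = float(np.mean(rho))
    var = float(np.sum((rho - mv) ** 2) / (T - 1))
    pav = float(np.mean(rho < 0))
    d = np.abs(np.diff(rho))
    crossings = (rho[1:] * rho[:-1] < 0) & (d >= c)
    zc = float(np.sum(crossings) / (T - 1))
    return mv, var, pav, zc


# ---------------------------------------------------------------------------
# Welch spectrum
# ---------------------------------------------------------------------------

def welch_spectrum(rho, tr: float | None = None,
                   settings: FeatureSettings = FeatureSettings(),
                   demean: bool = False):
    """Welch PSD of the trajectory plus the per-segment spectra.

    The averaged spectrum is the mean of the per-segment modified
    periodograms (scipy's Welch with mean averaging); density scaling makes
    sum(PSD) * df approximate the signal variance (Parseval).  With
    ``demean=True`` the global mean is removed first (used for PEAK and
    ALFF_dFC); segments are never individually detrended.
    """
    if isinstance(rho, DFCSeries):
        tr = rho.tr if tr is None else tr
        x = rho.rho
    else:
        if tr is None:
            raise ValueError("tr required when rho is a bare array")
        x = np.asarray(rho, dtype=float)
    nperseg = settings.nperseg or min(len(x), 128)
    if len(x) < nperseg:
        raise ValueError(
            f"series length {len(x)} shorter than one Welch segment "
            f"({nperseg}); choose a smaller nperseg")
    if demean:
        x = x - x.mean()
    fs = 1.0 / tr
    noverlap = int(nperseg * settings.overlap)
    freqs, t_seg, sxx = signal.spectrogram(
        x, fs=fs, window=settings.window, nperseg=nperseg, noverlap=noverlap,
        detrend=False, scaling="density", mode="psd")
    psd = sxx.mean(axis=1)
    df = freqs[1] - freqs[0] if len(freqs) > 1 else fs / nperseg
    return Spectrum(freqs=freqs, psd=psd, df=float(df)), \
        SegmentSpectra(freqs=freqs, psd=sxx)


# ---------------------------------------------------------------------------
# spectral moment / ordering features
# ---------------------------------------------------------------------------

def spectral_moment_features(spec: Spectrum):
    """SCO, SPR, SKW, KURT, SMED, SRO from magnitude-weighted moments.

    SPR is the second central moment (Hz^2); KURT is excess kurtosis.  With
    zero spread, SKW and KURT are undefined and returned as NaN.  SMED / SRO
    are the first frequencies where the cumulative magnitude reaches 50% /
    85% of the total.
    """
    m = spec.mags
    total = m.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum: moment features undefined")
    w = m / total
    f = spec.freqs
    sco = float(np.sum(f * w))
    spr = float(np.sum((f - sco) ** 2 * w))
    if spr > 0:
        skw = float(np.sum((f - sco) ** 3 * w) / spr ** 1.5)
        kurt = float(np.sum((f - sco) ** 4 * w) / spr ** 2 - 3.0)
    else:
        skw = kurt = float("nan")
    cum = np.cumsum(m)
    smed = float(f[np.argmax(cum >= 0.5 * total)])
    sro = float(f[np.argmax(cum >= 0.85 * total)])
    return sco, spr, skw, kurt, smed, sro


# ---------------------------------------------------------------------------
# spectral shape features
# ---------------------------------------------------------------------------

def _peak_frequency(spec: Spectrum, n_bins: int):
    """Frequency of the max-PSD point inside the highest-average-power bin.

    The (0, Nyquist] axis is divided into ``n_bins`` equal-width bins; the
    bin with the largest average power wins, and PEAK is the frequency of
    the largest PSD value inside it.  NaN if the spectrum carries no power.
    """
    mask = spec.freqs > 0  # DC excluded
    f, p = spec.freqs[mask], spec.psd[mask]
    if len(f) == 0 or p.sum() <= 0:
        return float("nan")
    nyq = spec.freqs[-1]
    edges = np.linspace(0.0, nyq, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, f, side="left") - 1, 0, n_bins - 1)
    means = np.full(n_bins, -np.inf)
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            means[b] = p[sel].mean()
    best = int(np.argmax(means))
    sel = idx == best
    return float(f[sel][np.argmax(p[sel])])


def spectral_shape_features(spec: Spectrum, segs: SegmentSpectra,
                            demeaned: Spectrum,
                            settings: FeatureSettings = FeatureSettings()):
    """PEAK, CREST, FLUX, SLOPE, FLAT, PSE, ALFF_dFC.

    ``spec``/``segs`` come from the mean-retained trajectory; ``demeaned``
    from the mean-removed pass (PEAK and ALFF_dFC only).
    """
    m = spec.mags
    if m.sum() <= 0:
        raise ValueError("all-zero spectrum: shape features undefined")
    amean = m.mean()
    crest = float(m.max() / amean)
    # geometric mean is zero whenever any magnitude is zero
    flat = 0.0 if np.any(m <= 0) else float(stats.gmean(m) / amean)
    ptot = spec.psd.sum()
    pk = spec.psd[spec.psd > 0] / ptot
    pse = float(-np.sum(pk * np.log2(pk)))
    slope = float(stats.linregress(spec.freqs, m).slope)

    if segs.n_segments < 2:
        raise ValueError("FLUX needs at least 2 Welch segments")
    seg_m = np.sqrt(segs.psd)  # (K, S) magnitude spectra
    sums = seg_m.sum(axis=0, keepdims=True)
    sums[sums == 0] = 1.0
    seg_n = seg_m / sums
    flux = float(np.mean(np.linalg.norm(np.diff(seg_n, axis=1), axis=0)))

    peak = _peak_frequency(demeaned, settings.n_peak_bins)

    lo, hi = settings.band
    nyq = spec.freqs[-1]
    if not (0 < lo < hi <= nyq + 1e-12):
        raise ValueError(f"band {settings.band} outside (0, {nyq}]")
    inband = (demeaned.freqs >= lo) & (demeaned.freqs <= hi) & (demeaned.freqs > 0)
    if not inband.any():
        raise ValueError(f"no frequency bins inside band {settings.band}")
    alff = float(np.mean(np.sqrt(demeaned.psd[inband])))
    return peak, crest, flux, slope, flat, pse, alff


# ---------------------------------------------------------------------------
# full vector
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """The 17 dFC features plus the settings that produced them."""

    values: dict
    provenance: dict

    def __post_init__(self):
        missing = set(FEATURE_NAMES) - set(self.values)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")

    def __getitem__(self, name):
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in FEATURE_NAMES})


def extract_feature_vector(rho, tr: float | None = None,
                           settings: FeatureSettings = FeatureSettings()
                           ) -> FeatureVector:
    """All 17 features of one dFC trajectory.

    Two Welch passes are run: mean-retained for the moment/shape features
    and mean-removed for PEAK and ALFF_dFC.  Feature-level degeneracies
    (e.g. a constant trajectory giving an all-zero demeaned spectrum) yield
    NaN for the affected features without aborting the vector.
    """
    dfc = rho if isinstance(rho, DFCSeries) else DFCSeries(np.asarray(rho, float),
                                                           tr=tr or 2.0)
    mv, var, pav, zc = temporal_features(dfc, c=settings.c)
    spec, segs = welch_spectrum(dfc, settings=settings, demean=False)
    dspec, _ = welch_spectrum(dfc, settings=settings, demean=True)

    nan6 = (float("nan"),) * 6
    try:
        sco, spr, skw, kurt, smed, sro = spectral_moment_features(spec)
    except ValueError:
        sco, spr, skw, kurt, smed, sro = nan6
    try:
        peak, crest, flux, slope, flat, pse, alff = spectral_shape_features(
            spec, segs, dspec, settings)
    except ValueError:
        peak = crest = flux = slope = flat = pse = float("nan")
        # ALFF of an identically-zero demeaned spectrum is genuinely 0
        alff = 0.0 if dspec.psd.sum() == 0 else float("nan")

    values = dict(MV=mv, VAR=var, ZC=zc, PAV=pav, SCO=sco, SPR=spr, SKW=skw,
                  KURT=kurt, SMED=smed, SRO=sro, PEAK=peak, CREST=crest,
                  FLUX=flux, SLOPE=slope, FLAT=flat, PSE=pse, ALFF_dFC=alff)
    prov = dict(asdict(settings), tr=dfc.tr, T=dfc.T,
                nperseg=settings.nperseg or min(dfc.T, 128))
    return FeatureVector(values=values, provenance=prov)


class DFCFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sklearn transformer mapping dFC trajectories to 17-feature rows.

    ``transform`` accepts a 2-D array (n_subjects, T), a list of 1-D
    arrays, or a list of :class:`DFCSeries`, and returns a DataFrame with
    one column per feature.
    """

    def __init__(self, tr=2.0, c=0.001, nperseg=None, overlap=0.5,
                 window="hann", band=(0.01, 0.08), n_peak_bins=8):
        self.tr = tr
        self.c = c
        self.nperseg = nperseg
        self.overlap = overlap
        self.window = window
        self.band = band
        self.n_peak_bins = n_peak_bins

    def _settings(self) -> FeatureSettings:
        return FeatureSettings(c=self.c, nperseg=self.nperseg,
                               overlap=self.overlap, window=self.window,
                               band=tuple(self.band),
                               n_peak_bins=self.n_peak_bins)

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        settings = self._settings()
        rows = []
        for item in X:
            fv = extract_feature_vector(item, tr=self.tr, settings=settings)
            rows.append(fv.as_series())
        return pd.DataFrame(rows).reset_index(drop=True)
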