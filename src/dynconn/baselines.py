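"""Comparison estimators: static FC and sliding-window dFC.

Static functional connectivity (sFC) is the full-length Pearson correlation
between the two region time courses.  The sliding-window estimator computes
the Pearson correlation within overlapping rectangular windows (default 80 s
with 50% overlap) and summarizes the window series by its mean (SW_Mean) and
unbiased variance (SW_Var).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .series import BivariateSeries


@dataclass(frozen=True)
class SlidingWindowSettings:
    window_seconds: float = 80.0
    overlap_fraction: float = 0.5
    tr: float = 2.0

    def __post_init__(self):
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap fraction must be in [0, 1)")
        if self.window_samples < 3:
            raise ValueError("window must span at least 3 samples")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_seconds / self.tr))

    @property
    def hop_samples(self) -> int:
        # nearest-integer hop, at least one sample
        return max(1, int(round(self.window_samples * (1 - self.overlap_fraction))))


def _values(series) -> np.ndarray:
    v = series.values if isinstance(series, BivariateSeries) else np.asarray(series, float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("expected a (T, 2) series")
    return v


def static_fc(series) -> float:
    """Full-length Pearson correlation between the two columns."""
    v = _values(series)
    if (v.std(axis=0) == 0).any():
        raise ValueError("constant column: static FC undefined")
    return float(np.corrcoef(v.T)[0, 1])


def sliding_window_dfc(series, settings: SlidingWindowSettings | None = None):
    """Windowed Pearson correlations plus their mean and unbiased variance.

    Windows are rectangular with hop = window * (1 - overlap) samples;
    trailing partial windows are discarded.  Returns
    ``(window_corrs, sw_mean, sw_var)``.
    """
    v = _values(series)
    if settings is None:
        tr = series.tr if isinstance(series, BivariateSeries) else 2.0
        settings = SlidingWindowSettings(tr=tr)
    w, hop = settings.window_samples, settings.hop_samples
    T = len(v)
    if T < w:
        raise ValueError(f"series length {T} shorter than window ({w} samples)")
    n_win = (T - w) // hop + 1
    corrs = np.empty(n_win)
    for i in range(n_win):
        seg = v[i * hop:i * hop + w]
        if (seg.std(axis=0) == 0).any():
            raise ValueError(f"constant column inside window {i}")
        corrs[i] = np.corrcoef(seg.T)[0, 1]
    sw_mean = float(np.mean(corrs))
    sw_var = float(np.var(corrs, ddof=1)) if n_win > 1 else 0.0
    return corrs, sw_mean, sw_var


class SlidingWindowDFC(TransformerMixin, BaseEstimator):
    """Transformer producing sFC / SW_Mean / SW_Var rows per subject."""

    def __init__(self, window_seconds=80.0, overlap_fraction=0.5, tr=2.0):
        self.window_seconds = window_seconds
        self.overlap_fraction = overlap_fraction
        self.tr = tr

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> pd.DataFrame:
        settings = SlidingWindowSettings(self.window_seconds,
                                         self.overlap_fraction, self.tr)
        rows = []
        for series in X:
            _, sw_mean, sw_var = sliding_window_dfc(series, settings)
            rows.append({"sFC": static_fc(series),
                         "SW_Mean": sw_mean, "SW_Var": sw_var})
        return pd.DataFrame(rows)
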