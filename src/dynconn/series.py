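"""Core data containers for bivariate BOLD-like series and dFC trajectories."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Minimum length needed to identify an ARMA(2,2)+GARCH(1,1) fit.
MIN_LENGTH = 50


@dataclass
class BivariateSeries:
    """A pair of aligned region/network time courses.

    Parameters
    ----------
    values : ndarray of shape (T, 2)
        The two time courses, one column per region.
    tr : float
        Sampling interval (repetition time) in seconds.
    labels : tuple of str
        Names of the two regions/networks.
    """

    values: np.ndarray
    tr: float = 2.0
    labels: tuple = ("roi1", "roi2")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError(f"values must be (T, 2), got {self.values.shape}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if np.isnan(self.values).any():
            rows = np.unique(np.nonzero(np.isnan(self.values))[0])
            raise ValueError(f"missing values at rows {rows.tolist()}")
        if len(self.values) < MIN_LENGTH:
            raise ValueError(
                f"need at least {MIN_LENGTH} time points, got {len(self.values)}"
            )
        if (self.values.std(axis=0) == 0).any():
            raise ValueError("both columns must have nonzero sample variance")

    @property
    def T(self) -> int:
        return len(self.values)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.T) * self.tr


@dataclass
class DFCSeries:
    """A dynamic functional connectivity trajectory rho_t in [-1, 1]."""

    rho: np.ndarray
    tr: float = 2.0

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        if self.rho.ndim != 1:
            raise ValueError("rho must be one-dimensional")
        if np.nanmax(np.abs(self.rho)) > 1 + 1e-9:
            raise ValueError("correlation trajectory must lie in [-1, 1]")

    @property
    def T(self) -> int:
        return len(self.rho)

    @property
    def nyquist(self) -> float:
        return 0.5 / self.tr
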