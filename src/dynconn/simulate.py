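"""Synthetic bivariate series with known time-varying correlation.

Each simulated series follows an ARMA(2,2) mean with GARCH(1,1) conditional
variance.  The cross-correlation of the innovations either evolves through a
DCC recursion (``dcc`` mode) or is prescribed deterministically (``constant``,
``sinusoid``, ``step``), in which case the correlated shocks are built by a
Cholesky factor of the 2x2 correlation at each time point so the ground truth
is exact.  Cohorts of two labelled groups with prescribed shifts in selected
dFC features support end-to-end power/null studies without any real data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .series import BivariateSeries

#: Samples discarded before recording, so initial-condition transients
#: do not contaminate fixtures.
BURN_IN = 200


# ---------------------------------------------------------------------------
# correlation modes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstantCorrelation:
    rho: float = 0.0

    def trajectory(self, idx: np.ndarray, tr: float) -> np.ndarray:
        return np.full(len(idx), float(self.rho))


@dataclass(frozen=True)
class SinusoidCorrelation:
    """rho(t) = offset + amplitude * sin(2 pi f t), f in Hz.

    ``t = 0`` is the first *recorded* sample (burn-in samples get t < 0).
    """

    amplitude: float = 0.5
    frequency: float = 0.02
    offset: float = 0.0

    def trajectory(self, idx: np.ndarray, tr: float) -> np.ndarray:
        t = idx * tr
        return self.offset + self.amplitude * np.sin(2 * np.pi * self.frequency * t)


@dataclass(frozen=True)
class StepCorrelation:
    """Piecewise-constant correlation with one change point, given as a
    sample index into the recorded window."""

    rho_before: float = 0.0
    rho_after: float = 0.5
    change_point: int = 0

    def trajectory(self, idx: np.ndarray, tr: float) -> np.ndarray:
        return np.where(idx < self.change_point, float(self.rho_before),
                        float(self.rho_after))


@dataclass(frozen=True)
class DCCCorrelation:
    """Correlation driven by the DCC(1,1) recursion with loading (eta1, eta2)."""

    eta1: float = 0.05
    eta2: float = 0.90
    xi: float = 0.5  # off-diagonal of the unconditional correlation matrix

    def __post_init__(self):
        if self.eta1 < 0 or self.eta2 < 0 or self.eta1 + self.eta2 >= 1:
            raise ValueError("need eta1, eta2 >= 0 and eta1 + eta2 < 1")
        if abs(self.xi) >= 1:
            raise ValueError("xi must be a valid correlation")


CorrelationMode = (ConstantCorrelation, SinusoidCorrelation, StepCorrelation,
                   DCCCorrelation)


# ---------------------------------------------------------------------------
# simulation spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanParams:
    """ARMA(2,2) mean: mu_t = alpha + b1 z_{t-1} + b2 z_{t-2} - t1 e_{t-1} - t2 e_{t-2}."""

    alpha: float = 0.0
    ar: tuple = (0.0, 0.0)
    ma: tuple = (0.0, 0.0)


@dataclass(frozen=True)
class VarianceParams:
    """GARCH(1,1): sigma2_t = omega + phi e2_{t-1} + psi sigma2_{t-1}."""

    omega: float = 1.0
    phi: float = 0.0
    psi: float = 0.0

    def __post_init__(self):
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.phi < 0 or self.psi < 0:
            raise ValueError("phi, psi must be >= 0")
        if self.phi + self.psi >= 1:
            raise ValueError("non-stationary variance: phi + psi >= 1")

    @property
    def unconditional(self) -> float:
        return self.omega / (1.0 - self.phi - self.psi)


@dataclass(frozen=True)
class SimulationSpec:
    """Full generative description of one simulated subject."""

    T: int = 450
    tr: float = 2.0
    mean_params: tuple = (MeanParams(), MeanParams())
    variance_params: tuple = (VarianceParams(), VarianceParams())
    correlation: object = field(default_factory=ConstantCorrelation)
    seed: int = 0

    def __post_init__(self):
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if not isinstance(self.correlation, CorrelationMode):
            raise TypeError(f"unknown correlation mode {self.correlation!r}")


@dataclass
class SimulatedSubject:
    series: BivariateSeries
    true_correlation: np.ndarray
    spec: SimulationSpec


# ---------------------------------------------------------------------------
# single-subject simulation
# ---------------------------------------------------------------------------

def _correlated_shocks(rho: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw e_t ~ N(0, R_t) with R_t = [[1, rho_t], [rho_t, 1]] via Cholesky."""
    if np.max(np.abs(rho)) > 1:
        raise ValueError("|rho(t)| > 1 somewhere in the prescribed trajectory")
    v = rng.standard_normal((len(rho), 2))
    e1 = v[:, 0]
    e2 = rho * v[:, 0] + np.sqrt(1.0 - rho ** 2) * v[:, 1]
    return np.column_stack([e1, e2])


def _dcc_shocks(mode: DCCCorrelation, n: int, rng: np.random.Generator):
    """Simulate standardized shocks from the DCC(1,1) recursion.

    Returns (e, rho) where e are the correlated unit-variance shocks and rho
    the realized conditional correlation path.
    """
    eta1, eta2, xi = mode.eta1, mode.eta2, mode.xi
    q11 = q22 = 1.0
    q12 = xi
    e = np.empty((n, 2))
    rho = np.empty(n)
    v = rng.standard_normal((n, 2))
    c = 1.0 - eta1 - eta2
    for t in range(n):
        r = q12 / np.sqrt(q11 * q22)
        rho[t] = r
        e[t, 0] = v[t, 0]
        e[t, 1] = r * v[t, 0] + np.sqrt(1.0 - r * r) * v[t, 1]
        q11 = c * 1.0 + eta1 * e[t, 0] ** 2 + eta2 * q11
        q22 = c * 1.0 + eta1 * e[t, 1] ** 2 + eta2 * q22
        q12 = c * xi + eta1 * e[t, 0] * e[t, 1] + eta2 * q12
    return e, rho


def simulate_subject(spec: SimulationSpec) -> SimulatedSubject:
    """Simulate one subject from ``spec`` (deterministic under ``spec.seed``).

    The ARMA-GARCH recursion is run for ``BURN_IN`` extra initial samples
    which are discarded.  ``true_correlation`` records the innovation
    correlation rho(t) exactly for the retained window.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.T + BURN_IN

    if isinstance(spec.correlation, DCCCorrelation):
        e, rho_full = _dcc_shocks(spec.correlation, n, rng)
    else:
        idx = np.arange(-BURN_IN, spec.T)
        rho_full = np.asarray(spec.correlation.trajectory(idx, spec.tr),
                              dtype=float)
        e = _correlated_shocks(rho_full, rng)

    z = np.empty((n, 2))
    for j in range(2):
        mp: MeanParams = spec.mean_params[j]
        vp: VarianceParams = spec.variance_params[j]
        b1, b2 = mp.ar
        t1, t2 = mp.ma
        sigma2 = vp.unconditional
        eps_1 = eps_2 = 0.0  # lagged residuals
        zc = z[:, j]
        for t in range(n):
            sigma2 = vp.omega + vp.phi * eps_1 ** 2 + vp.psi * sigma2 if t else vp.unconditional
            eps = np.sqrt(sigma2) * e[t, j]
            z_1 = zc[t - 1] if t >= 1 else 0.0
            z_2 = zc[t - 2] if t >= 2 else 0.0
            zc[t] = (mp.alpha + b1 * z_1 + b2 * z_2 - t1 * eps_1 - t2 * eps_2 + eps)
            eps_2, eps_1 = eps_1, eps

    series = BivariateSeries(z[BURN_IN:], tr=spec.tr)
    return SimulatedSubject(series=series,
                            true_correlation=rho_full[BURN_IN:].copy(),
                            spec=spec)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Features for which the generator has an explicit handle, and how the
#: per-group setting is applied to the base correlation mode.
_EFFECT_HANDLES = {
    "MV": "offset",        # mean level of rho(t)
    "PAV": "offset",       # shifts the sign balance of rho(t)
    "VAR": "amplitude",    # fluctuation size of rho(t)
    "ALFF_dFC": "amplitude",
    "PEAK": "frequency",   # dominant frequency of rho(t)
    "SCO": "frequency",
    "SMED": "frequency",
}

FEATURE_GLOSSARY = (
    "MV", "VAR", "ZC", "PAV", "SCO", "SPR", "SKW", "KURT", "SMED", "SRO",
    "PEAK", "CREST", "FLUX", "SLOPE", "FLAT", "PSE", "ALFF_dFC",
)


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with prescribed generative shifts in named features."""

    n_per_group: tuple = (23, 25)
    feature_effects: dict = field(default_factory=dict)
    base_spec: SimulationSpec = field(default_factory=SimulationSpec)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_group) < 2:
            raise ValueError("each group needs at least 2 subjects")
        for name in self.feature_effects:
            if name not in FEATURE_GLOSSARY:
                raise ValueError(f"unknown feature {name!r}")
            if name not in _EFFECT_HANDLES:
                raise ValueError(
                    f"no generative handle for feature {name!r}; "
                    f"supported: {sorted(_EFFECT_HANDLES)}"
                )


def _apply_effects(base: SimulationSpec, effects: dict, group: int) -> SimulationSpec:
    """Apply the group-specific generative settings to the base spec."""
    mode = base.correlation
    for name, settings in effects.items():
        value = settings[group]
        handle = _EFFECT_HANDLES[name]
        if handle == "offset":
            if isinstance(mode, ConstantCorrelation):
                mode = replace(mode, rho=value)
            elif isinstance(mode, SinusoidCorrelation):
                mode = replace(mode, offset=value)
            else:
                raise ValueError(f"offset effect needs constant/sinusoid mode, got {mode!r}")
        elif handle == "amplitude":
            if not isinstance(mode, SinusoidCorrelation):
                raise ValueError(f"amplitude effect needs sinusoid mode, got {mode!r}")
            mode = replace(mode, amplitude=value)
        elif handle == "frequency":
            if not isinstance(mode, SinusoidCorrelation):
                raise ValueError(f"frequency effect needs sinusoid mode, got {mode!r}")
            mode = replace(mode, frequency=value)
    return replace(base, correlation=mode)


def generate_cohort(cohort: CohortSpec, require_effect: bool = False) -> pd.DataFrame:
    """Generate a two-group cohort as a table of simulated subjects.

    Returns a DataFrame with columns ``subject_id``, ``label`` (``"group0"`` /
    ``"group1"``), ``subject`` (:class:`SimulatedSubject`).  The two groups
    differ only in the generative settings named in ``feature_effects``.
    """
    if require_effect and not cohort.feature_effects:
        raise ValueError("a nonzero effect was demanded but feature_effects is empty")
    rows = []
    counter = 0
    for group, n in enumerate(cohort.n_per_group):
        spec_g = _apply_effects(cohort.base_spec, cohort.feature_effects, group)
        for _ in range(n):
            spec = replace(spec_g, seed=int(cohort.seed + 1_000_003 * counter))
            rows.append({
                "subject_id": f"sub-{counter:03d}",
                "label": f"group{group}",
                "subject": simulate_subject(spec),
            })
            counter += 1
    return pd.DataFrame(rows)
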