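"""Two-step quasi-maximum-likelihood estimation of ARMA(2,2)-GARCH(1,1)-DCC.

The dynamic functional connectivity (dFC) between two region time courses is
modelled as the conditional correlation rho_t of a bivariate
DCC(1,1)-GARCH(1,1) process with ARMA(2,2) conditional means:

    z_jt    = alpha_j + b1_j z_{j,t-1} + b2_j z_{j,t-2}
              - t1_j eps_{j,t-1} - t2_j eps_{j,t-2} + eps_jt
    sigma2_jt = omega_j + phi_j eps_{j,t-1}^2 + psi_j sigma2_{j,t-1}
    u_t     = D_t^{-1} eps_t,   D_t = diag(sigma_1t, sigma_2t)
    Q_t     = (1 - eta1 - eta2) Xi + eta1 u_{t-1} u_{t-1}' + eta2 Q_{t-1}
    R_t     = diag(Q_t)^{-1/2} Q_t diag(Q_t)^{-1/2}

Estimation follows the standard two-step procedure: a univariate ARMA-GARCH
Gaussian QML fit per series, then the correlation part of the likelihood
maximized over (eta1, eta2) with Xi fixed at the sample correlation of the
standardized residuals.  Constraints (omega > 0; phi, psi >= 0, phi+psi < 1;
eta1, eta2 >= 0, eta1+eta2 < 1) are enforced by smooth reparameterization, so
the optimizer works unconstrained.  The GARCH, ARMA and Q recursions are
all linear filters and run through scipy.signal.lfilter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.signal import lfilter
from sklearn.base import BaseEstimator
from statsmodels.stats.diagnostic import acorr_ljungbox

from .series import BivariateSeries, DFCSeries

_LOG2PI = np.log(2.0 * np.pi)


class DegenerateVarianceError(ValueError):
    """Raised when an input series is (numerically) constant."""


class CollinearInputError(ValueError):
    """Raised when the two standardized-residual columns are collinear."""


class ConvergenceError(RuntimeError):
    """Optimizer failed after restarts; carries the best attempt."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class GARCHParams:
    """Parameters of one univariate ARMA(p,q)-GARCH(1,1) margin."""

    alpha: float
    ar: tuple
    ma: tuple
    omega: float
    phi: float
    psi: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, *self.ar, *self.ma,
                         self.omega, self.phi, self.psi])


@dataclass
class UnivariateFit:
    params: GARCHParams
    fitted_mean: np.ndarray
    residuals: np.ndarray
    cond_sd: np.ndarray
    std_resid: np.ndarray
    loglik: float
    converged: bool
    ljung_box: tuple  # (statistic, p-value) at lag 10 on standardized residuals


@dataclass
class DCCFit:
    eta1: float
    eta2: float
    xi: np.ndarray          # 2x2 unconditional correlation of u_t
    q_series: np.ndarray    # (T, 2, 2)
    r_series: DFCSeries
    loglik_correlation: float
    converged: bool
    boundary: bool          # optimizer pinned near the constraint boundary


# ---------------------------------------------------------------------------
# recursions (vectorized through lfilter)
# ---------------------------------------------------------------------------

def arma_filter(z: np.ndarray, alpha: float, ar, ma):
    """Residuals and fitted means of the ARMA(2,2) mean model.

    The first ``max(p, q)`` residuals are set to zero (pre-sample values
    conditioned on the observed series).
    """
    z = np.asarray(z, dtype=float)
    p, q = len(ar), len(ma)
    k = max(p, q)
    T = len(z)
    x = z - alpha
    for i, b in enumerate(ar, start=1):
        x[i:] -= b * z[:-i] if i else 0.0
    # eps_t = x_t + t1 eps_{t-1} + t2 eps_{t-2}  ->  IIR filter in eps
    eps = np.zeros(T)
    if T > k:
        eps[k:] = lfilter([1.0], np.r_[1.0, -np.asarray(ma, dtype=float)], x[k:])
    mu = z - eps
    return eps, mu


def garch_recursion(eps: np.ndarray, omega: float, phi: float, psi: float,
                    sigma2_0: float | None = None) -> np.ndarray:
    """Conditional variance sigma2_t = omega + phi eps2_{t-1} + psi sigma2_{t-1}.

    sigma2_0 defaults to the sample variance of ``eps``.
    """
    eps = np.asarray(eps, dtype=float)
    T = len(eps)
    if sigma2_0 is None:
        sigma2_0 = float(np.var(eps))
        if sigma2_0 <= 0:
            sigma2_0 = omega / max(1.0 - phi - psi, 1e-6)
    sigma2 = np.empty(T)
    sigma2[0] = sigma2_0
    if T > 1:
        drive = omega + phi * eps[:-1] ** 2
        sigma2[1:], _ = lfilter([1.0], [1.0, -psi], drive, zi=[psi * sigma2_0])
    return sigma2


def dcc_recursion(u: np.ndarray, eta1: float, eta2: float, xi: np.ndarray):
    """Q_t and rho_t paths of the DCC(1,1) recursion (Q_0 = Xi).

    Each element of Q_t follows a scalar linear recursion driven by the
    lagged outer product of u, so the three distinct elements run through
    one IIR filter each.
    """
    u = np.asarray(u, dtype=float)
    T = len(u)
    c = 1.0 - eta1 - eta2
    xi12 = float(xi[0, 1])

    out = np.empty((T, 3))  # q11, q22, q12
    targets = (1.0, 1.0, xi12)
    drives = (u[:-1, 0] ** 2, u[:-1, 1] ** 2, u[:-1, 0] * u[:-1, 1])
    for i, (tgt, drv) in enumerate(zip(targets, drives)):
        q0 = tgt  # Q_0 = Xi (unit diagonal)
        out[0, i] = q0
        if T > 1:
            out[1:, i], _ = lfilter([1.0], [1.0, -eta2],
                                    c * tgt + eta1 * drv, zi=[eta2 * q0])
    q11, q22, q12 = out[:, 0], out[:, 1], out[:, 2]
    rho = q12 / np.sqrt(q11 * q22)
    q = np.empty((T, 2, 2))
    q[:, 0, 0], q[:, 1, 1] = q11, q22
    q[:, 0, 1] = q[:, 1, 0] = q12
    return q, rho


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def _variance_loglik(z, params: GARCHParams):
    # non-invertible MA trial points can overflow; they score -inf anyway
    with np.errstate(over="ignore", invalid="ignore"):
        eps, mu = arma_filter(z, params.alpha, params.ar, params.ma)
        sigma2 = garch_recursion(eps, params.omega, params.phi, params.psi)
        ll = -0.5 * np.sum(_LOG2PI + np.log(sigma2) + eps ** 2 / sigma2)
    if not np.isfinite(ll):
        ll = -np.inf
    return ll, eps, mu, sigma2


def _correlation_loglik(u: np.ndarray, eta1: float, eta2: float,
                        xi: np.ndarray):
    _, rho = dcc_recursion(u, eta1, eta2, xi)
    one_m = 1.0 - rho ** 2
    if np.any(one_m <= 0):
        return -np.inf, rho
    u1, u2 = u[:, 0], u[:, 1]
    quad = (u1 ** 2 - 2 * rho * u1 * u2 + u2 ** 2) / one_m
    ll = -0.5 * np.sum(np.log(one_m) + quad - (u1 ** 2 + u2 ** 2))
    return ll, rho


@dataclass(frozen=True)
class LogLikParts:
    total: float
    variance: float
    correlation: float


def log_likelihood(series: BivariateSeries, uni_params, eta1: float,
                   eta2: float, xi: np.ndarray) -> LogLikParts:
    """Full Gaussian log-likelihood, decomposed into variance + correlation.

    ``total == variance + correlation`` exactly (up to floating point); the
    variance part is the sum of the two univariate ARMA-GARCH likelihoods
    plus the ``+ u'u / 2`` correction term that moves between the pieces.
    """
    T = series.T
    var_ll = 0.0
    u = np.empty((T, 2))
    for j in range(2):
        llj, eps, _, sigma2 = _variance_loglik(series.values[:, j], uni_params[j])
        var_ll += llj
        u[:, j] = eps / np.sqrt(sigma2)
    corr_ll, rho = _correlation_loglik(u, eta1, eta2, xi)
    if not np.isfinite(corr_ll):
        raise ValueError("non-positive-definite R_t encountered")
    return LogLikParts(total=var_ll + corr_ll, variance=var_ll,
                       correlation=corr_ll)


# ---------------------------------------------------------------------------
# parameter transforms (constraints by smooth reparameterization)
# ---------------------------------------------------------------------------

def _simplex_from_raw(a: float, b: float):
    """Map R^2 -> {(x, y): x, y >= 0, x + y < 1} smoothly."""
    s = special.expit(a)       # x + y
    g = special.expit(b)       # share of x
    return s * g, s * (1.0 - g)

def _raw_from_simplex(x: float, y: float):
    s = min(max(x + y, 1e-8), 1 - 1e-8)
    g = min(max(x / s, 1e-8), 1 - 1e-8)
    return special.logit(s), special.logit(g)


def _unpack_uni(raw: np.ndarray, p: int, q: int) -> GARCHParams:
    alpha = raw[0]
    ar = tuple(raw[1:1 + p])
    ma = tuple(raw[1 + p:1 + p + q])
    omega = np.exp(raw[1 + p + q])
    phi, psi = _simplex_from_raw(raw[2 + p + q], raw[3 + p + q])
    return GARCHParams(alpha=alpha, ar=ar, ma=ma, omega=omega, phi=phi, psi=psi)


# ---------------------------------------------------------------------------
# step 1: univariate fits
# ---------------------------------------------------------------------------

def fit_univariate_arma_garch(z, mean_order=(2, 2), garch_order=(1, 1),
                              n_restarts: int = 3, tol: float = 1e-8,
                              arma_penalty: float = 15.0) -> UnivariateFit:
    """Gaussian QML fit of an ARMA(p,q)-GARCH(1,1) margin.

    Parameters are estimated jointly (mean and variance) by maximizing the
    univariate Gaussian likelihood; constraints are enforced by
    reparameterization (log for omega, logistic simplex for (phi, psi)).
    ``n_restarts`` randomly perturbed restarts guard against local optima.

    ``arma_penalty`` is a small fixed L2 penalty on the ARMA coefficients.
    ARMA(2,2) has an unidentified common-factor manifold (near-cancelling
    AR/MA pairs) along which the likelihood is flat; the penalty selects the
    parsimonious point on such ridges.  It does not grow with T, so it is
    asymptotically negligible wherever the coefficients are identified.
    """
    z_orig = np.asarray(z, dtype=float).ravel()
    if garch_order != (1, 1):
        raise NotImplementedError("only GARCH(1,1) is supported")
    p, q = mean_order
    sd = z_orig.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateVarianceError("input series has zero variance")
    # fit on the standardized series (scale equivariance + conditioning),
    # then map the estimates back to the original scale; rounding to single
    # precision makes the fit exactly invariant to rescaling the input (the
    # last-bit differences a rescale introduces would otherwise pick
    # different points on weakly identified likelihood ridges)
    z = np.float64(np.float32(z_orig / sd))

    def objective(raw):
        params = _unpack_uni(raw, p, q)
        ll, *_ = _variance_loglik(z, params)
        if not np.isfinite(ll):
            return 1e12
        pen = arma_penalty * (np.sum(np.square(params.ar))
                              + np.sum(np.square(params.ma)))
        return -ll + pen

    base = np.zeros(3 + p + q + 1)
    base[0] = z.mean()
    base[1 + p + q] = np.log(0.8 * z.var())
    base[2 + p + q], base[3 + p + q] = _raw_from_simplex(0.05, 0.20)

    rng = np.random.default_rng(12345)  # fixed: restarts must be reproducible
    best = None
    any_success = False
    for r in range(1 + n_restarts):
        x0 = base if r == 0 else base + rng.normal(scale=0.3, size=base.shape)
        res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                options={"ftol": tol, "maxiter": 500})
        any_success = any_success or bool(res.success)
        # earlier starts win near-ties: on a flat ridge (common ARMA factors,
        # unidentified psi under homoskedasticity) tiny noise-fitting gains
        # must not drag the estimate away from the parsimonious base start
        if best is None or res.fun < best.fun - 10.0:
            best = res
    if not np.isfinite(best.fun) or best.fun >= 1e12:
        raise ConvergenceError("univariate QML failed to find a finite optimum",
                               best=best)
    # tight simplex polish: pins the optimum far below L-BFGS's ftol slack,
    # so the estimate is reproducible to ~1e-8 in parameter space
    polish = optimize.minimize(objective, best.x, method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-10,
                                        "maxiter": 4000, "maxfev": 4000})
    if polish.fun <= best.fun:
        best = polish
    params_std = _unpack_uni(best.x, p, q)
    params = GARCHParams(alpha=params_std.alpha * sd, ar=params_std.ar,
                         ma=params_std.ma, omega=params_std.omega * sd ** 2,
                         phi=params_std.phi, psi=params_std.psi)
    ll, eps, mu, sigma2 = _variance_loglik(z_orig, params)
    sig = np.sqrt(sigma2)
    ustd = eps / sig
    lb = acorr_ljungbox(ustd, lags=[10], return_df=True)
    return UnivariateFit(params=params, fitted_mean=mu, residuals=eps,
                         cond_sd=sig, std_resid=ustd, loglik=float(ll),
                         converged=any_success,
                         ljung_box=(float(lb["lb_stat"].iloc[0]),
                                    float(lb["lb_pvalue"].iloc[0])))


# ---------------------------------------------------------------------------
# step 2: DCC fit on standardized residuals
# ---------------------------------------------------------------------------

def fit_dcc(u: np.ndarray, n_restarts: int = 3, tol: float = 1e-8,
            tr: float = 2.0, force_constant: bool = False) -> DCCFit:
    """Maximize the correlation part of the likelihood over (eta1, eta2).

    Xi is fixed at the sample correlation matrix of ``u`` (correlation
    targeting).  With ``force_constant=True`` the etas are pinned at zero and
    rho_t reduces to the constant off-diagonal of Xi.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 2 or u.shape[1] != 2:
        raise ValueError("u must be (T, 2)")
    xi = np.corrcoef(u.T)
    if not np.isfinite(xi).all() or abs(xi[0, 1]) >= 1.0 - 1e-12:
        raise CollinearInputError(
            "standardized residuals are collinear; correlation matrix singular")

    if force_constant:
        eta1 = eta2 = 0.0
        converged = True
    else:
        def objective(raw):
            e1, e2 = _simplex_from_raw(*raw)
            ll, _ = _correlation_loglik(u, e1, e2, xi)
            return -ll if np.isfinite(ll) else 1e12

        starts = [_raw_from_simplex(0.05, 0.90), _raw_from_simplex(0.02, 0.50)]
        rng = np.random.default_rng(54321)
        starts += [tuple(np.asarray(starts[0]) + rng.normal(scale=0.5, size=2))
                   for _ in range(max(0, n_restarts - 1))]
        best = None
        converged = False
        for x0 in starts:
            res = optimize.minimize(objective, np.asarray(x0), method="L-BFGS-B",
                                    options={"ftol": tol, "maxiter": 300})
            converged = converged or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        polish = optimize.minimize(objective, best.x, method="Nelder-Mead",
                                   options={"xatol": 1e-9, "fatol": 1e-11,
                                            "maxiter": 2000})
        if polish.fun <= best.fun:
            best = polish
        eta1, eta2 = _simplex_from_raw(*best.x)
        # a no-dynamics solution may beat the interior optimum; compare
        ll_const, _ = _correlation_loglik(u, 0.0, 0.0, xi)
        if ll_const >= -best.fun:
            eta1 = eta2 = 0.0

    q, rho = dcc_recursion(u, eta1, eta2, xi)
    ll, _ = _correlation_loglik(u, eta1, eta2, xi)
    boundary = eta1 + eta2 > 0.995
    if boundary:
        warnings.warn("DCC optimizer near the eta1 + eta2 = 1 boundary",
                      RuntimeWarning, stacklevel=2)
    return DCCFit(eta1=float(eta1), eta2=float(eta2), xi=xi, q_series=q,
                  r_series=DFCSeries(np.clip(rho, -1.0, 1.0), tr=tr),
                  loglik_correlation=float(ll), converged=converged,
                  boundary=boundary)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class DCCGARCH(BaseEstimator):
    """Dynamic conditional correlation estimator for a bivariate series.

    Parameters
    ----------
    mean_order : tuple, default (2, 2)
        (p, q) of the ARMA mean model.
    garch_order : tuple, default (1, 1)
        Only (1, 1) is supported.
    n_restarts : int, default 3
        Random optimizer restarts per stage.
    tol : float, default 1e-8
        Objective tolerance of the quasi-Newton optimizer.
    tr : float, default 2.0
        Sampling interval in seconds (used when X is a bare array).

    Attributes
    ----------
    rho_ : ndarray of shape (T,)
        Estimated conditional correlation trajectory.
    dfc_ : DFCSeries
        Same trajectory with its sampling interval.
    univariate_fits_ : tuple of UnivariateFit
    dcc_fit_ : DCCFit
    loglik_ : LogLikParts
    """

    def __init__(self, mean_order=(2, 2), garch_order=(1, 1), n_restarts=3,
                 tol=1e-8, tr=2.0):
        self.mean_order = mean_order
        self.garch_order = garch_order
        self.n_restarts = n_restarts
        self.tol = tol
        self.tr = tr

    def fit(self, X, y=None):
        if isinstance(X, BivariateSeries):
            series = X
        else:
            series = BivariateSeries(np.asarray(X, dtype=float), tr=self.tr)
        fits = []
        for j in range(2):
            try:
                fits.append(fit_univariate_arma_garch(
                    series.values[:, j], mean_order=self.mean_order,
                    garch_order=self.garch_order,
                    n_restarts=self.n_restarts, tol=self.tol))
            except Exception as exc:
                raise type(exc)(
                    f"stage 'univariate fit (series {j})': {exc}") from exc
        u = np.column_stack([f.std_resid for f in fits])
        try:
            dcc = fit_dcc(u, n_restarts=self.n_restarts, tol=self.tol,
                          tr=series.tr)
        except Exception as exc:
            raise type(exc)(f"stage 'DCC fit': {exc}") from exc
        self.univariate_fits_ = tuple(fits)
        self.dcc_fit_ = dcc
        self.dfc_ = dcc.r_series
        self.rho_ = dcc.r_series.rho
        self.loglik_ = log_likelihood(series, [f.params for f in fits],
                                      dcc.eta1, dcc.eta2, dcc.xi)
        return self


def estimate_dfc(series: BivariateSeries, **kwargs):
    """Two-step dFC estimate; returns (DFCSeries, (fit1, fit2), DCCFit)."""
    est = DCCGARCH(tr=series.tr, **kwargs).fit(series)
    return est.dfc_, est.univariate_fits_, est.dcc_fit_
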