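"""Group comparison: BCa bootstrap intervals for mean differences, with
Benjamini-Hochberg FDR control across the feature family.

The bias-corrected and accelerated (BCa) interval adjusts the percentile
bootstrap endpoints by a median-bias factor z0 (from the fraction of
bootstrap statistics below the observed value) and an acceleration factor a
(from the jackknife skewness of the statistic).  Resampling is stratified:
each group is resampled independently with replacement.  Two-sided p-values
are obtained by interval inversion — the smallest alpha at which the
1 - alpha BCa interval excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests


@dataclass
class BootstrapResult:
    observed_diff: float
    boot_samples: np.ndarray
    z0: float
    a: float
    ci: tuple
    p_value: float
    level: float
    B: int
    seed: int | None
    degenerate: bool = False


def _jackknife_acceleration(x: np.ndarray, y: np.ndarray) -> float:
    """Acceleration from group-wise delete-one jackknife of mean(x)-mean(y)."""
    nx, ny = len(x), len(y)
    sx, sy = x.sum(), y.sum()
    theta_x = (sx - x) / (nx - 1) - y.mean()          # delete one from x
    theta_y = x.mean() - (sy - y) / (ny - 1)          # delete one from y
    theta = np.concatenate([theta_x, theta_y])
    d = theta.mean() - theta
    denom = (d ** 2).sum() ** 1.5
    if denom == 0:
        return 0.0
    return float((d ** 3).sum() / (6.0 * denom))


def _bca_interval(boot: np.ndarray, z0: float, a: float, level: float):
    alpha = 1.0 - level
    zlo, zhi = norm.ppf(alpha / 2), norm.ppf(1 - alpha / 2)
    def adj(z):
        num = z0 + z
        return norm.cdf(z0 + num / (1 - a * num))
    qlo, qhi = adj(zlo), adj(zhi)
    lo = float(np.quantile(boot, qlo))
    hi = float(np.quantile(boot, qhi))
    return (lo, hi) if lo <= hi else (hi, lo)


def bca_diff_means(x, y, B: int = 1000, level: float = 0.95,
                   seed: int | None = None, method: str = "bca"
                   ) -> BootstrapResult:
    """BCa bootstrap CI and p-value for mean(x) - mean(y).

    With ``method="percentile"`` the bias-correction and acceleration are
    forced to zero, reducing the interval to the plain percentile interval
    of the same bootstrap draws.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    obs = float(x.mean() - y.mean())
    bx = x[rng.integers(0, len(x), size=(B, len(x)))].mean(axis=1)
    by = y[rng.integers(0, len(y), size=(B, len(y)))].mean(axis=1)
    boot = bx - by

    degenerate = bool(np.ptp(boot) == 0)
    if degenerate:
        warnings.warn("degenerate bootstrap distribution (point interval)",
                      RuntimeWarning, stacklevel=2)
        v = float(boot[0])
        return BootstrapResult(obs, boot, 0.0, 0.0, (v, v),
                               1.0 if v == 0 else 0.0, level, B, seed,
                               degenerate=True)

    if method == "percentile":
        z0 = a = 0.0
    elif method == "bca":
        frac = np.mean(boot < obs) + 0.5 * np.mean(boot == obs)
        frac = min(max(frac, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
        z0 = float(norm.ppf(frac))
        a = _jackknife_acceleration(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")

    ci = _bca_interval(boot, z0, a, level)

    # invert the interval family for a two-sided p-value: smallest alpha at
    # which the 1 - alpha interval excludes zero (monotone in alpha)
    def excludes(alpha):
        lo, hi = _bca_interval(boot, z0, a, 1.0 - alpha)
        return lo > 0 or hi < 0
    if excludes(1e-8):
        p = 1e-8
    elif not excludes(1.0 - 1e-8):
        p = 1.0
    else:
        lo_a, hi_a = 1e-8, 1.0 - 1e-8
        for _ in range(60):
            mid = 0.5 * (lo_a + hi_a)
            if excludes(mid):
                hi_a = mid
            else:
                lo_a = mid
        p = hi_a
    return BootstrapResult(obs, boot, z0, a, ci, float(p), level, B, seed,
                           degenerate=False)


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclass
class GroupComparison:
    table: pd.DataFrame          # feature, pair, diff, ci_lo, ci_hi, p_raw, p_adj, rejected
    q: float
    level: float
    B: int
    group_order: tuple


def compare_groups(feature_table: pd.DataFrame, labels, B: int = 1000,
                   level: float = 0.95, q: float = 0.05,
                   seed: int | None = None, group_order=None,
                   family: str = "joint") -> GroupComparison:
    """Per-feature BCa comparisons between two groups, FDR-controlled.

    ``feature_table`` has one row per subject and one column per feature
    (an optional ``pair`` column splits the family by network pair).  The
    difference is mean(first group) - mean(second group) in ``group_order``
    (sorted labels by default), so positive values mean larger in the first
    group.  ``family="joint"`` adjusts across all feature x pair tests;
    ``family="per_pair"`` adjusts within each pair separately.
    """
    labels = np.asarray(labels)
    if group_order is None:
        group_order = tuple(sorted(pd.unique(labels)))
    if len(group_order) != 2:
        raise ValueError("exactly two groups required")
    ga, gb = group_order
    if (labels == ga).sum() < 2 or (labels == gb).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")

    df = feature_table.reset_index(drop=True)
    pairs = df["pair"] if "pair" in df else pd.Series(["all"] * len(df))
    feature_cols = [c for c in df.columns if c not in ("pair", "subject_id", "label")]

    rows = []
    rng = np.random.default_rng(seed)
    for pair in pd.unique(pairs):
        sel = (pairs == pair).to_numpy()
        for feat in feature_cols:
            vals = df.loc[sel, feat].to_numpy(dtype=float)
            lab = labels[sel]
            ok = ~np.isnan(vals)
            x = vals[ok & (lab == ga)]
            y = vals[ok & (lab == gb)]
            res = bca_diff_means(x, y, B=B, level=level,
                                 seed=int(rng.integers(2 ** 31)))
            rows.append({"feature": feat, "pair": pair,
                         "diff": res.observed_diff, "ci_lo": res.ci[0],
                         "ci_hi": res.ci[1], "p_raw": res.p_value,
                         "n_a": len(x), "n_b": len(y),
                         "n_missing": int((~ok).sum())})
    table = pd.DataFrame(rows)
    if family == "joint":
        p_adj, rej = bh_fdr(table["p_raw"].to_numpy(), q=q)
        table["p_adj"], table["rejected"] = p_adj, rej
    elif family == "per_pair":
        table["p_adj"] = np.nan
        table["rejected"] = False
        for pair in pd.unique(table["pair"]):
            sel = table["pair"] == pair
            p_adj, rej = bh_fdr(table.loc[sel, "p_raw"].to_numpy(), q=q)
            table.loc[sel, "p_adj"] = p_adj
            table.loc[sel, "rejected"] = rej
    else:
        raise ValueError(f"unknown family {family!r}")
    return GroupComparison(table=table, q=q, level=level, B=B,
                           group_order=tuple(group_order))
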