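"""Differential melting statistics: pooled vs condition-specific sigmoid
fits, F-tests with data-estimated effective degrees of freedom, BH
correction, and 4PL curve fits with confidence bands for reporting.

The melting model is the classic thermal-shift sigmoid with a reciprocal
temperature exponent,

    f(T) = (1 - pl) / (1 + exp(b - a / T)) + pl,

where ``pl`` is the non-melting plateau.  The null model pools both
treatment arms into one fit; the alternative fits each arm separately.  The
improvement statistic

    F = ((RSS0 - RSS1) / d1) / (RSS1 / d2)

is referred to an F(d1, d2) distribution whose effective degrees of freedom
are estimated across all tested groups by scaled chi-square moment matching,
because residuals of nonlinear fits on correlated melt points do not follow
the nominal counting degrees of freedom.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import FourPLParams, TemperatureGrid

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sigmoid fitting
# ---------------------------------------------------------------------------


@dataclass
class SigmoidFit:
    pl: float
    a: float
    b: float
    rss: float
    n_points: int
    converged: bool

    def predict(self, T) -> np.ndarray:
        T = np.asarray(T, float)
        return (1.0 - self.pl) / (1.0 + np.exp(self.b - self.a / T)) + self.pl


def _sigmoid(T, pl, a, b):
    return (1.0 - pl) / (1.0 + np.exp(b - a / T)) + pl


def fit_melt_model(
    T: np.ndarray,
    y: np.ndarray,
    starts: Optional[Sequence[Tuple[float, float, float]]] = None,
) -> SigmoidFit:
    """Least-squares sigmoid fit with a small multi-start grid.

    Starts cover melting points across the grid range; the plateau starts at
    the smallest observed fraction.  The best-RSS solution is returned;
    failure of every start is flagged via ``converged=False``.
    """
    T = np.asarray(T, float)
    y = np.asarray(y, float)
    ok = np.isfinite(T) & np.isfinite(y)
    T, y = T[ok], y[ok]
    if T.size < 5:
        raise ValueError("need at least 5 points to fit the melting model")
    if np.allclose(y, y[0]):
        return SigmoidFit(pl=float(y[0]), a=1.0, b=0.0, rss=0.0, n_points=T.size, converged=True)
    pl0 = float(np.clip(np.min(y), 0.0, 0.5))
    if starts is None:
        tm_guesses = np.quantile(T, [0.25, 0.5, 0.75])
        starts = [
            (pl0, a, a / tm)
            for a in (500.0, 1500.0)
            for tm in tm_guesses
        ]
    best = None
    for s in starts:
        try:
            res = optimize.least_squares(
                lambda p: _sigmoid(T, *p) - y,
                x0=np.asarray(s, float),
                bounds=([0.0, 1e-6, -np.inf], [0.9999, np.inf, np.inf]),
                method="trf",
                max_nfev=400,
            )
        except Exception:  # numerical failure of one start is tolerable
            continue
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        return SigmoidFit(pl=pl0, a=np.nan, b=np.nan, rss=float(np.sum((y - y.mean()) ** 2)),
                          n_points=T.size, converged=False)
    rss, res = best
    pl, a, b = (float(v) for v in res.x)
    return SigmoidFit(pl=pl, a=a, b=b, rss=rss, n_points=T.size, converged=bool(res.success))


# ---------------------------------------------------------------------------
# curve completeness filter
# ---------------------------------------------------------------------------


def filter_complete_curves(
    group_curves: Mapping[str, pd.DataFrame],
    design: Sequence[Tuple[str, int]],
    n_temperatures: int,
) -> List[str]:
    """Groups retained for a comparison: every (condition, replicate) cell of
    the design must have a complete melt curve (all temperatures finite)."""
    kept = []
    for gid, df in group_curves.items():
        ok = True
        for cond, rep in design:
            cell = df[(df["condition"] == cond) & (df["replicate"] == rep)]
            vals = cell["value"].to_numpy()
            if len(cell) < n_temperatures or not np.all(np.isfinite(vals)):
                ok = False
                break
        if ok:
            kept.append(gid)
    return kept


# ---------------------------------------------------------------------------
# NPARC F-test
# ---------------------------------------------------------------------------


@dataclass
class NparcFits:
    """Null/alternative residual sums for one group and comparison scope."""

    group_id: str
    rss0: float
    rss1: float
    n_points: int
    n_conditions: int
    n_params: int = 3


def nparc_rss(curves: pd.DataFrame, group_id: str = "") -> NparcFits:
    """Pooled (null) and per-condition (alternative) sigmoid fits.

    ``curves`` needs columns condition, T, value.  RSS1 is the sum of the
    per-condition fits' RSS; numerically RSS0 is floored at RSS1.
    """
    T = curves["T"].to_numpy(float)
    y = curves["value"].to_numpy(float)
    null_fit = fit_melt_model(T, y)
    # warm-starting each model with the other's optimum guards against the
    # nested models landing in inconsistent local minima
    warm = [(null_fit.pl, null_fit.a, null_fit.b)] if np.isfinite(null_fit.a) else []
    rss1 = 0.0
    conditions = sorted(curves["condition"].unique())
    cond_params = []
    for cond in conditions:
        sub = curves[curves["condition"] == cond]
        Tc = sub["T"].to_numpy(float)
        yc = sub["value"].to_numpy(float)
        fit = fit_melt_model(Tc, yc)
        if warm:
            alt = fit_melt_model(Tc, yc, starts=warm)
            if alt.rss < fit.rss:
                fit = alt
        rss1 += fit.rss
        if np.isfinite(fit.a):
            cond_params.append((fit.pl, fit.a, fit.b))
    if cond_params:
        refit = fit_melt_model(T, y, starts=cond_params)
        if refit.rss < null_fit.rss:
            null_fit = refit
    rss0 = max(null_fit.rss, rss1)
    return NparcFits(
        group_id=group_id,
        rss0=rss0,
        rss1=rss1,
        n_points=int(np.isfinite(y).sum()),
        n_conditions=len(conditions),
    )


def fit_scaled_chi2(
    x: np.ndarray, q_max: float = 0.8
) -> Optional[Tuple[float, float]]:
    """Fit (dof, scale) of a scaled chi-square to the quantile body of ``x``.

    Least squares on log quantiles from 0.05 up to ``q_max``; the upper tail
    is ignored, so a minority of strongly non-null observations (true
    positives in a screen) cannot corrupt the null model.  Returns None when
    the body is degenerate (non-positive quantiles) or the fit diverges.
    """
    x = np.asarray(x, float)
    med = float(np.median(x))
    if med <= 0:
        return None
    qs = np.linspace(0.05, q_max, 12)
    emp = np.quantile(x / med, qs)  # median-normalized: fit is scale-free
    if np.any(emp <= 0):
        return None

    def loss(v: np.ndarray) -> float:
        d, scale = np.exp(v)
        model = scale * stats.chi2.ppf(qs, d)
        return float(np.sum((np.log(emp) - np.log(model)) ** 2))

    res = optimize.minimize(
        loss, x0=[np.log(3.0), np.log(1.0 / 3.0)], method="Nelder-Mead"
    )
    d, scale = (float(np.exp(v)) for v in res.x)
    if not (np.isfinite(d) and np.isfinite(scale) and d > 0 and scale > 0):
        return None
    return d, scale * med


def estimate_effective_dof(
    rss_diffs: np.ndarray,
    rss1s: np.ndarray,
    min_groups: int = 50,
    counting_fallback: Optional[Tuple[float, float]] = None,
    return_scales: bool = False,
):
    """Effective (d1, d2) by scaled chi-square moment matching.

    If X ~ sigma^2 chi2_d then d = 2 mean(X)^2 / var(X) and
    sigma^2 = var(X) / (2 mean(X)).  The two components carry their own
    fitted scales (``return_scales=True`` to get them); the F statistic must
    normalize each component by its scale, since in practice the denominator
    is slightly overdispersed relative to the numerator and ignoring the
    scale ratio biases every p-value.  With too few groups, or degenerate
    variances, nominal counting degrees of freedom (unit scales) are
    returned with a logged notice.
    """
    rss_diffs = np.asarray(rss_diffs, float)
    rss1s = np.asarray(rss1s, float)
    ok = np.isfinite(rss_diffs) & np.isfinite(rss1s)
    rss_diffs, rss1s = rss_diffs[ok], rss1s[ok]

    def _moment_fit(x: np.ndarray) -> Tuple[float, float]:
        v = float(np.var(x, ddof=1))
        m = float(np.mean(x))
        if v <= 0 or m <= 0:
            return np.nan, np.nan
        return 2.0 * m * m / v, v / (2.0 * m)

    def _robust_fit(x: np.ndarray) -> Tuple[float, float]:
        fitted = fit_scaled_chi2(x)
        return fitted if fitted is not None else _moment_fit(x)

    if rss_diffs.size >= min_groups:
        d1, s1 = _robust_fit(rss_diffs)
        d2, s2 = _robust_fit(rss1s)
        if np.isfinite(d1) and np.isfinite(d2):
            return (d1, d2, s1, s2) if return_scales else (d1, d2)
    if counting_fallback is None:
        raise ValueError(
            "too few groups for moment matching and no counting fallback given"
        )
    logger.info(
        "effective-dof moment matching unavailable (%d groups); "
        "falling back to counting degrees of freedom",
        rss_diffs.size,
    )
    d1, d2 = counting_fallback
    return (d1, d2, 1.0, 1.0) if return_scales else (d1, d2)


def nparc_f_test(
    fits: Sequence[NparcFits],
    scope: str = "all",
    min_groups: int = 50,
) -> pd.DataFrame:
    """F statistics and BH-adjusted p-values across a comparison scope.

    Effective degrees of freedom are pooled across all groups in the scope.
    Returns one row per group: group, scope, RSS0, RSS1, d1, d2, F, p, p_adj.
    """
    if not fits:
        return pd.DataFrame(
            columns=["group_id", "scope", "rss0", "rss1", "d1", "d2", "F", "p", "p_adj"]
        )
    diffs = np.array([f.rss0 - f.rss1 for f in fits])
    rss1s = np.array([f.rss1 for f in fits])
    f0 = fits[0]
    counting = (
        float((f0.n_conditions - 1) * f0.n_params),
        float(f0.n_points - f0.n_conditions * f0.n_params),
    )
    d1, d2, s1, s2 = estimate_effective_dof(
        diffs, rss1s, min_groups=min_groups, counting_fallback=counting,
        return_scales=True,
    )
    rows = []
    for f in fits:
        if f.rss1 <= 0:
            F = np.inf if f.rss0 > f.rss1 else 0.0
        else:
            F = max(
                ((f.rss0 - f.rss1) / (s1 * d1)) / (f.rss1 / (s2 * d2)), 0.0
            )
        p = float(stats.f.sf(F, d1, d2))
        rows.append(
            {
                "group_id": f.group_id,
                "scope": scope,
                "rss0": f.rss0,
                "rss1": f.rss1,
                "d1": d1,
                "d2": d2,
                "F": F,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# 4PL reporting fits
# ---------------------------------------------------------------------------


@dataclass
class FourPLFit:
    params: FourPLParams
    rss: float
    covariance: Optional[np.ndarray]
    band_ok: bool
    grid_T: np.ndarray
    fitted: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    point_mean: pd.Series
    point_sd: pd.Series


def _four_pl(T, bottom, top, tm, scale):
    return bottom + (top - bottom) / (1.0 + np.exp((T - tm) / scale))


def fit_4pl(points: pd.DataFrame, conf: float = 0.95) -> FourPLFit:
    """4PL least squares with a first-order-propagated confidence band.

    ``points`` needs columns T and value (several observations per
    temperature are expected).  The band is f(T) +/- t * se(T) with
    se^2 = g' C g from the parameter covariance; a singular covariance sets
    ``band_ok=False`` and a zero-width band.
    """
    T = points["T"].to_numpy(float)
    y = points["value"].to_numpy(float)
    ok = np.isfinite(T) & np.isfinite(y)
    T, y = T[ok], y[ok]
    if np.unique(T).size < 5:
        raise ValueError("need at least 5 distinct temperatures for a 4PL fit")
    b0 = float(np.min(y))
    t0 = float(np.max(y))
    mid = (b0 + t0) / 2.0
    tm0 = float(T[np.argmin(np.abs(y - mid))])
    p0 = [b0, t0, tm0, 2.0]
    popt, pcov = optimize.curve_fit(
        _four_pl,
        T,
        y,
        p0=p0,
        maxfev=20000,
        bounds=([-0.5, 0.0, T.min() - 30.0, 1e-3], [0.9, 2.5, T.max() + 30.0, 50.0]),
    )
    resid = y - _four_pl(T, *popt)
    rss = float(np.sum(resid**2))
    params = FourPLParams(bottom=float(popt[0]), top=float(popt[1]), tm=float(popt[2]), scale=float(popt[3]))

    grid_T = np.unique(T)
    fitted = _four_pl(grid_T, *popt)
    dof = max(T.size - 4, 1)
    tcrit = stats.t.ppf(0.5 + conf / 2.0, dof)
    band_ok = bool(np.all(np.isfinite(pcov)))
    se = np.zeros_like(grid_T)
    if band_ok:
        eps = 1e-6
        J = np.zeros((grid_T.size, 4))
        for k in range(4):
            dp = np.array(popt, float)
            step = eps * max(abs(dp[k]), 1.0)
            dp[k] += step
            J[:, k] = (_four_pl(grid_T, *dp) - fitted) / step
        var = np.einsum("ij,jk,ik->i", J, pcov, J)
        if np.any(var < 0) or not np.all(np.isfinite(var)):
            band_ok = False
        else:
            se = np.sqrt(var)
    by_T = pd.DataFrame({"T": T, "value": y}).groupby("T")["value"]
    return FourPLFit(
        params=params,
        rss=rss,
        covariance=pcov if band_ok else None,
        band_ok=band_ok,
        grid_T=grid_T,
        fitted=fitted,
        ci_lower=fitted - tcrit * se,
        ci_upper=fitted + tcrit * se,
        point_mean=by_T.mean(),
        point_sd=by_T.std(ddof=1),
    )


def plot_melt_curve(fit: FourPLFit, ax=None, label: Optional[str] = None, color=None):
    """Basic melt-curve plot: points (mean +/- sd), 4PL fit and CI band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    Ts = np.linspace(fit.grid_T.min(), fit.grid_T.max(), 200)
    curve = _four_pl(Ts, *fit.params.as_array())
    ax.errorbar(
        fit.point_mean.index,
        fit.point_mean.values,
        yerr=fit.point_sd.values,
        fmt="o",
        color=color,
        label=label,
    )
    ax.plot(Ts, curve, color=color)
    if fit.band_ok:
        ax.fill_between(fit.grid_T, fit.ci_lower, fit.ci_upper, alpha=0.2, color=color)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("fraction non-denatured")
    return ax
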