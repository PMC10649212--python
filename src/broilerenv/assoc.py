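"""Correlation screening and simple linear regression of exposure vs performance.

For every candidate pair — a performance response at one weekly age against
the exposure hours in one environmental band over either the same-age week
or the cumulative window from placement — the screen computes the Pearson
product-moment correlation with a two-sided t-test p-value, and fits a
simple ordinary-least-squares regression (response on exposure hours) for
pairs passing the significance screen.  Reported fit statistics are the
intercept, slope, R^2, adjusted R^2, root mean square error on n-2 degrees
of freedom, and the slope p-value.

No multiple-testing correction is applied by default; a Benjamini-Hochberg
option is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import BAND_COLUMNS

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "pearson_r",
    "fit_simple_ols",
    "grid_correlations",
    "screen",
    "association_table",
    "RESPONSES",
]

RESPONSES = ("bw", "bw_gain", "fcr", "week_mortality", "cum_mortality")
AGES = (7, 14, 21, 28, 35)


@dataclass(frozen=True)
class CorrelationResult:
    x_label: str
    y_label: str
    n: int
    r: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    x_label: str
    y_label: str
    n: int
    intercept: float
    slope: float
    r2: float
    r2_adj: float
    rmse: float
    p_slope: float


def _check_pair(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    return x, y


def pearson_r(x, y, x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    """Pearson product-moment correlation with two-sided t-test p-value.

    ``p`` is from ``t = r * sqrt((n-2) / (1-r^2))`` on n-2 degrees of
    freedom.  Constant vectors have no defined correlation and raise.
    """
    x, y = _check_pair(x, y)
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(x_label=x_label, y_label=y_label, n=n, r=r, p=p)


def fit_simple_ols(x, y, x_label: str = "x", y_label: str = "y") -> RegressionResult:
    """Simple OLS of ``y`` on ``x`` with closed-form normal equations.

    slope = Sxy/Sxx, intercept = mean(y) - slope*mean(x);
    rmse = sqrt(SSE/(n-2)); the slope p-value is a two-sided t-test.
    """
    x, y = _check_pair(x, y)
    n = x.size
    xc = x - x.mean()
    sxx = float((xc ** 2).sum())
    if sxx == 0:
        raise ValueError("degenerate design: x is constant")
    sxy = float((xc * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float((resid ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    rmse = np.sqrt(sse / (n - 2))
    se_slope = np.sqrt(sse / (n - 2) / sxx)
    if se_slope == 0:
        p_slope = 0.0
    else:
        t = slope / se_slope
        p_slope = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return RegressionResult(
        x_label=x_label, y_label=y_label, n=n,
        intercept=intercept, slope=slope,
        r2=float(r2), r2_adj=float(r2_adj), rmse=float(rmse), p_slope=p_slope,
    )


def _grid_pairs(exposure: pd.DataFrame, performance: pd.DataFrame):
    """Yield (meta, x, y) for every candidate (response, age, band, window)."""
    exp_idx = exposure.set_index(["kind", "start_day", "end_day"]).sort_index()
    for response in RESPONSES:
        for age in AGES:
            perf_age = performance.loc[performance["age_day"] == age, ["flock_id", response]]
            for kind, start, end in (("week", age - 7, age), ("cum", 0, age)):
                try:
                    exp_win = exp_idx.loc[(kind, start, end)]
                except KeyError:
                    continue
                if isinstance(exp_win, pd.Series):
                    continue
                merged = perf_age.merge(exp_win.reset_index(drop=True), on="flock_id")
                for band in BAND_COLUMNS:
                    meta = {
                        "response": response, "age_day": age, "band": band,
                        "window_kind": kind, "start_day": start, "end_day": end,
                    }
                    yield meta, merged[band].to_numpy(float), merged[response].to_numpy(float)


def grid_correlations(exposure: pd.DataFrame, performance: pd.DataFrame) -> pd.DataFrame:
    """Pearson r/p for the full (response, age) x (band, window) grid.

    Pairs with a constant exposure vector (nobody exposed in that band) are
    reported with ``r`` and ``p`` as NaN rather than dropped, so the grid
    shape is predictable.  Ordering is deterministic: response, age, band,
    window kind.
    """
    rows = []
    for meta, x, y in _grid_pairs(exposure, performance):
        row = dict(meta)
        try:
            res = pearson_r(x, y)
            row.update(n=res.n, r=res.r, p=res.p)
        except ValueError:
            row.update(n=len(x), r=np.nan, p=np.nan)
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["response", "age_day", "band", "window_kind"], kind="stable"
    ).reset_index(drop=True)


def screen(exposure: pd.DataFrame, performance: pd.DataFrame,
           alpha: float = 0.05, adjust: str | None = None) -> pd.DataFrame:
    """Return the grid pairs whose correlation p-value is below ``alpha``.

    ``adjust='bh'`` applies a Benjamini-Hochberg correction across the grid
    before filtering (off by default).
    """
    grid = grid_correlations(exposure, performance)
    valid = grid.dropna(subset=["p"]).copy()
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        valid["p_adj"] = multipletests(valid["p"], method="fdr_bh")[1]
        return valid[valid["p_adj"] < alpha].reset_index(drop=True)
    if adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return valid[valid["p"] < alpha].reset_index(drop=True)


def association_table(exposure: pd.DataFrame, performance: pd.DataFrame,
                      alpha: float = 0.05, adjust: str | None = None) -> pd.DataFrame:
    """Screen the grid, then fit simple OLS for every significant pair.

    Output columns mirror a correlation/regression report: age, response,
    band, window, r, p, n, intercept, estimate (slope), R^2, adjusted R^2,
    RMSE and the regression p-value.
    """
    hits = screen(exposure, performance, alpha=alpha, adjust=adjust)
    exp_idx = exposure.set_index(["kind", "start_day", "end_day"]).sort_index()
    rows = []
    for hit in hits.itertuples(index=False):
        exp_win = exp_idx.loc[(hit.window_kind, hit.start_day, hit.end_day)].reset_index(drop=True)
        perf_age = performance.loc[performance["age_day"] == hit.age_day,
                                   ["flock_id", hit.response]]
        merged = perf_age.merge(exp_win, on="flock_id")
        fit = fit_simple_ols(merged[hit.band], merged[hit.response])
        rows.append({
            "age_day": hit.age_day, "response": hit.response, "band": hit.band,
            "window_kind": hit.window_kind,
            "start_day": hit.start_day, "end_day": hit.end_day,
            "r": hit.r, "p_correlation": hit.p, "n": fit.n,
            "intercept": fit.intercept, "estimate": fit.slope,
            "r2": fit.r2, "r2_adj": fit.r2_adj, "rmse": fit.rmse,
            "p_regression": fit.p_slope,
        })
    return pd.DataFrame(rows)
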