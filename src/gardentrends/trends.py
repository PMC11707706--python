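"""Per-era OLS trend fits, reference detrending and the decoupling test.

For one centroid, era and metric (season-mean NDVI or within-season NDVI
variance) the year series is modeled as a straight line by ordinary least
squares; the trend is the slope per year. A garden is "decoupled" from the
local background when its slope remains significantly nonzero after the
trend of its nearest abandoned-land-use reference has been removed.

Two detrending modes exist:

* ``fitted_line`` (default): subtract the reference's fitted OLS line
  evaluated at the garden's years. This tolerates year sets that differ
  between garden and reference. Because subtracting an affine function leaves
  the garden's own residuals unchanged, the plain OLS p-value of the adjusted
  series ignores the sampling error of the reference slope; by default the
  decoupling test therefore *propagates* that error (combined standard error,
  Welch-Satterthwaite df), which keeps the null rejection rate at the nominal
  alpha. Set ``reference_uncertainty="ignore"`` for the naive p.
* ``paired_values``: subtract the reference's raw season metrics on the years
  common to both series. The reference noise then enters the residuals of the
  adjusted series, so the plain OLS p is already calibrated.

Convention: a fit with exactly zero residual sum of squares has p = 0.
Fits with fewer than ``min_years`` seasons are insufficient-data outcomes
(returned as None, never an exception) and are recorded per garden.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .config import EraDefinition
from .errors import ContractError

MIN_YEARS_DEFAULT = 5


@dataclass(frozen=True)
class TrendFit:
    """An OLS line over years for one metric.

    slope/intercept are in metric units per year and metric units; the
    intercept is taken at ``origin_year`` (years are centered there before
    fitting, which leaves the slope unchanged). ``df`` is the t-test degrees
    of freedom (n-2 for a plain fit; Welch-Satterthwaite for a combined
    detrended fit).
    """

    slope: float
    intercept: float
    stderr: float
    p_value: float
    n_years: int
    origin_year: int
    df: float
    rss: float = 0.0

    def predict(self, years) -> np.ndarray:
        years = np.asarray(years, dtype=float)
        return self.intercept + self.slope * (years - self.origin_year)


@dataclass
class SeasonSeries:
    """Year-indexed values of one metric for one centroid and era."""

    centroid_id: str
    era: Optional[str]
    metric: str  # "mean" or "variance"
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ContractError("years and values must have equal length")
        if len(self.years) > 1 and not np.all(np.diff(self.years) > 0):
            raise ContractError("years must be strictly increasing")


# ---------------------------------------------------------------------------
# core masked batch engine
# ---------------------------------------------------------------------------

def batch_ols(x: np.ndarray, V: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized OLS of each row of ``V`` (NaN = missing) on the shared axis ``x``.

    Returns arrays slope, intercept (at x = 0), stderr, p_value, n, df, rss.
    Rows need n >= 3 and at least two distinct observed x to be meaningful;
    other rows come back as NaN.
    """
    V = np.atleast_2d(np.asarray(V, dtype=float))
    x = np.asarray(x, dtype=float)
    M = np.isfinite(V)
    n = M.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xs = np.where(M, x[None, :], 0.0)
        vs = np.where(M, V, 0.0)
        xbar = xs.sum(axis=1) / n
        vbar = vs.sum(axis=1) / n
        dx = np.where(M, x[None, :] - xbar[:, None], 0.0)
        dv = np.where(M, V - vbar[:, None], np.float64(0.0))
        sxx = (dx * dx).sum(axis=1)
        sxy = (dx * dv).sum(axis=1)
        syy = (dv * dv).sum(axis=1)
        slope = sxy / sxx
        intercept = vbar - slope * xbar
        rss = np.maximum(syy - slope * sxy, 0.0)
        df = n - 2.0
        sigma2 = rss / df
        stderr = np.sqrt(sigma2 / sxx)
        t = np.abs(slope) / stderr
    p = np.full(len(slope), np.nan)
    ok = (n >= 3) & (sxx > 0)
    finite_t = ok & (stderr > 0)
    p[finite_t] = 2.0 * stats.t.sf(t[finite_t], df[finite_t])
    p[ok & (rss == 0.0)] = 0.0  # exact-fit convention
    bad = ~ok
    for arr in (slope, intercept, stderr, rss):
        arr[bad] = np.nan
    p[bad] = np.nan
    return {"slope": slope, "intercept": intercept, "stderr": stderr,
            "p_value": p, "n": n, "df": df, "rss": rss}


def ols_fit(series: SeasonSeries, min_years: int = MIN_YEARS_DEFAULT,
            origin_year: Optional[int] = None) -> Optional[TrendFit]:
    """OLS trend of one season series; None if fewer than ``min_years`` seasons."""
    if len(series.years) < max(min_years, 3):
        return None
    origin = int(origin_year if origin_year is not None else series.years.min())
    res = batch_ols(series.years - origin, series.values[None, :])
    if not np.isfinite(res["slope"][0]):
        return None
    return TrendFit(
        slope=float(res["slope"][0]),
        intercept=float(res["intercept"][0]),
        stderr=float(res["stderr"][0]),
        p_value=float(res["p_value"][0]),
        n_years=int(res["n"][0]),
        origin_year=origin,
        df=float(res["df"][0]),
        rss=float(res["rss"][0]),
    )


def detrend_against_reference(garden: SeasonSeries, reference_fit: TrendFit,
                              reference_era: Optional[str] = None,
                              reference_metric: Optional[str] = None) -> SeasonSeries:
    """Subtract the reference's fitted line from a garden series (years unchanged)."""
    if reference_era is not None and reference_era != garden.era:
        raise ContractError(f"era mismatch: garden {garden.era!r} vs reference {reference_era!r}")
    if reference_metric is not None and reference_metric != garden.metric:
        raise ContractError(
            f"metric mismatch: garden {garden.metric!r} vs reference {reference_metric!r}")
    adjusted = garden.values - reference_fit.predict(garden.years)
    return SeasonSeries(garden.centroid_id, garden.era, garden.metric,
                        garden.years.copy(), adjusted)


def combine_stderr(slope: float, se_g: float, df_g: float,
                   se_r: float, df_r: float) -> tuple[float, float, float]:
    """Combined SE, Welch-Satterthwaite df and two-sided p for a slope difference."""
    se = float(np.hypot(se_g, se_r))
    if se == 0.0:
        return 0.0, df_g + df_r, 0.0 if slope != 0.0 else 1.0
    num = se ** 4
    den = 0.0
    if se_g > 0:
        den += se_g ** 4 / df_g
    if se_r > 0:
        den += se_r ** 4 / df_r
    df = num / den if den > 0 else df_g + df_r
    p = float(2.0 * stats.t.sf(abs(slope) / se, df))
    return se, df, p


def decoupling_test(garden: SeasonSeries, reference: SeasonSeries,
                    alpha: float = 0.05, min_years: int = MIN_YEARS_DEFAULT,
                    detrend_mode: str = "fitted_line",
                    reference_uncertainty: str = "propagate",
                    ) -> tuple[Optional[TrendFit], Optional[bool]]:
    """Detrended trend fit of a garden against its paired reference.

    Returns ``(fit, significant)`` where ``significant`` is the strict test
    ``p < alpha``; ``(None, None)`` when either series is an insufficient-data
    outcome.
    """
    if garden.era != reference.era:
        raise ContractError(f"era mismatch: {garden.era!r} vs {reference.era!r}")
    if garden.metric != reference.metric:
        raise ContractError(f"metric mismatch: {garden.metric!r} vs {reference.metric!r}")

    if detrend_mode == "paired_values":
        common, gi, ri = np.intersect1d(garden.years, reference.years, return_indices=True)
        if len(common) < max(min_years, 3):
            return None, None
        adjusted = SeasonSeries(garden.centroid_id, garden.era, garden.metric,
                                common, garden.values[gi] - reference.values[ri])
        fit = ols_fit(adjusted, min_years=min_years)
        if fit is None:
            return None, None
        return fit, bool(fit.p_value < alpha)

    origin = int(min(garden.years.min(), reference.years.min()))
    ref_fit = ols_fit(reference, min_years=min_years, origin_year=origin)
    if ref_fit is None:
        return None, None
    adjusted = detrend_against_reference(garden, ref_fit)
    fit = ols_fit(adjusted, min_years=min_years, origin_year=origin)
    if fit is None:
        return None, None
    if reference_uncertainty == "propagate":
        se, df, p = combine_stderr(fit.slope, fit.stderr, fit.df,
                                   ref_fit.stderr, ref_fit.df)
        fit = replace(fit, stderr=se, df=df, p_value=p)
    return fit, bool(fit.p_value < alpha)


# ---------------------------------------------------------------------------
# batch interface over season-metric tables (pipeline path)
# ---------------------------------------------------------------------------

def fit_era_trends(metrics: pd.DataFrame, eras: dict[str, EraDefinition],
                   min_years: int = MIN_YEARS_DEFAULT) -> pd.DataFrame:
    """OLS fits for every (centroid, era, metric) in a season-metrics table.

    Input columns: centroid_id, era, year, mean_ndvi, var_ndvi. Output is a
    long table (centroid_id, era, metric, slope, intercept, stderr, p_value,
    n_years, df, rss); series with fewer than ``min_years`` seasons are
    excluded (insufficient-data outcomes).
    """
    frames = []
    for era_name, era in eras.items():
        sub = metrics[metrics["era"] == era_name]
        if sub.empty:
            continue
        for metric, col in (("mean", "mean_ndvi"), ("variance", "var_ndvi")):
            wide = sub.pivot_table(index="centroid_id", columns="year", values=col,
                                   aggfunc="first")
            x = wide.columns.to_numpy(dtype=float) - era.year_start
            res = batch_ols(x, wide.to_numpy(dtype=float))
            frame = pd.DataFrame({
                "centroid_id": wide.index.to_numpy(),
                "era": era_name,
                "metric": metric,
                "slope": res["slope"],
                "intercept": res["intercept"],
                "stderr": res["stderr"],
                "p_value": res["p_value"],
                "n_years": res["n"].astype(int),
                "df": res["df"],
                "rss": res["rss"],
            })
            frames.append(frame[frame["n_years"] >= min_years])
    if not frames:
        return pd.DataFrame(columns=["centroid_id", "era", "metric", "slope", "intercept",
                                     "stderr", "p_value", "n_years", "df", "rss"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["centroid_id", "era", "metric"], kind="stable").reset_index(drop=True)


def detrended_garden_fits(garden_fits: pd.DataFrame, reference_fits: pd.DataFrame,
                          pairs: pd.DataFrame, alpha: float,
                          metrics: Optional[pd.DataFrame] = None,
                          eras: Optional[dict[str, EraDefinition]] = None,
                          min_years: int = MIN_YEARS_DEFAULT,
                          detrend_mode: str = "fitted_line",
                          reference_uncertainty: str = "propagate") -> pd.DataFrame:
    """Detrended fits for all gardens, vectorized over the trend tables.

    ``fitted_line`` works purely on the fitted-trend tables (detrended slope
    = garden slope - reference slope; residuals are the garden's own, so the
    standard error and df come from the garden fit, optionally combined with
    the reference fit's). ``paired_values`` needs the raw season ``metrics``
    table to difference values on common years.
    """
    if detrend_mode == "paired_values":
        if metrics is None or eras is None:
            raise ContractError("paired_values mode needs the season metrics table and eras")
        return _paired_values_fits(metrics, pairs, alpha, eras, min_years)

    merged = garden_fits.merge(pairs, left_on="centroid_id", right_on="garden_id")
    merged = merged.merge(
        reference_fits, left_on=["reference_id", "era", "metric"],
        right_on=["centroid_id", "era", "metric"], suffixes=("", "_ref"))
    slope = merged["slope"] - merged["slope_ref"]
    intercept = merged["intercept"] - merged["intercept_ref"]
    se_g = merged["stderr"].to_numpy(dtype=float)
    se_r = merged["stderr_ref"].to_numpy(dtype=float)
    df_g = merged["df"].to_numpy(dtype=float)
    df_r = merged["df_ref"].to_numpy(dtype=float)
    if reference_uncertainty == "propagate":
        se = np.hypot(se_g, se_r)
        with np.errstate(invalid="ignore", divide="ignore"):
            den = np.where(se_g > 0, se_g ** 4 / df_g, 0.0) + np.where(se_r > 0, se_r ** 4 / df_r, 0.0)
            df = np.where(den > 0, se ** 4 / den, df_g + df_r)
            t = np.abs(slope) / se
        p = np.where(se > 0, 2.0 * stats.t.sf(np.where(se > 0, t, 0.0), df),
                     np.where(slope != 0, 0.0, 1.0))
    else:
        se, df = se_g, df_g
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.abs(slope) / se
        p = np.where(se > 0, 2.0 * stats.t.sf(np.where(se > 0, t, 0.0), df),
                     np.where(merged["rss"].to_numpy() == 0.0, 0.0, np.nan))
    out = pd.DataFrame({
        "garden_id": merged["garden_id"],
        "era": merged["era"],
        "metric": merged["metric"],
        "slope": slope,
        "intercept": intercept,
        "stderr": se,
        "p_value": p,
        "n_years": merged["n_years"],
        "df": df,
    })
    out["significant"] = out["p_value"] < alpha
    return out.sort_values(["garden_id", "era", "metric"], kind="stable").reset_index(drop=True)


def _paired_values_fits(metrics: pd.DataFrame, pairs: pd.DataFrame, alpha: float,
                        eras: dict[str, EraDefinition], min_years: int) -> pd.DataFrame:
    value_cols = {"mean": "mean_ndvi", "variance": "var_ndvi"}
    garden_side = metrics.merge(pairs, left_on="centroid_id", right_on="garden_id")
    merged = garden_side.merge(
        metrics, left_on=["reference_id", "era", "year"],
        right_on=["centroid_id", "era", "year"], suffixes=("", "_ref"))
    frames = []
    for metric, col in value_cols.items():
        adj = merged[["garden_id", "era", "year"]].copy()
        adj["value"] = merged[col] - merged[f"{col}_ref"]
        for era_name, era in eras.items():
            sub = adj[adj["era"] == era_name]
            if sub.empty:
                continue
            wide = sub.pivot_table(index="garden_id", columns="year", values="value",
                                   aggfunc="first")
            x = wide.columns.to_numpy(dtype=float) - era.year_start
            res = batch_ols(x, wide.to_numpy(dtype=float))
            frame = pd.DataFrame({
                "garden_id": wide.index.to_numpy(),
                "era": era_name,
                "metric": metric,
                "slope": res["slope"],
                "intercept": res["intercept"],
                "stderr": res["stderr"],
                "p_value": res["p_value"],
                "n_years": res["n"].astype(int),
                "df": res["df"],
            })
            frames.append(frame[frame["n_years"] >= min_years])
    if not frames:
        return pd.DataFrame(columns=["garden_id", "era", "metric", "slope", "intercept",
                                     "stderr", "p_value", "n_years", "df", "significant"])
    out = pd.concat(frames, ignore_index=True)
    out["significant"] = out["p_value"] < alpha
    return out.sort_values(["garden_id", "era", "metric"], kind="stable").reset_index(drop=True)
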