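"""Growing-season filtering, era assignment and per-season NDVI metrics.

The analysis universe is: observations within the May-September growing
season, at centroids within ``village_radius`` of the nearest village or
hamlet center, assigned to a sensor era (E1 = Landsat 5 / 1990-2011,
E2 = Landsat 8 / 2013-2024; the 2012 gap year belongs to neither). Each
surviving (centroid, era, year) group is reduced to its season-mean NDVI
(greening metric) and within-season NDVI variance (diversification metric).
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import GROWING_SEASON_MONTHS, EraDefinition, default_eras
from .errors import ConfigurationError

log = logging.getLogger(__name__)


def filter_growing_season(obs: pd.DataFrame) -> pd.DataFrame:
    """Retain exactly the observations with calendar month in May-September."""
    months = pd.to_datetime(obs["date"]).dt.month
    return obs[months.isin(GROWING_SEASON_MONTHS)].copy()


def filter_village_radius(centroids: pd.DataFrame, radius: float) -> pd.DataFrame:
    """Retain gardens/references within ``radius`` meters (closed ball, <=) of
    the nearest village center; village centers pass through unchanged."""
    if radius <= 0:
        raise ConfigurationError("radius must be positive")
    villages = centroids[centroids["role"] == "village_center"]
    if villages.empty:
        raise ConfigurationError("no village_center centroid present; cannot apply radius filter")
    others = centroids["role"] != "village_center"
    keep = pd.Series(True, index=centroids.index)
    if others.any():
        tree = cKDTree(villages[["x", "y"]].to_numpy(dtype=float))
        dist, _ = tree.query(centroids.loc[others, ["x", "y"]].to_numpy(dtype=float))
        keep.loc[others] = dist <= radius
    out = centroids[keep].copy()
    log.info("village-radius filter (r=%.0f m): kept %d of %d centroids",
             radius, len(out), len(centroids))
    return out


def assign_era(sensor: str, year: int,
               eras: Optional[dict[str, EraDefinition]] = None) -> Optional[str]:
    """Era of a single observation, or None for gap-year / sensor-era mismatch."""
    eras = eras if eras is not None else default_eras()
    for name, era in eras.items():
        if sensor == era.sensor and era.year_start <= year <= era.year_end:
            return name
    return None


def with_era(obs: pd.DataFrame,
             eras: Optional[dict[str, EraDefinition]] = None) -> pd.DataFrame:
    """Vectorized era assignment; adds an ``era`` column (NaN = unassignable)."""
    eras = eras if eras is not None else default_eras()
    out = obs.copy()
    years = pd.to_datetime(out["date"]).dt.year
    era_col = pd.Series(pd.NA, index=out.index, dtype="object")
    for name, era in eras.items():
        mask = (out["sensor"] == era.sensor) & years.between(era.year_start, era.year_end)
        era_col[mask] = name
    out["era"] = era_col
    n_dropped = int(era_col.isna().sum())
    if n_dropped:
        log.info("era assignment: %d observation(s) assignable to no era", n_dropped)
    return out


def season_stats(obs: pd.DataFrame, min_obs_per_season: int = 3,
                 variance_divisor: str = "n_minus_1") -> pd.DataFrame:
    """Per-(centroid, era, year) season metrics.

    Expects observations already growing-season-filtered and era-assigned
    (an ``era`` column; rows with no era are ignored). The mean is the
    arithmetic season mean; the variance is the unbiased sample variance
    (divisor n-1) by default, or the population variance (divisor n) when
    ``variance_divisor="n"``. Groups with fewer than ``min_obs_per_season``
    observations are omitted (and counted in the log).
    """
    ddof = 1 if variance_divisor == "n_minus_1" else 0
    valid = obs.dropna(subset=["era"])
    work = valid[["centroid_id", "era", "ndvi"]].copy()
    work["year"] = pd.to_datetime(valid["date"]).dt.year
    grouped = work.groupby(["centroid_id", "era", "year"], sort=True)["ndvi"]
    stats = grouped.agg(mean_ndvi="mean", n_obs="size")
    stats["var_ndvi"] = grouped.var(ddof=ddof)
    stats = stats.reset_index()
    enough = stats["n_obs"] >= min_obs_per_season
    n_omitted = int((~enough).sum())
    if n_omitted:
        log.info("season_stats: omitted %d season group(s) with n < %d",
                 n_omitted, min_obs_per_season)
    out = stats[enough].reset_index(drop=True)
    return out[["centroid_id", "era", "year", "mean_ndvi", "var_ndvi", "n_obs"]]
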