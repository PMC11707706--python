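"""Readers and writers for the interchange formats.

Tables travel as UTF-8 CSV with a header row and "." decimal separator;
classified garden maps are written as RFC 7946 GeoJSON FeatureCollections of
Point features. Coordinates are projected planar meters throughout (the 1 km
village radius and nearest-reference pairing are Euclidean distances);
geographic lon/lat input is rejected.

All readers validate and reject rather than coerce: a malformed row raises a
named :mod:`gardentrends.errors` exception identifying the row and value.
Row numbers in messages are 1-based data rows (header excluded).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    CoordinateError,
    DateFormatError,
    DuplicateIdError,
    GeographicCoordinateError,
    MissingColumnError,
    NdviRangeError,
    ReferentialError,
    UnknownRoleError,
    UnknownSensorError,
)

CENTROID_ROLES = ("garden", "reference", "village_center")
SENSORS = ("L5", "L8")

CENTROID_COLUMNS = ["centroid_id", "role", "x", "y"]
OBSERVATION_COLUMNS = ["centroid_id", "date", "sensor", "ndvi"]


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing required column(s) {missing}")


def _rows(mask: pd.Series) -> list[int]:
    # 1-based data-row numbers for error messages
    return [int(i) + 1 for i in np.flatnonzero(np.asarray(mask))]


def validate_centroids(df: pd.DataFrame, *, assume_projected: bool = False,
                       source: str = "<centroids>") -> pd.DataFrame:
    """Validate an in-memory centroid table and return it with clean dtypes."""
    _require_columns(df, CENTROID_COLUMNS, source)
    df = df.copy().reset_index(drop=True)
    df["centroid_id"] = df["centroid_id"].astype(str)

    dup = df["centroid_id"][df["centroid_id"].duplicated()]
    if not dup.empty:
        raise DuplicateIdError(
            f"{source}: duplicate centroid_id value(s): {sorted(dup.unique().tolist())}"
        )

    bad_role = ~df["role"].isin(CENTROID_ROLES)
    if bad_role.any():
        i = _rows(bad_role)[0]
        raise UnknownRoleError(
            f"{source}: row {i}: unknown role {df['role'].iloc[i - 1]!r} "
            f"(expected one of {list(CENTROID_ROLES)})"
        )

    for col in ("x", "y"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(values.to_numpy(dtype=float, na_value=np.nan))
        if bad.any():
            i = _rows(bad)[0]
            raise CoordinateError(
                f"{source}: row {i}: non-numeric or non-finite {col} value "
                f"{df[col].iloc[i - 1]!r}"
            )
        df[col] = values.astype(float)

    if not assume_projected and len(df) > 0:
        if df["x"].abs().le(180).all() and df["y"].abs().le(90).all():
            raise GeographicCoordinateError(
                f"{source}: coordinates look like geographic lon/lat degrees; "
                "projected planar meters are required (the 1 km radius and "
                "nearest-reference pairing are Euclidean). Reproject, or pass "
                "assume_projected=True if the values really are meters."
            )
    return df


def read_centroids(path, *, assume_projected: bool = False) -> pd.DataFrame:
    """Read and validate a centroid CSV (centroid_id, role, x, y)."""
    df = pd.read_csv(path, dtype={"centroid_id": str, "role": str})
    return validate_centroids(df, assume_projected=assume_projected, source=str(path))


def write_centroids(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=CENTROID_COLUMNS)


def validate_observations(df: pd.DataFrame, *, source: str = "<observations>") -> pd.DataFrame:
    """Validate an in-memory observation table; parses dates to datetime64."""
    _require_columns(df, OBSERVATION_COLUMNS, source)
    df = df.copy().reset_index(drop=True)
    df["centroid_id"] = df["centroid_id"].astype(str)

    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad = dates.isna()
    if bad.any():
        i = _rows(bad)[0]
        raise DateFormatError(
            f"{source}: row {i}: unparseable ISO-8601 date {df['date'].iloc[i - 1]!r}"
        )
    df["date"] = dates

    bad_sensor = ~df["sensor"].isin(SENSORS)
    if bad_sensor.any():
        i = _rows(bad_sensor)[0]
        raise UnknownSensorError(
            f"{source}: row {i}: unknown sensor {df['sensor'].iloc[i - 1]!r} "
            f"(expected one of {list(SENSORS)})"
        )

    ndvi = pd.to_numeric(df["ndvi"], errors="coerce")
    values = ndvi.to_numpy(dtype=float, na_value=np.nan)
    bad_ndvi = ~np.isfinite(values) | (values < -1.0) | (values > 1.0)
    if bad_ndvi.any():
        i = _rows(bad_ndvi)[0]
        raise NdviRangeError(
            f"{source}: row {i}: NDVI value {df['ndvi'].iloc[i - 1]!r} outside [-1, 1]"
        )
    df["ndvi"] = ndvi.astype(float)
    return df


def read_observations(path) -> pd.DataFrame:
    """Read and validate a long-format NDVI observation CSV."""
    df = pd.read_csv(path, dtype={"centroid_id": str, "sensor": str, "date": str})
    return validate_observations(df, source=str(path))


def write_observations(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, columns=OBSERVATION_COLUMNS)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"garden_id": str, "reference_id": str})
    _require_columns(df, ["garden_id", "reference_id", "distance_m"], str(path))
    df["distance_m"] = df["distance_m"].astype(float)
    return df


def write_pairs(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=["garden_id", "reference_id", "distance_m"])


def write_trend_table(df: pd.DataFrame, path) -> None:
    """Write the per-(centroid, era, metric) trend-fit table."""
    cols = ["centroid_id", "era", "metric", "slope", "stderr", "p_value", "n_years",
            "significant"]
    df.to_csv(path, index=False, columns=[c for c in cols if c in df.columns])


_GEOJSON_PROPS = ["garden_id", "era", "mean_slope", "var_slope", "mean_p", "var_p",
                  "sig_mean", "sig_var", "label", "representative_label"]


def write_classified_geojson(results: pd.DataFrame, centroids: pd.DataFrame, path) -> None:
    """Write classified gardens as a GeoJSON FeatureCollection of Points.

    Each feature carries the per-garden trend properties (era, slopes,
    p-values, significance flags, cluster label). Coordinates are the planar
    centroid coordinates of the input table. Every ``garden_id`` must have a
    matching centroid, otherwise a :class:`ReferentialError` is raised.
    """
    coords = centroids.set_index("centroid_id")[["x", "y"]]
    missing = [g for g in results.get("garden_id", pd.Series(dtype=str)) if g not in coords.index]
    if missing:
        raise ReferentialError(
            f"garden_id(s) with no matching centroid: {sorted(set(missing))}"
        )
    features = []
    for _, row in results.iterrows():
        xy = coords.loc[row["garden_id"]]
        props = {}
        for key in _GEOJSON_PROPS:
            if key in results.columns:
                value = row[key]
                if isinstance(value, (np.floating, np.integer)):
                    value = value.item()
                if isinstance(value, float) and not np.isfinite(value):
                    value = None
                props[key] = value
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(xy["x"]), float(xy["y"])]},
            "properties": props,
        })
    collection = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(collection, fh, indent=1)
        fh.write("\n")


def import_deposit(zip_path, out_dir):  # pragma: no cover - stub by design
    """Adapter hook for the published Landsat NDVI garden deposit.

    The deposited archive (shapefiles of garden locations and village centers
    plus zipped NDVI time-series tables) has an unspecified internal layout;
    this adapter is the single place where that layout would be mapped onto
    the canonical interchange CSVs (centroids.csv, observations.csv) consumed
    by :func:`gardentrends.pipeline.run_pipeline`. It is intentionally left
    unimplemented: write the mapping against the actual archive contents.
    """
    raise NotImplementedError(
        "import_deposit is an adapter stub: map the deposited archive onto "
        "centroids.csv / observations.csv (see module docstring)."
    )
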