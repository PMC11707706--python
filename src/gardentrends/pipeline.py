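"""End-to-end orchestration: interchange files in, classified maps and
landscape summaries out.

Stage order: growing-season filter -> village-radius filter -> era assignment
-> season metrics -> nearest-reference pairing -> detrended decoupling tests
(per garden x era x metric) -> quadrant classification -> era combination ->
summary -> rendered outputs. The run is a pure function of (config, inputs):
reruns produce bit-identical CSV/JSON outputs; the manifest records the
config, input digests, package version and a conserved row-count ledger per
stage (rows in = rows retained + rows dropped).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import io as gio
from .classify import classify_table, combine_eras
from .config import PipelineConfig
from .errors import ConfigurationError
from .pairing import pair_nearest
from .seasons import filter_growing_season, filter_village_radius, season_stats, with_era
from .summary import SummaryTable, render_outputs, summarize
from .trends import detrended_garden_fits, fit_era_trends

log = logging.getLogger(__name__)


@dataclass
class StageCount:
    stage: str
    n_in: int
    n_kept: int

    @property
    def n_dropped(self) -> int:
        return self.n_in - self.n_kept


@dataclass
class PipelineResult:
    summary: SummaryTable
    classifications: pd.DataFrame
    combined: pd.DataFrame
    detrended_fits: pd.DataFrame
    season_metrics: pd.DataFrame
    pairs: pd.DataFrame
    centroids: pd.DataFrame
    stage_counts: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _regional_mean_fallback(reference_fits: pd.DataFrame) -> pd.DataFrame:
    """Mean reference trend per (era, metric), usable as a background stand-in
    for gardens whose own paired reference has no fittable series."""
    grouped = reference_fits.groupby(["era", "metric"])
    out = grouped.agg(slope=("slope", "mean"), intercept=("intercept", "mean"),
                      n_refs=("slope", "size"), slope_sd=("slope", "std")).reset_index()
    out["stderr"] = out["slope_sd"].fillna(0.0) / np.sqrt(out["n_refs"])
    out["df"] = (out["n_refs"] - 1).clip(lower=1).astype(float)
    out["n_years"] = 0
    out["rss"] = np.nan
    return out


def run_pipeline(config: Optional[PipelineConfig] = None,
                 centroids: Optional[pd.DataFrame] = None,
                 observations: Optional[pd.DataFrame] = None) -> PipelineResult:
    """Run the full analysis; reads inputs from config paths unless given in memory."""
    config = config if config is not None else PipelineConfig()
    config.validate()
    t0 = time.perf_counter()
    counts: list[StageCount] = []
    manifest: dict = {"config": _config_dict(config), "version": __version__,
                      "inputs": {}}

    if centroids is None and config.centroids_path is None:
        raise ConfigurationError("no centroid table: set centroids_path or pass a DataFrame")
    if observations is None and config.observations_path is None:
        raise ConfigurationError("no observation table: set observations_path or pass a DataFrame")
    if centroids is None:
        centroids = gio.read_centroids(config.centroids_path)
        manifest["inputs"]["centroids"] = {"path": str(config.centroids_path),
                                           "sha256": _digest(config.centroids_path)}
    else:
        centroids = gio.validate_centroids(centroids, assume_projected=True)
    if observations is None:
        observations = gio.read_observations(config.observations_path)
        manifest["inputs"]["observations"] = {"path": str(config.observations_path),
                                              "sha256": _digest(config.observations_path)}
    else:
        observations = gio.validate_observations(observations)

    # --- observation-level filters -----------------------------------------
    n0 = len(observations)
    obs = filter_growing_season(observations)
    counts.append(StageCount("filter_growing_season", n0, len(obs)))

    nc0 = len(centroids)
    kept_centroids = filter_village_radius(centroids, config.village_radius)
    counts.append(StageCount("filter_village_radius", nc0, len(kept_centroids)))

    obs_in = len(obs)
    obs = obs[obs["centroid_id"].isin(set(kept_centroids["centroid_id"]))]
    counts.append(StageCount("restrict_obs_to_kept_centroids", obs_in, len(obs)))

    obs = with_era(obs, config.eras)
    n_assignable = int(obs["era"].notna().sum())
    counts.append(StageCount("assign_era", len(obs), n_assignable))

    # --- season metrics ----------------------------------------------------
    metrics = season_stats(obs, min_obs_per_season=config.min_obs_per_season,
                           variance_divisor=config.variance_divisor)
    n_groups = int(obs.dropna(subset=["era"])
                   .groupby(["centroid_id", "era"])["date"]
                   .apply(lambda d: pd.to_datetime(d).dt.year.nunique()).sum()) \
        if n_assignable else 0
    counts.append(StageCount("season_stats", n_groups, len(metrics)))

    # --- pairing -----------------------------------------------------------
    pair_universe = centroids if config.pair_before_filter else kept_centroids
    gardens = pair_universe[pair_universe["role"] == "garden"]
    references = pair_universe[pair_universe["role"] == "reference"]
    pairs = pair_nearest(gardens, references, max_pair_distance=config.max_pair_distance)
    counts.append(StageCount("pair_nearest", len(gardens), len(pairs)))

    # --- trend fits and decoupling tests -----------------------------------
    garden_ids = set(gardens["centroid_id"])
    ref_ids = set(references["centroid_id"])
    garden_fits = fit_era_trends(metrics[metrics["centroid_id"].isin(garden_ids)],
                                 config.eras, min_years=config.min_years_per_era)
    reference_fits = fit_era_trends(metrics[metrics["centroid_id"].isin(ref_ids)],
                                    config.eras, min_years=config.min_years_per_era)

    if config.background_fallback == "regional_mean" and not reference_fits.empty:
        fallback = _regional_mean_fallback(reference_fits)
        have = reference_fits.set_index(["centroid_id", "era", "metric"]).index
        needed = pairs.merge(garden_fits, left_on="garden_id", right_on="centroid_id")
        missing = needed[~needed.set_index(["reference_id", "era", "metric"]).index.isin(have)]
        if not missing.empty:
            synth = missing[["reference_id", "era", "metric"]].drop_duplicates().merge(
                fallback, on=["era", "metric"])
            synth = synth.rename(columns={"reference_id": "centroid_id"})
            synth["p_value"] = np.nan
            reference_fits = pd.concat(
                [reference_fits, synth[reference_fits.columns]], ignore_index=True)

    detrended = detrended_garden_fits(
        garden_fits, reference_fits, pairs, alpha=config.alpha,
        metrics=metrics, eras=config.eras, min_years=config.min_years_per_era,
        detrend_mode=config.detrend_mode,
        reference_uncertainty=config.reference_uncertainty)
    counts.append(StageCount("decoupling_test", len(garden_fits), len(detrended)))

    # --- classification and summary ----------------------------------------
    classifications = classify_table(detrended)
    combined = combine_eras(classifications)
    counts.append(StageCount("classify", len(classifications),
                             int((classifications["label"] != "none").sum())
                             if not classifications.empty else 0))

    n_universe = len(gardens)
    analyzed_by_era = (classifications.groupby("era")["garden_id"].nunique().to_dict()
                       if not classifications.empty else {})
    n_insufficient_by_era = {era: n_universe - n for era, n in analyzed_by_era.items()}
    summary = summarize(classifications, combined, n_gardens_universe=n_universe,
                        n_insufficient_by_era=n_insufficient_by_era)

    manifest["stage_counts"] = [
        {"stage": c.stage, "n_in": c.n_in, "n_kept": c.n_kept, "n_dropped": c.n_dropped}
        for c in counts
    ]
    manifest["n_gardens_universe"] = n_universe

    result = PipelineResult(summary=summary, classifications=classifications,
                            combined=combined, detrended_fits=detrended,
                            season_metrics=metrics, pairs=pairs,
                            centroids=kept_centroids, stage_counts=counts,
                            manifest=manifest)

    if config.out_dir is not None:
        _write_outputs(result, config)

    log.info("pipeline finished in %.2f s: %d gardens, %d qualifying",
             time.perf_counter() - t0, n_universe, summary.n_qualifying)
    return result


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["eras"] = {k: [v.sensor, v.year_start, v.year_end] for k, v in config.eras.items()}
    return d


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    render_outputs(result.summary, result.classifications, result.combined,
                   result.centroids, out)
    gio.write_pairs(result.pairs, out / "pairs.csv")
    fits = result.detrended_fits.rename(columns={"garden_id": "centroid_id"})
    gio.write_trend_table(fits, out / "detrended_trends.csv")
    result.classifications.to_csv(out / "classification.csv", index=False)
    result.combined.to_csv(out / "classification_combined.csv", index=False)
    pd.DataFrame(result.manifest["stage_counts"]).to_csv(out / "stage_counts.csv", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
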