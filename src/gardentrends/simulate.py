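"""Synthetic scene generator.

Emulates the statistical structure the pipeline assumes in a Brandenburg-like
village landscape so that every downstream stage is testable without the
satellite deposit: village centers with gardens and abandoned-land-use
references scattered within the village radius, per-year Poisson observation
counts inside the May-September window over 1990-2024 (Landsat 5 through
2012, Landsat 8 afterwards, so the 2012 gap year is assignable to no era), a
single-harmonic seasonal NDVI curve peaking in mid-July, a shared linear
background greening trend and background variance trend, garden-specific
injected deviations delta (season-mean slope) and gamma (within-season
variance slope) drawn per cluster label, i.i.d. Gaussian observation noise
and random missingness.

Generative model for garden g, year y (offset t = y - y0), day offset d
within the season window::

    NDVI = mu0 + s(d) + (beta_bg + delta_g) * t + eps,
    s(d) = A * cos(2*pi*(d - 76) / 365.25),
    eps ~ Normal(0, sigma_g(y)^2),
    sigma_g(y)^2 = max(eps_floor * sigma0^2, sigma0^2 + (gamma_bg + gamma_g) * t)

so the within-season variance of the observations has the linear year trend
gamma_bg + gamma_g on top of a constant seasonal-curve contribution;
references use delta = gamma = 0. Values are clipped to [-1, 1] (the default
world keeps clipping events below 1% so the linear model stays honest).
Everything is reproducible under a fixed seed.

The generator's noise and seasonal forms are stand-ins — no distributional
description of real garden NDVI exists here — so all testing against it is
recovery-based (does the pipeline recover the injected truth), not
value-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, default_eras
from .errors import ConfigurationError
from . import io as gio

SEASON_DAYS = 153           # May 1 .. Sep 30 inclusive
SEASON_PEAK_OFFSET = 76.0   # days after May 1 (~July 16)
L8_FIRST_YEAR = 2013        # Landsat 8 era start; 2012 stays on L5 => gap year


@dataclass
class SimulatedScene:
    """Centroids + observations + per-garden ground truth of one simulation."""

    centroids: pd.DataFrame
    observations: pd.DataFrame
    truth: pd.DataFrame          # garden_id, delta, gamma, label
    n_clipped: int = 0
    config: SimulationConfig = field(default_factory=SimulationConfig)

    @property
    def truth_map(self) -> dict[str, tuple[float, float, str]]:
        return {
            row.garden_id: (row.delta, row.gamma, row.label)
            for row in self.truth.itertuples()
        }


def seasonal_value(day_offset, amplitude: float) -> np.ndarray:
    """Seasonal NDVI component at ``day_offset`` days after May 1."""
    day_offset = np.asarray(day_offset, dtype=float)
    return amplitude * np.cos(2.0 * np.pi * (day_offset - SEASON_PEAK_OFFSET) / 365.25)


def seasonal_variance(amplitude: float) -> float:
    """Within-season variance contributed by the seasonal curve alone
    (uniform day sampling over the 153-day window)."""
    d = np.arange(SEASON_DAYS, dtype=float)
    return float(np.var(seasonal_value(d, amplitude)))


def detrended_variance_slope_se(config: SimulationConfig, n_seasons: int,
                                obs_per_season: float | None = None) -> float:
    """Approximate standard error of the detrended within-season-variance slope.

    Normal approximation: the season sample variance V_hat of n observations
    has sd ~ sqrt(2/(n-1)) * Var_tot with Var_tot the seasonal-curve variance
    plus the noise variance; the detrended slope over k seasons (x centered,
    Sxx = k(k^2-1)/12) differences two independent fits, doubling the
    variance. Used to size injected gamma effects ("5x the estimator SE").
    """
    n = obs_per_season if obs_per_season is not None else (
        config.obs_per_season * (1.0 - config.missing_rate))
    var_tot = seasonal_variance(config.seasonal_amplitude) + config.noise_sd ** 2
    sd_vhat = np.sqrt(2.0 / (n - 1.0)) * var_tot
    sxx = n_seasons * (n_seasons ** 2 - 1) / 12.0
    return float(sd_vhat * np.sqrt(2.0 / sxx))


def _place_in_disk(rng, centers, radius, k):
    """k points uniform in the union-of-disks around randomly chosen centers."""
    which = rng.integers(0, len(centers), size=k)
    r = radius * np.sqrt(rng.random(k))
    theta = rng.random(k) * 2.0 * np.pi
    return (centers[which, 0] + r * np.cos(theta),
            centers[which, 1] + r * np.sin(theta))


def _place_decoys(rng, centers, radius, k, x0, y0, extent, max_tries=100_000):
    xs, ys = [], []
    tries = 0
    while len(xs) < k:
        if tries >= max_tries:
            raise ConfigurationError(
                "could not place out-of-radius decoys; domain too small relative "
                "to village_radius")
        x = x0 + rng.random() * extent
        y = y0 + rng.random() * extent
        tries += 1
        d2 = (centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2
        if d2.min() > radius ** 2:
            xs.append(x)
            ys.append(y)
    return np.array(xs), np.array(ys)


def generate_scene(config: SimulationConfig | None = None) -> SimulatedScene:
    """Generate one synthetic scene from a validated :class:`SimulationConfig`."""
    config = config if config is not None else SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- centroid placement ------------------------------------------------
    vx = config.origin_x + rng.random(config.n_villages) * config.domain_extent
    vy = config.origin_y + rng.random(config.n_villages) * config.domain_extent
    centers = np.column_stack([vx, vy])

    gx, gy = _place_in_disk(rng, centers, config.village_radius, config.n_gardens)
    rx, ry = _place_in_disk(rng, centers, config.village_radius, config.n_references)
    if config.n_decoy_gardens:
        dx, dy = _place_decoys(rng, centers, config.village_radius,
                               config.n_decoy_gardens, config.origin_x,
                               config.origin_y, config.domain_extent)
        gx = np.concatenate([gx, dx])
        gy = np.concatenate([gy, dy])

    n_gardens = config.n_gardens + config.n_decoy_gardens
    garden_ids = np.array([f"g{i:05d}" for i in range(n_gardens)])
    ref_ids = np.array([f"r{i:05d}" for i in range(config.n_references)])
    village_ids = np.array([f"v{i:03d}" for i in range(config.n_villages)])
    centroids = pd.DataFrame({
        "centroid_id": np.concatenate([garden_ids, ref_ids, village_ids]),
        "role": (["garden"] * n_gardens + ["reference"] * config.n_references
                 + ["village_center"] * config.n_villages),
        "x": np.concatenate([gx, rx, vx]),
        "y": np.concatenate([gy, ry, vy]),
    })

    # --- per-garden truth --------------------------------------------------
    mix_labels = sorted(config.cluster_mix)
    mix_p = np.array([config.cluster_mix[l] for l in mix_labels], dtype=float)
    mix_p = mix_p / mix_p.sum()
    labels = rng.choice(mix_labels, size=n_gardens, p=mix_p)
    delta = np.array([config.garden_mean_slope_by_cluster.get(l, 0.0) for l in labels])
    gamma = np.array([config.garden_var_slope_by_cluster.get(l, 0.0) for l in labels])
    truth = pd.DataFrame({"garden_id": garden_ids, "delta": delta, "gamma": gamma,
                          "label": labels})

    # --- observations ------------------------------------------------------
    all_ids = np.concatenate([garden_ids, ref_ids])
    all_delta = np.concatenate([delta, np.zeros(config.n_references)])
    all_gamma = np.concatenate([gamma, np.zeros(config.n_references)])
    years = np.arange(config.year_start, config.year_end + 1)
    n_cent, n_years = len(all_ids), len(years)

    counts = rng.poisson(config.obs_per_season, size=(n_cent, n_years))
    total = int(counts.sum())
    cent_idx = np.repeat(np.arange(n_cent), counts.sum(axis=1))
    year_idx = np.concatenate([np.repeat(np.arange(n_years), row) for row in counts]) \
        if total else np.empty(0, dtype=int)

    window_days = 365 if config.emit_off_season else SEASON_DAYS
    day_offset = rng.integers(0, window_days, size=total)

    t = years[year_idx] - config.year_start
    sigma0_sq = config.noise_sd ** 2
    sigma_sq = np.maximum(config.epsilon_floor * sigma0_sq,
                          sigma0_sq + (config.background_var_slope + all_gamma[cent_idx]) * t)
    values = (config.baseline_mean
              + seasonal_value(day_offset, config.seasonal_amplitude)
              + (config.background_mean_slope + all_delta[cent_idx]) * t
              + rng.standard_normal(total) * np.sqrt(sigma_sq))

    keep = rng.random(total) >= config.missing_rate
    values = values[keep]
    cent_idx = cent_idx[keep]
    year_idx = year_idx[keep]
    day_offset = day_offset[keep]

    n_clipped = int(((values < -1.0) | (values > 1.0)).sum())
    if config.clip:
        values = np.clip(values, -1.0, 1.0)

    season_start = np.array([f"{y}-05-01" for y in years], dtype="datetime64[D]")
    dates = season_start[year_idx] + day_offset.astype("timedelta64[D]")
    sensor = np.where(years[year_idx] >= L8_FIRST_YEAR, "L8", "L5")

    observations = pd.DataFrame({
        "centroid_id": all_ids[cent_idx],
        "date": pd.to_datetime(dates),
        "sensor": sensor,
        "ndvi": values,
    }).sort_values(["centroid_id", "date"], kind="stable").reset_index(drop=True)

    return SimulatedScene(centroids=centroids, observations=observations,
                          truth=truth, n_clipped=n_clipped, config=config)


def write_scene(scene: SimulatedScene, out_dir) -> None:
    """Write centroids.csv, observations.csv and truth.csv to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gio.write_centroids(scene.centroids, out / "centroids.csv")
    gio.write_observations(scene.observations, out / "observations.csv")
    scene.truth.to_csv(out / "truth.csv", index=False)
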