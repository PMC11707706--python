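import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import gardentrends as gt

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scene() -> gt.SimulatedScene:
    """A small deterministic scene with all four clusters present."""
    cfg = gt.SimulationConfig(n_gardens=80, n_references=25, n_villages=4,
                              domain_extent=8000.0, seed=42)
    return gt.generate_scene(cfg)


@pytest.fixture(scope="session")
def small_result(small_scene) -> gt.PipelineResult:
    return gt.run_pipeline(gt.PipelineConfig(),
                           centroids=small_scene.centroids,
                           observations=small_scene.observations)


@pytest.fixture
def centroid_table() -> pd.DataFrame:
    """A tiny valid centroid table in projected-meter coordinates."""
    return pd.DataFrame({
        "centroid_id": ["g1", "g2", "r1", "v1"],
        "role": ["garden", "garden", "reference", "village_center"],
        "x": [3300100.0, 3300400.0, 3300250.0, 3300200.0],
        "y": [5700100.0, 5700300.0, 5700150.0, 5700200.0],
    })


@pytest.fixture
def observation_table() -> pd.DataFrame:
    rng = np.random.default_rng(3)
    rows = []
    for cid in ("g1", "g2", "r1"):
        for year in (1995, 1996, 2015):
            for day in (5, 50, 110):
                rows.append({
                    "centroid_id": cid,
                    "date": f"{year}-05-01",
                    "sensor": "L5" if year < 2013 else "L8",
                    "ndvi": float(np.round(rng.uniform(0.1, 0.8), 4)),
                })
    df = pd.DataFrame(rows)
    df["date"] = pd.to_datetime(df["date"]) + pd.to_timedelta(
        np.tile([5, 50, 110], len(df) // 3), unit="D")
    return df
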