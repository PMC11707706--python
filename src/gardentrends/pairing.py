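"""Nearest-reference assignment: each garden gets the closest abandoned-land-use
reference centroid (Euclidean, centroid-to-centroid; ties broken by the
lexicographically smallest reference_id; many gardens may share one reference).
"""
from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError

log = logging.getLogger(__name__)


def pair_nearest(gardens: pd.DataFrame, references: pd.DataFrame,
                 max_pair_distance: Optional[float] = None,
                 chunk_size: int = 512) -> pd.DataFrame:
    """Pair every garden with its nearest reference centroid.

    A chunked exact all-pairs scan (deterministic, handles distance ties by
    reference_id order); adequate at deposit scale. Gardens whose nearest
    reference is farther than ``max_pair_distance`` (if set) are dropped with
    a logged count.
    """
    if references.empty:
        raise ConfigurationError("reference table is empty; cannot pair gardens")
    refs = references.sort_values("reference_id" if "reference_id" in references else "centroid_id",
                                  kind="stable")
    refs = refs.reset_index(drop=True)
    ref_ids = refs["centroid_id"].to_numpy()
    rx = refs["x"].to_numpy(dtype=float)
    ry = refs["y"].to_numpy(dtype=float)

    gx = gardens["x"].to_numpy(dtype=float)
    gy = gardens["y"].to_numpy(dtype=float)
    n = len(gardens)
    nearest = np.empty(n, dtype=int)
    distance = np.empty(n, dtype=float)
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        d2 = (gx[start:stop, None] - rx[None, :]) ** 2 + (gy[start:stop, None] - ry[None, :]) ** 2
        j = np.argmin(d2, axis=1)  # first minimum = smallest reference_id on ties
        nearest[start:stop] = j
        distance[start:stop] = np.sqrt(d2[np.arange(stop - start), j])

    out = pd.DataFrame({
        "garden_id": gardens["centroid_id"].to_numpy(),
        "reference_id": ref_ids[nearest],
        "distance_m": distance,
    })
    if max_pair_distance is not None:
        far = out["distance_m"] > max_pair_distance
        if far.any():
            log.info("pair_nearest: dropped %d garden(s) with nearest reference "
                     "beyond %.0f m", int(far.sum()), max_pair_distance)
        out = out[~far].reset_index(drop=True)
    return out
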