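"""Significance gating and four-quadrant trend classification.

A garden qualifies for a cluster label only when BOTH detrended trends (the
greening slope of season-mean NDVI and the diversification slope of
within-season NDVI variance) are individually significant. The label is then
the sign quadrant of (mean slope, variance slope):

    A intensification    (+, -)   greening with homogenizing vegetation
    B naturalization     (+, +)   greening with rising phenological variation
    C artificialization  (-, -)   green-feature loss, e.g. soil sealing
    D ruralization       (-, +)   browning with rising seasonal variability

Slope magnitude ("strength") is carried through to the outputs but does not
affect cluster membership, which is sign-only.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import CLUSTER_LABELS, NO_LABEL
from .errors import ContractError

log = logging.getLogger(__name__)


def classify(mean_slope: float, var_slope: float, sig_mean: bool, sig_var: bool) -> str:
    """Cluster label for one garden-era trend pair (``none`` unless both significant)."""
    if not (sig_mean and sig_var):
        return NO_LABEL
    if mean_slope == 0.0 or var_slope == 0.0:
        # measure-zero on continuous data; possible only on degenerate input
        log.warning("significant trend pair with an exactly-zero slope "
                    "(mean=%r, var=%r): no quadrant assigned", mean_slope, var_slope)
        return NO_LABEL
    if mean_slope > 0:
        return CLUSTER_LABELS["A"] if var_slope < 0 else CLUSTER_LABELS["B"]
    return CLUSTER_LABELS["C"] if var_slope < 0 else CLUSTER_LABELS["D"]


def significance_category(sig_mean: bool, sig_var: bool) -> str:
    """"both" / "at_least_one" / "none"; insufficient-data outcomes count as
    not significant. "both" implies "at_least_one" in all summary accounting."""
    if sig_mean and sig_var:
        return "both"
    if sig_mean or sig_var:
        return "at_least_one"
    return "none"


def classify_table(detrended: pd.DataFrame) -> pd.DataFrame:
    """Per-(garden, era) classification from a long detrended-fit table.

    Input columns: garden_id, era, metric ("mean"/"variance"), slope, p_value,
    significant. Gardens with only one metric fit in an era are treated as
    insufficient and excluded. Output columns: garden_id, era, mean_slope,
    var_slope, mean_p, var_p, sig_mean, sig_var, label.
    """
    if detrended.empty:
        return pd.DataFrame(columns=["garden_id", "era", "mean_slope", "var_slope",
                                     "mean_p", "var_p", "sig_mean", "sig_var", "label"])
    wide = detrended.pivot_table(
        index=["garden_id", "era"], columns="metric",
        values=["slope", "p_value", "significant"], aggfunc="first")
    wide = wide.dropna(subset=[("slope", "mean"), ("slope", "variance")])
    out = pd.DataFrame({
        "garden_id": wide.index.get_level_values("garden_id"),
        "era": wide.index.get_level_values("era"),
        "mean_slope": wide[("slope", "mean")].to_numpy(dtype=float),
        "var_slope": wide[("slope", "variance")].to_numpy(dtype=float),
        "mean_p": wide[("p_value", "mean")].to_numpy(dtype=float),
        "var_p": wide[("p_value", "variance")].to_numpy(dtype=float),
        "sig_mean": wide[("significant", "mean")].to_numpy(dtype=bool),
        "sig_var": wide[("significant", "variance")].to_numpy(dtype=bool),
    })
    out["label"] = [
        classify(ms, vs, sm, sv)
        for ms, vs, sm, sv in zip(out["mean_slope"], out["var_slope"],
                                  out["sig_mean"], out["sig_var"])
    ]
    return out.sort_values(["garden_id", "era"], kind="stable").reset_index(drop=True)


def combine_eras(per_era: pd.DataFrame) -> pd.DataFrame:
    """Combine per-era classifications into the map-ready per-garden set.

    A garden qualifies iff it carries a cluster label in at least one era.
    Both per-era labels are retained (columns ``label_E1`` / ``label_E2`` for
    the eras present); when both eras qualify, the representative label comes
    from the era with the smaller max(mean_p, var_p), ties going to the
    earlier era. Duplicate (garden, era) records raise a ContractError.
    """
    if per_era.duplicated(subset=["garden_id", "era"]).any():
        dups = per_era[per_era.duplicated(subset=["garden_id", "era"], keep=False)]
        raise ContractError(
            f"duplicate era records for garden(s): {sorted(dups['garden_id'].unique().tolist())}")
    labeled = per_era[per_era["label"] != NO_LABEL].copy()
    if labeled.empty:
        return pd.DataFrame(columns=["garden_id", "representative_label",
                                     "representative_era", "n_qualifying_eras"])
    labeled["max_p"] = np.maximum(labeled["mean_p"], labeled["var_p"])
    labeled = labeled.sort_values(["garden_id", "max_p", "era"], kind="stable")
    rep = labeled.groupby("garden_id", sort=True).first().reset_index()
    rep = rep.rename(columns={"label": "representative_label", "era": "representative_era"})
    rep["n_qualifying_eras"] = labeled.groupby("garden_id", sort=True).size().to_numpy()
    per_garden_labels = labeled.pivot(index="garden_id", columns="era", values="label")
    for era in sorted(per_garden_labels.columns):
        rep[f"label_{era}"] = per_garden_labels[era].reindex(rep["garden_id"]).to_numpy()
    cols = (["garden_id", "representative_label", "representative_era", "n_qualifying_eras",
             "mean_slope", "var_slope", "mean_p", "var_p"]
            + [f"label_{e}" for e in sorted(per_garden_labels.columns)])
    return rep[[c for c in cols if c in rep.columns]]
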