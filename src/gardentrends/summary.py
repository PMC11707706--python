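"""Landscape-level summaries and map/plot exports.

Percentages mirror the study's reporting: per era, the share of garden
centroids with two significant detrended trends ("both"), the share with at
least one, and the cluster composition (denominator = both-significant
gardens of that era). The primary denominator is the gardens analyzed in the
era (sufficient data for both fits); an alternative denominator that also
counts insufficient-data gardens is emitted alongside, since the study does
not state which it used.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import significance_category
from .config import CLUSTER_LABELS, NO_LABEL
from . import io as gio

ALL_LABELS = list(CLUSTER_LABELS.values())


@dataclass
class EraSummary:
    era: str
    n_gardens_analyzed: int = 0
    n_insufficient: int = 0
    n_both_significant: int = 0
    n_at_least_one: int = 0
    n_tests: int = 0
    pct_both_significant: float = 0.0
    pct_at_least_one: float = 0.0
    #: alternative denominator including insufficient-data gardens
    pct_both_significant_incl_insufficient: float = 0.0
    pct_at_least_one_incl_insufficient: float = 0.0
    cluster_counts: dict = field(default_factory=dict)
    #: shares over both-significant gardens; empty when that denominator is 0
    cluster_shares: dict = field(default_factory=dict)
    cluster_shares_defined: bool = False


@dataclass
class SummaryTable:
    eras: dict = field(default_factory=dict)          # era -> EraSummary
    n_gardens_universe: int = 0
    #: gardens qualifying (cluster label in >= 1 era), counted once per garden
    n_qualifying: int = 0
    #: the same gardens counted once per qualifying era (the other convention)
    n_qualifying_era_records: int = 0
    pct_qualifying_of_all: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else 0.0


def summarize(classifications: pd.DataFrame, combined: pd.DataFrame,
              n_gardens_universe: int | None = None,
              n_insufficient_by_era: dict[str, int] | None = None) -> SummaryTable:
    """Build the landscape summary from per-era and combined classifications.

    ``n_gardens_universe`` is the number of garden centroids in the analysis
    universe (post village-radius filter); defaults to the gardens appearing
    in ``classifications``. ``n_insufficient_by_era`` gives, per era, gardens
    of the universe without fittable detrended series.
    """
    table = SummaryTable()
    gardens_seen = (classifications["garden_id"].nunique()
                    if not classifications.empty else 0)
    table.n_gardens_universe = (n_gardens_universe if n_gardens_universe is not None
                                else gardens_seen)
    n_insufficient_by_era = n_insufficient_by_era or {}

    eras = sorted(classifications["era"].unique()) if not classifications.empty else []
    for era in eras:
        sub = classifications[classifications["era"] == era]
        cats = [significance_category(sm, sv)
                for sm, sv in zip(sub["sig_mean"], sub["sig_var"])]
        n_analyzed = len(sub)
        n_both = sum(c == "both" for c in cats)
        n_alo = sum(c in ("both", "at_least_one") for c in cats)
        n_insuff = int(n_insufficient_by_era.get(
            era, max(table.n_gardens_universe - n_analyzed, 0)))
        labeled = sub[sub["label"] != NO_LABEL]
        counts = {lab: int((labeled["label"] == lab).sum()) for lab in ALL_LABELS}
        shares_defined = n_both > 0
        shares = ({lab: _pct(c, n_both) for lab, c in counts.items()}
                  if shares_defined else {})
        table.eras[era] = EraSummary(
            era=era,
            n_gardens_analyzed=n_analyzed,
            n_insufficient=n_insuff,
            n_both_significant=n_both,
            n_at_least_one=n_alo,
            n_tests=2 * n_analyzed,
            pct_both_significant=_pct(n_both, n_analyzed),
            pct_at_least_one=_pct(n_alo, n_analyzed),
            pct_both_significant_incl_insufficient=_pct(n_both, n_analyzed + n_insuff),
            pct_at_least_one_incl_insufficient=_pct(n_alo, n_analyzed + n_insuff),
            cluster_counts=counts,
            cluster_shares=shares,
            cluster_shares_defined=shares_defined,
        )

    table.n_qualifying = len(combined) if combined is not None else 0
    table.n_qualifying_era_records = int(
        combined["n_qualifying_eras"].sum()) if table.n_qualifying else 0
    table.pct_qualifying_of_all = _pct(table.n_qualifying, table.n_gardens_universe)
    return table


def largest_remainder_round(values, decimals: int = 2, total: float = 100.0):
    """Round shares to ``decimals`` so they sum exactly to ``total``.

    Classic largest-remainder (Hare) correction: floor everything at the
    target precision, then distribute the leftover quanta to the entries with
    the largest remainders (ties by position).
    """
    values = np.asarray(values, dtype=float)
    if len(values) == 0:
        return values
    scale = 10 ** decimals
    scaled = values * scale
    floors = np.floor(scaled)
    leftover = int(round(total * scale - floors.sum()))
    order = np.argsort(-(scaled - floors), kind="stable")
    out = floors.copy()
    for i in range(abs(leftover)):
        out[order[i % len(values)]] += np.sign(leftover)
    return out / scale


def render_outputs(summary: SummaryTable, classifications: pd.DataFrame,
                   combined: pd.DataFrame, centroids: pd.DataFrame, out_dir) -> None:
    """Write summary CSV/JSON, per-era and combined GeoJSON, share table and
    the quadrant scatter plot into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary.to_dict(), fh, indent=1)
        fh.write("\n")

    rows = [dataclasses.asdict(es) for es in summary.eras.values()]
    for row in rows:
        row.pop("cluster_counts", None)
        row.pop("cluster_shares", None)
    pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)

    share_rows = []
    for era, es in summary.eras.items():
        labels = list(es.cluster_counts)
        counts = [es.cluster_counts[l] for l in labels]
        raw = [es.cluster_shares.get(l, 0.0) for l in labels]
        rounded = largest_remainder_round(raw) if es.cluster_shares_defined else [0.0] * len(labels)
        for lab, cnt, shr in zip(labels, counts, rounded):
            share_rows.append({"era": era, "label": lab, "count": cnt,
                               "share_pct": f"{shr:.2f}"})
    pd.DataFrame(share_rows, columns=["era", "label", "count", "share_pct"]).to_csv(
        out / "cluster_shares.csv", index=False)

    for era in summary.eras:
        sub = classifications[(classifications["era"] == era)
                              & (classifications["label"] != NO_LABEL)]
        gio.write_classified_geojson(sub, centroids, out / f"classified_{era}.geojson")
    comb = combined.copy()
    if not comb.empty:
        comb = comb.rename(columns={"representative_era": "era",
                                    "representative_label": "label"})
        comb["representative_label"] = comb["label"]
    gio.write_classified_geojson(comb, centroids, out / "classified_combined.geojson")

    _quadrant_scatter(classifications, out / "quadrant_scatter.png")


_CLUSTER_COLORS = {
    "A_intensification": "#1b9e77",
    "B_naturalization": "#7570b3",
    "C_artificialization": "#d95f02",
    "D_ruralization": "#e7298a",
}


def _quadrant_scatter(classifications: pd.DataFrame, path) -> None:
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 5))
    ax = fig.add_subplot(111)
    labeled = classifications[classifications["label"] != NO_LABEL] \
        if not classifications.empty else classifications
    for lab, color in _CLUSTER_COLORS.items():
        sub = labeled[labeled["label"] == lab] if len(labeled) else labeled
        if len(sub):
            ax.scatter(sub["mean_slope"], sub["var_slope"], s=8, alpha=0.6,
                       color=color, label=lab)
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.axvline(0.0, color="0.6", lw=0.8)
    ax.set_xlabel("detrended greening slope (NDVI / yr)")
    ax.set_ylabel("detrended within-season variance slope (1 / yr)")
    ax.set_title("Significant detrended garden trends by cluster")
    if len(labeled):
        ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
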