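"""Figure analogues of the standard report views.

Regression panels follow the convention of drawing significant (p < 0.05)
fits as solid lines and non-significant fits as dashed lines; the NMDS
biplot colours samples by habitat.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

log = logging.getLogger(__name__)

_HAB_COLORS = {"bacterioplankton": "#1f77b4", "biofilm": "#2ca02c", "soil": "#8c564b"}


def _panel(ax, x, y, fit: dict, title: str, xlabel: str, ylabel: str):
    ax.scatter(x, y, s=25, color="#444444")
    style = "-" if fit.get("significant") else "--"
    xs = pd.Series(sorted(x))
    ax.plot(xs, fit["intercept"] + fit["slope"] * xs, style, color="#d62728")
    ax.set_title(title, fontsize=9)
    ax.set_xlabel(xlabel, fontsize=8)
    ax.set_ylabel(ylabel, fontsize=8)


def make_figures(report: dict, out_dir) -> list[Path]:
    """Render available report sections to PNG files; skip missing ones."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    tables = report.get("tables", {})
    regs = report.get("regressions", {})
    beta = pd.DataFrame(tables.get("temporal_beta", []))
    decay = pd.DataFrame(tables.get("distance_decay", []))

    if not beta.empty and regs:
        fig, axes = plt.subplots(2, 3, figsize=(10, 6), constrained_layout=True)
        for j, hab in enumerate(("bacterioplankton", "biofilm", "soil")):
            b = beta[beta["habitat"] == hab]
            d = decay[decay["habitat"] == hab]
            x = _site_distances(report, b["site_id"])
            if x is None:
                continue
            _panel(axes[0, j], x, b["mean_consecutive_dissimilarity"],
                   regs.get(f"temporal_beta_vs_distance/{hab}", {}),
                   hab, "dendritic distance (km)", "temporal β")
            xd = _site_distances(report, d["site_id"])
            _panel(axes[1, j], xd, d["slope"],
                   regs.get(f"distance_decay_vs_distance/{hab}", {}),
                   hab, "dendritic distance (km)", "decay slope (per day)")
        p = out_dir / "temporal_beta_vs_distance.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        log.warning("temporal-beta panels skipped: missing statistics")

    coords = pd.DataFrame(tables.get("nmds_coordinates", []))
    if not coords.empty:
        hab_by_sample = report.get("sample_habitats", {})
        fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
        for hab, color in _HAB_COLORS.items():
            ids = [s for s, h in hab_by_sample.items() if h == hab]
            sub = coords[coords["sample_id"].isin(ids)]
            if sub.empty and not hab_by_sample:
                sub = coords  # no habitat map available: plot everything once
            ax.scatter(sub["NMDS1"], sub["NMDS2"], s=12, color=color, label=hab)
            if not hab_by_sample:
                break
        ax.legend(fontsize=7)
        stress = report.get("nmds", {}).get("stress")
        ax.set_title(f"NMDS (stress = {stress:.3f})" if stress is not None else "NMDS")
        p = out_dir / "nmds.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        log.warning("NMDS panel skipped: no coordinates in report")

    shared = pd.DataFrame(tables.get("shared_taxa", []))
    trends = report.get("shared_taxa", {}).get("trend_vs_distance", {})
    if not shared.empty and trends:
        fig, ax = plt.subplots(figsize=(5, 4), constrained_layout=True)
        for pair, grp in shared.groupby("pair"):
            x = _site_distances(report, grp["site_id"])
            if x is None:
                continue
            fit = trends.get(pair, {})
            style = "-" if fit.get("significant") else "--"
            ax.scatter(x, grp["mean_shared"], s=18, label=pair)
            xs = pd.Series(sorted(x))
            ax.plot(xs, fit["intercept"] + fit["slope"] * xs, style)
        ax.set_xlabel("dendritic distance (km)")
        ax.set_ylabel("mean shared ASVs")
        ax.legend(fontsize=7)
        p = out_dir / "shared_taxa.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    else:
        log.warning("shared-taxa panel skipped: missing statistics")

    if not written:
        log.warning("empty report: no figures produced")
    return written


def _site_distances(report: dict, site_ids) -> pd.Series | None:
    dist = report.get("site_distances")
    if not dist:
        return None
    return pd.Series([dist.get(s) for s in site_ids], index=list(site_ids))
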