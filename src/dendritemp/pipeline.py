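"""End-to-end orchestration: preprocess → dissimilarity → temporal statistics
→ inference → shared taxa, with a machine-readable JSON report.

The pipeline consumes a processed ASV count table (it never touches reads),
and is deterministic for a fixed seed and configuration: two runs on the
same inputs produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    HABITATS,
    VARIABLE_SETS,
    AsvTable,
    ValidationError,
    align,
    file_checksum,
)
from .dissimilarity import bray_curtis
from .inference import centroid_distance, nmds, ols, partial_regression, permanova
from .preprocess import RarefactionSpec, percentile_depth, rarefy, to_relative_abundance, zscore
from .shared import shared_taxa_table, sharing_trend
from .temporal import (
    distance_decay_table,
    env_variability_table,
    linkage_table,
    temporal_beta_table,
)

log = logging.getLogger(__name__)

#: environmental variables screened one at a time as drivers of aquatic
#: community variability (with the full-set variability used for soil)
FOCAL_ENV_DRIVERS = {
    "water_chemistry": ["pH", "SUVA"],
    "physical": ["temperature"],
}


@dataclass(frozen=True)
class PipelineConfig:
    """Run-level knobs; defaults mirror the analysis conventions."""

    rarefaction_depth: int | None = None  # None = lower percentile of totals
    rarefaction_percentile: float = 5.0
    passthrough_below_depth: bool = True
    time_unit: str = "days"
    n_permutations: int = 999
    nmds_k: int = 2
    nmds_restarts: int = 20
    nmds_max_iter: int = 300
    seed: int = 0


def _reg(fit) -> dict:
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "p_value": fit.p_value,
        "n": fit.n,
        "significant": bool(fit.significant),
    }


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def run_analysis(table: AsvTable, meta: pd.DataFrame, env: pd.DataFrame,
                 config: PipelineConfig | None = None,
                 checksums: dict | None = None) -> dict:
    """Full analysis on validated in-memory inputs; returns the report bundle.

    The report is a nested dict (JSON-serializable) whose every statistic is
    keyed by the module operation that produced it; ``tables`` holds the
    tidy per-site frames as records.
    """
    config = config or PipelineConfig()
    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items()},
        "input_checksums": checksums or {},
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                out = fn()
            except Exception as e:  # abort with stage name and offending entity
                raise StageError(name, e) from e
            report["stages"][name] = "ok"
            return out
        return deco

    @stage("align")
    def _aligned():
        t, m, rep = align(table, meta)
        if not rep.clean:
            log.info("alignment dropped samples: table-only=%s meta-only=%s",
                     rep.only_in_table, rep.only_in_metadata)
        return t, m

    table_a, meta_a = _aligned

    @stage("rarefy")
    def _rarefied():
        depth = config.rarefaction_depth or percentile_depth(table_a, config.rarefaction_percentile)
        spec = RarefactionSpec(depth, config.passthrough_below_depth, config.seed)
        rt = rarefy(table_a, spec)
        below = int((table_a.sample_totals() < depth).sum())
        report["rarefaction"] = {
            "depth": depth,
            "n_samples": rt.shape[0],
            "n_below_depth_passed_through": below if config.passthrough_below_depth else 0,
        }
        return rt

    rt = _rarefied
    meta_a = meta_a[meta_a["sample_id"].isin(rt.sample_ids)].reset_index(drop=True)
    dist_by_site = meta_a.groupby("site_id")["dendritic_distance_km"].first()
    report["site_distances"] = {s: float(d) for s, d in dist_by_site.items()}
    report["sample_habitats"] = dict(zip(meta_a["sample_id"], meta_a["habitat"]))

    @stage("dissimilarity")
    def _proportions():
        return to_relative_abundance(rt)

    p = _proportions

    @stage("temporal_statistics")
    def _temporal():
        # per-series distance matrices are small; one global matrix serves NMDS
        D_all = bray_curtis(p)
        beta = temporal_beta_table(D_all, meta_a)
        decay = distance_decay_table(D_all, meta_a, time_unit=config.time_unit)
        return D_all, beta, decay

    D_all, beta_tab, decay_tab = _temporal

    @stage("environmental_variability")
    def _envvar():
        return env_variability_table(env)

    env_tab = _envvar

    @stage("network_position_regressions")
    def _regressions():
        out = {}
        for hab in HABITATS:
            b = beta_tab[beta_tab["habitat"] == hab].set_index("site_id")
            d = decay_tab[decay_tab["habitat"] == hab].set_index("site_id")
            x = dist_by_site.loc[b.index].to_numpy()
            out[f"temporal_beta_vs_distance/{hab}"] = _reg(
                ols(b["mean_consecutive_dissimilarity"].to_numpy(), x))
            out[f"distance_decay_vs_distance/{hab}"] = _reg(
                ols(d.loc[b.index, "slope"].to_numpy(), x))
        for vs in VARIABLE_SETS:
            e = env_tab[env_tab["variable_set"] == vs].set_index("site_id")
            x = dist_by_site.loc[e.index].to_numpy()
            out[f"env_variability_vs_distance/{vs}"] = _reg(
                ols(e["mean_consecutive_distance"].to_numpy(), x))
        return out

    report["regressions"] = _regressions

    @stage("beta_vs_environment")
    def _beta_env():
        out = {}
        pairs = [("bacterioplankton", "water_chemistry"), ("biofilm", "water_chemistry"),
                 ("bacterioplankton", "physical"), ("biofilm", "physical"),
                 ("soil", "soil")]
        for hab, vs in pairs:
            b = beta_tab[beta_tab["habitat"] == hab].set_index("site_id")
            e = env_tab[env_tab["variable_set"] == vs].set_index("site_id")
            sites = b.index.intersection(e.index)
            y = b.loc[sites, "mean_consecutive_dissimilarity"].to_numpy()
            x = e.loc[sites, "mean_consecutive_distance"].to_numpy()
            z = dist_by_site.loc[sites].to_numpy()
            out[f"beta_vs_env/{hab}/{vs}"] = _reg(ols(y, x))
            out[f"beta_vs_env_partial_distance/{hab}/{vs}"] = _reg(partial_regression(y, x, z))
        return out

    report["environment_regressions"] = _beta_env

    @stage("permanova")
    def _permanova():
        groups = dict(zip(meta_a["sample_id"], meta_a["habitat"]))
        out = {}
        combos = [("biofilm", "soil"), ("bacterioplankton", "soil"),
                  ("bacterioplankton", "biofilm")]
        for a, b in combos:
            ids = meta_a.loc[meta_a["habitat"].isin([a, b]), "sample_id"].tolist()
            res = permanova(D_all.submatrix(ids), {i: groups[i] for i in ids},
                            n_perm=config.n_permutations, seed=config.seed)
            out[f"{a}_vs_{b}"] = {
                "pseudo_F": res.pseudo_F, "p_value": res.p_value,
                "df_among": res.df_among, "df_within": res.df_within,
                "n_permutations": res.n_permutations,
            }
        return out

    report["permanova"] = _permanova

    @stage("nmds")
    def _nmds():
        res = nmds(D_all, k=config.nmds_k, n_restarts=config.nmds_restarts,
                   max_iter=config.nmds_max_iter, seed=config.seed)
        cent = centroid_distance(res, dict(zip(meta_a["sample_id"], meta_a["habitat"])))
        return res, cent

    nmds_res, centroids = _nmds
    report["nmds"] = {
        "stress": nmds_res.stress,
        "converged": bool(nmds_res.converged),
        "n_restarts": nmds_res.n_restarts,
        "centroid_distances": {f"{a}_vs_{b}": float(centroids.loc[a, b])
                               for i, a in enumerate(centroids.index)
                               for b in centroids.index[i + 1:]},
    }

    @stage("linkage")
    def _linkage():
        return linkage_table(rt, meta_a)

    link_tab = _linkage

    @stage("shared_taxa")
    def _shared():
        st = shared_taxa_table(rt, meta_a)
        trends = {pair: _reg(fit) for pair, fit in sharing_trend(st, meta_a).items()}
        return st, trends

    shared_tab, shared_trends = _shared
    report["shared_taxa"] = {
        "trend_vs_distance": shared_trends,
        "mean_shared_by_pair": {
            pair: float(grp["mean_shared"].mean())
            for pair, grp in shared_tab.groupby("pair")
        },
    }

    report["summary"] = {
        "mean_temporal_beta": {
            hab: float(beta_tab.loc[beta_tab["habitat"] == hab,
                                    "mean_consecutive_dissimilarity"].mean())
            for hab in HABITATS
        },
        "n_samples": rt.shape[0],
        "n_asvs": rt.shape[1],
    }

    report["tables"] = {
        "temporal_beta": beta_tab.to_dict(orient="records"),
        "distance_decay": decay_tab.to_dict(orient="records"),
        "env_variability": env_tab.to_dict(orient="records"),
        "linkage": link_tab.to_dict(orient="records"),
        "shared_taxa": shared_tab.to_dict(orient="records"),
        "nmds_coordinates": nmds_res.coordinates.round(10).reset_index(
            names="sample_id").to_dict(orient="records"),
    }
    return report


def run_files(asv_path, meta_path, env_path, config: PipelineConfig | None = None,
              out_dir=None, orientation: str = "samples_as_rows") -> dict:
    """File-based entry point; optionally writes report.json and TSV tables."""
    from .core import read_asv_table, read_env_table, read_metadata

    table = read_asv_table(asv_path, orientation=orientation)
    meta = read_metadata(meta_path)
    env = read_env_table(env_path)
    checksums = {
        "asv": file_checksum(asv_path),
        "metadata": file_checksum(meta_path),
        "environment": file_checksum(env_path),
    }
    report = run_analysis(table, meta, env, config, checksums=checksums)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def report_json(report: dict) -> str:
    """Canonical JSON text of a report (sorted keys, fixed float repr)."""
    return json.dumps(_jsonify(report), indent=2, sort_keys=True, default=str)


def write_report(report: dict, out_dir) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(report_json(report) + "\n")
    for name, records in report.get("tables", {}).items():
        pd.DataFrame(records).to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
    return path
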