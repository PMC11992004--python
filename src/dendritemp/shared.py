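"""Shared-ASV analysis between habitat pairs.

An ASV is "shared" by a focal aquatic sample with a partner habitat at the
same site when it occurs (count > 0) in the focal sample and anywhere in the
partner habitat's samples of that site, at any sampling occasion. Occurrence
is evaluated on the rarefied table by default (presence detection is
depth-sensitive, so callers may pass the unrarefied table instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AsvTable, ValidationError, normalize_habitat
from .inference import RegressionResult, ols
from .preprocess import to_relative_abundance

HABITAT_PAIRS = (
    ("soil", "bacterioplankton"),
    ("soil", "biofilm"),
    ("biofilm", "bacterioplankton"),
)


@dataclass(frozen=True)
class SharedTaxaResult:
    site_id: str
    focal_habitat: str
    partner_habitat: str
    per_occasion_shared: dict[int, int] = field(repr=False)
    mean_shared: float = 0.0
    shared_fraction: float = 0.0  # of the focal habitat's dataset-wide ASV pool


def site_occurrence_union(table: AsvTable, meta: pd.DataFrame, site: str, habitat: str) -> set[str]:
    """ASVs occurring at a site/habitat at any sampling occasion."""
    habitat = normalize_habitat(habitat)
    ids = meta.loc[(meta["site_id"] == str(site)) & (meta["habitat"] == habitat), "sample_id"]
    if ids.empty:
        raise ValidationError(f"no samples for site {site}, habitat {habitat}")
    sub = table.counts.loc[list(ids)]
    present = (sub > 0).any(axis=0)
    return set(present.index[present])


def shared_count(focal_sample: pd.Series | np.ndarray, partner_union: set[str]) -> int:
    """Number of ASVs present in the focal sample and in the partner union."""
    if isinstance(focal_sample, pd.Series):
        support = set(focal_sample.index[focal_sample > 0])
        return len(support & partner_union)
    raise TypeError("focal_sample must be a labelled pandas Series of counts")


def habitat_asv_pool_size(table: AsvTable, meta: pd.DataFrame, habitat: str) -> int:
    """Total distinct ASVs of a habitat across the whole data set."""
    habitat = normalize_habitat(habitat)
    ids = meta.loc[meta["habitat"] == habitat, "sample_id"]
    return int((table.counts.loc[list(ids)] > 0).any(axis=0).sum())


def shared_taxa_site(table: AsvTable, meta: pd.DataFrame, site: str,
                     focal_habitat: str, partner_habitat: str) -> SharedTaxaResult:
    """Per-occasion and site-mean shared ASV counts for one habitat pair."""
    focal_habitat = normalize_habitat(focal_habitat)
    partner_habitat = normalize_habitat(partner_habitat)
    union = site_occurrence_union(table, meta, site, partner_habitat)
    focal = meta[(meta["site_id"] == str(site)) & (meta["habitat"] == focal_habitat)]
    if focal.empty:
        raise ValidationError(f"no {focal_habitat} samples at site {site}")
    per_occ = {}
    for _, row in focal.sort_values("occasion").iterrows():
        per_occ[int(row["occasion"])] = shared_count(table.counts.loc[row["sample_id"]], union)
    pool = habitat_asv_pool_size(table, meta, focal_habitat)
    mean_shared = float(np.mean(list(per_occ.values())))
    return SharedTaxaResult(str(site), focal_habitat, partner_habitat, per_occ,
                            mean_shared, mean_shared / pool if pool else float("nan"))


def shared_taxa_table(table: AsvTable, meta: pd.DataFrame,
                      pairs=HABITAT_PAIRS) -> pd.DataFrame:
    """Site-level mean shared counts for every habitat pair.

    The pair (partner, focal) is oriented so the second habitat is focal —
    e.g. ("soil", "bacterioplankton") counts soil-derived ASVs per
    bacterioplankton sample.
    """
    rows = []
    for partner, focal in pairs:
        for site in sorted(meta["site_id"].unique()):
            r = shared_taxa_site(table, meta, site, focal, partner)
            rows.append({
                "site_id": r.site_id,
                "pair": f"{partner}-{focal}",
                "focal_habitat": r.focal_habitat,
                "partner_habitat": r.partner_habitat,
                "mean_shared": r.mean_shared,
                "shared_fraction": r.shared_fraction,
            })
    return pd.DataFrame(rows)


def sharing_trend(shared: pd.DataFrame, meta: pd.DataFrame) -> dict[str, RegressionResult]:
    """OLS of site-mean shared counts on dendritic distance, per pair."""
    dist = meta.groupby("site_id")["dendritic_distance_km"].first()
    out = {}
    for pair, grp in shared.groupby("pair"):
        x = dist.loc[grp["site_id"]].to_numpy()
        out[pair] = ols(grp["mean_shared"].to_numpy(), x)
    return out


def taxon_group_summary(table: AsvTable, taxonomy: pd.Series, asv_set,
                        sample_ids=None, rank: str = "phylum") -> pd.DataFrame:
    """Mean relative abundance per taxon group, restricted to ``asv_set``.

    Returns both the raw mean relative abundance of each group (share of
    whole-sample reads) and the within-set renormalized share. ASVs absent
    from the taxonomy are reported as "unclassified".
    """
    asv_set = [a for a in table.asv_ids if a in set(asv_set)]
    if not asv_set:
        raise ValidationError("empty ASV set has no taxon summary")
    sub = table if sample_ids is None else table.select_samples(list(sample_ids))
    rel = to_relative_abundance(sub)[asv_set]
    groups = pd.Series([taxonomy.get(a, "unclassified") for a in asv_set], index=asv_set)
    raw = rel.T.groupby(groups).sum().T.mean(axis=0)
    total = raw.sum()
    out = pd.DataFrame({
        "mean_relative_abundance": raw,
        "renormalized_share": raw / total if total > 0 else np.nan,
    })
    out.index.name = rank
    return out.sort_values("mean_relative_abundance", ascending=False)
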