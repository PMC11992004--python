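"""Temporal β-diversity statistics and soil–stream linkage measures.

Two complementary site-level summaries of compositional change through time:

* **temporal turnover** — the mean Bray–Curtis dissimilarity between samples
  from consecutive sampling occasions of one site/habitat series; high when
  the community is reshuffled between visits regardless of any directional
  trend.
* **temporal distance decay** — the slope of an ordinary least-squares
  regression of all within-series pairwise dissimilarities on the elapsed
  time between samples; high when dissimilarity accumulates with time
  separation (directional/seasonal change), near zero when variation is as
  large between adjacent visits as between distant ones.

"Consecutive" is defined by the occasion index; elapsed time is measured in
calendar days by default because sampling intervals are only approximately
regular. Missing occasions reduce the number of usable pairs and are logged,
never interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AsvTable, DistanceMatrix, ValidationError, normalize_habitat
from .dissimilarity import bray_curtis, euclidean
from .inference import RegressionResult, ols
from .preprocess import to_relative_abundance, zscore

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TemporalBetaResult:
    site_id: str
    habitat: str
    mean_consecutive_dissimilarity: float
    n_pairs: int


@dataclass(frozen=True)
class DecayResult:
    site_id: str
    habitat: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_pairs: int


@dataclass(frozen=True)
class EnvVariabilityResult:
    site_id: str
    variable_set: str
    mean_consecutive_distance: float
    n_pairs: int


@dataclass(frozen=True)
class LinkageResult:
    site_id: str
    habitat: str  # the aquatic partner of soil
    mean_similarity: float
    sd_similarity: float
    sd_similarity_consecutive: float
    n_times: int


def _series_samples(meta: pd.DataFrame, site: str, habitat: str) -> pd.DataFrame:
    habitat = normalize_habitat(habitat)
    sel = meta[(meta["site_id"] == str(site)) & (meta["habitat"] == habitat)]
    return sel.sort_values("occasion")


def temporal_beta(D: DistanceMatrix, meta: pd.DataFrame, site: str, habitat: str) -> TemporalBetaResult:
    """Mean dissimilarity across consecutive sampling occasions of one series.

    Gaps in the occasion sequence skip the affected pair (a pair is
    consecutive only when occasion indices differ by exactly 1).
    """
    sel = _series_samples(meta, site, habitat)
    if len(sel) < 2:
        raise ValidationError(f"site {site}/{habitat}: need >= 2 occasions, have {len(sel)}")
    occ = sel["occasion"].to_numpy()
    ids = sel["sample_id"].to_numpy()
    vals = []
    skipped = 0
    for a, b, oa, ob in zip(ids[:-1], ids[1:], occ[:-1], occ[1:]):
        if ob - oa == 1:
            vals.append(D[a, b])
        else:
            skipped += 1
    if skipped:
        log.info("temporal_beta %s/%s: %d gap(s) in occasion sequence", site, habitat, skipped)
    if not vals:
        raise ValidationError(f"site {site}/{habitat}: no consecutive occasion pairs")
    return TemporalBetaResult(str(site), habitat, float(np.mean(vals)), len(vals))


def distance_decay(D: DistanceMatrix, meta: pd.DataFrame, site: str, habitat: str,
                   time_unit: str = "days") -> DecayResult:
    """OLS of all within-series pairwise dissimilarities on |Δt|."""
    if time_unit not in ("days", "occasions"):
        raise ValueError("time_unit must be 'days' or 'occasions'")
    sel = _series_samples(meta, site, habitat)
    if len(sel) < 3:
        raise ValidationError(f"site {site}/{habitat}: need >= 3 occasions for decay")
    ids = sel["sample_id"].to_numpy()
    if time_unit == "days":
        t = pd.to_datetime(pd.Series(list(sel["date"]))).astype("int64").to_numpy() / 86_400e9
    else:
        t = sel["occasion"].to_numpy(dtype=float)
    y, x = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            y.append(D[ids[i], ids[j]])
            x.append(abs(t[j] - t[i]))
    x = np.asarray(x)
    if np.ptp(x) == 0:
        raise ValidationError(f"site {site}/{habitat}: degenerate design, all time separations equal")
    fit = ols(np.asarray(y), x)
    return DecayResult(str(site), normalize_habitat(habitat), fit.slope, fit.intercept,
                       fit.r_squared, fit.p_value, fit.n)


def env_temporal_variability(env_std: pd.DataFrame, site: str, variable_set: str,
                             variables: list[str] | None = None) -> EnvVariabilityResult:
    """Mean Euclidean distance between consecutive occasions of one site.

    ``env_std`` is a standardized environment table indexed by
    (site_id, occasion); ``variables`` can narrow the declared set to a
    single variable (used when screening drivers one at a time). Pairs with
    any missing variable are skipped and logged.
    """
    from .core import VARIABLE_SETS

    cols = variables if variables is not None else list(VARIABLE_SETS[variable_set])
    try:
        rows = env_std.loc[str(site)][cols]
    except KeyError:
        raise ValidationError(f"site {site} absent from environment table") from None
    rows = rows.sort_index()
    occ = rows.index.to_numpy()
    x = rows.to_numpy(dtype=float)
    dists = []
    skipped = 0
    for k in range(len(occ) - 1):
        if occ[k + 1] - occ[k] != 1:
            continue
        a, b = x[k], x[k + 1]
        if np.isnan(a).any() or np.isnan(b).any():
            skipped += 1
            continue
        dists.append(float(np.sqrt(np.sum((b - a) ** 2))))
    if skipped:
        log.info("env_temporal_variability %s/%s: %d pair(s) skipped (missing values)",
                 site, variable_set, skipped)
    if len(dists) < 1:
        raise ValidationError(f"site {site}/{variable_set}: no usable consecutive pairs")
    return EnvVariabilityResult(str(site), variable_set, float(np.mean(dists)), len(dists))


def cross_habitat_linkage(table: AsvTable, meta: pd.DataFrame, site: str,
                          aquatic_habitat: str) -> LinkageResult:
    """Time-matched similarity between soil and one aquatic habitat at a site.

    For each occasion sampled in both habitats, similarity
    s_t = 1 − BrayCurtis(soil_t, aquatic_t) on relative abundances. Returns
    the mean, the sd over all matched occasions (default variant) and the sd
    restricted to consecutive-occasion similarity values (alternative
    reading of "variation across consecutive sampling times"); both use the
    n−1 denominator.
    """
    aquatic_habitat = normalize_habitat(aquatic_habitat)
    if aquatic_habitat == "soil":
        raise ValidationError("aquatic habitat must be bacterioplankton or biofilm")
    soil = _series_samples(meta, site, "soil").set_index("occasion")["sample_id"]
    aqua = _series_samples(meta, site, aquatic_habitat).set_index("occasion")["sample_id"]
    shared_occ = sorted(set(soil.index) & set(aqua.index))
    if len(shared_occ) < 2:
        raise ValidationError(
            f"site {site}: soil and {aquatic_habitat} share {len(shared_occ)} occasion(s), need >= 2"
        )
    ids = [soil[o] for o in shared_occ] + [aqua[o] for o in shared_occ]
    p = to_relative_abundance(table.select_samples(ids))
    sims = []
    for o in shared_occ:
        D = bray_curtis(p.loc[[soil[o], aqua[o]]])
        sims.append(1.0 - D.values[0, 1])
    sims = np.asarray(sims)
    # sd of similarities restricted to occasions that participate in a consecutive pair
    consec_vals = [sims[k] for k in range(len(shared_occ))
                   if (k > 0 and shared_occ[k] - shared_occ[k - 1] == 1)
                   or (k < len(shared_occ) - 1 and shared_occ[k + 1] - shared_occ[k] == 1)]
    sd_all = float(np.std(sims, ddof=1))
    sd_consec = float(np.std(consec_vals, ddof=1)) if len(consec_vals) > 1 else float("nan")
    return LinkageResult(str(site), aquatic_habitat, float(np.mean(sims)), sd_all,
                         sd_consec, len(shared_occ))


# ---------------------------------------------------------------------------
# Convenience sweeps over every site/habitat series

def temporal_beta_table(D: DistanceMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (site, hab), _ in meta.groupby(["site_id", "habitat"]):
        r = temporal_beta(D, meta, site, hab)
        rows.append(vars(r))
    return pd.DataFrame(rows).sort_values(["habitat", "site_id"]).reset_index(drop=True)


def distance_decay_table(D: DistanceMatrix, meta: pd.DataFrame, time_unit: str = "days") -> pd.DataFrame:
    rows = []
    for (site, hab), _ in meta.groupby(["site_id", "habitat"]):
        r = distance_decay(D, meta, site, hab, time_unit=time_unit)
        rows.append(vars(r))
    return pd.DataFrame(rows).sort_values(["habitat", "site_id"]).reset_index(drop=True)


def env_variability_table(env: pd.DataFrame, variable_sets: list[str] | None = None,
                          standardized: bool = False) -> pd.DataFrame:
    """Site × variable-set table of temporal environmental variability.

    ``env`` is raw unless ``standardized``; z-scoring is applied per
    variable over all rows before distances are taken.
    """
    from .core import VARIABLE_SETS

    sets = variable_sets if variable_sets is not None else list(VARIABLE_SETS)
    rows = []
    for vs in sets:
        env_std = env if standardized else zscore(env, vs)
        for site in sorted(env.index.get_level_values("site_id").unique()):
            r = env_temporal_variability(env_std, site, vs)
            rows.append(vars(r))
    return pd.DataFrame(rows)


def linkage_table(table: AsvTable, meta: pd.DataFrame) -> pd.DataFrame:
    rows = []
    sites = sorted(meta.loc[meta["habitat"] == "soil", "site_id"].unique())
    for hab in ("bacterioplankton", "biofilm"):
        for site in sites:
            try:
                rows.append(vars(cross_habitat_linkage(table, meta, site, hab)))
            except ValidationError:
                log.info("linkage skipped for site %s/%s", site, hab)
    return pd.DataFrame(rows)
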