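"""Seeded generator of dendritic stream-network metacommunity data sets.

The generator emulates the processes the analysis is designed to detect, at
the study's design scale (13 sites in a branching network, 7 roughly
biweekly occasions, 3 habitats):

* **Riparian soil** communities: site-specific, soil-guild-dominated
  compositions following an AR(1) log-abundance drift whose innovation
  scale tracks that site's soil-environment variability (a latent per-site
  factor with no relation to network position).
* **Bacterioplankton**: at each occasion a mixture of the local soil
  community (weight proportional to a network-wide rainfall pulse times an
  exponential decay with dendritic distance from the source — the
  "soil taxa wash in at headwaters and are gradually lost" mechanism),
  flow-weighted upstream plankton, and a stable aquatic-generalist core.
* **Biofilm**: a selection kernel strongly favouring biofilm-specialist
  taxa applied to the local water-column pool, with AR(1) log-abundance
  noise whose innovation scale increases with dendritic distance (the
  downstream physical regime is temporally more variable).

Sequencing is emulated as a multinomial draw at a log-normal depth per
sample, anchored to realistic amplicon read-depth scales. Environmental
tables mirror the latent drivers: water-chemistry temporal variance
decreases with distance, physical variance increases, soil-variable
variance follows the latent per-site factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .core import AsvTable, ValidationError, validate_env_table, validate_metadata

GUILDS = ("soil", "aquatic", "biofilm")


@dataclass(frozen=True)
class NetworkLayout:
    """Rooted dendritic network; leaves are headwaters, root is the outlet."""

    sites: pd.DataFrame = field(repr=False)  # site_id, dendritic_distance_km, stream_order
    parents: dict = field(repr=False)  # site -> tuple of immediate upstream sites

    def __post_init__(self):
        s = self.sites.set_index("site_id")
        for child, ups in self.parents.items():
            for up in ups:
                if s.loc[up, "dendritic_distance_km"] >= s.loc[child, "dendritic_distance_km"]:
                    raise ValidationError(
                        f"distance does not increase from {up} to {child}"
                    )

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites["site_id"])

    def distance(self, site: str) -> float:
        return float(self.sites.set_index("site_id").loc[site, "dendritic_distance_km"])

    def topological_order(self) -> list[str]:
        """Sites ordered so every site appears after its upstream parents."""
        order, placed = [], set()
        pending = list(self.site_ids)
        while pending:
            progressed = False
            for s in list(pending):
                if all(p in placed for p in self.parents.get(s, ())):
                    order.append(s)
                    placed.add(s)
                    pending.remove(s)
                    progressed = True
            if not progressed:
                raise ValidationError("network topology has a cycle")
        return order


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator knobs, with study-scale defaults.

    Units: distances km, rates per occasion, log-abundance scales are
    natural-log standard deviations.
    """

    # community pool
    n_asv: int = 800
    frac_soil_guild: float = 0.45
    frac_aquatic_guild: float = 0.35  # biofilm guild takes the remainder
    n_occasions: int = 7
    start_date: date = date(2018, 7, 4)
    occasion_day_offsets: tuple = (0, 14, 27, 42, 56, 71, 85)

    # rainfall-driven soil input to the water column
    rain_pulse_sd: float = 1.0          # scale of the half-normal network-wide pulse R_t
    soil_coupling: float = 0.8          # w_soil = min(max, coupling * R_t * exp(-dist/delta))
    soil_input_decay_km: float = 2.0    # e-folding distance of the soil imprint
    w_soil_max: float = 0.85
    upstream_mixing: float = 0.5        # share of the non-soil part taken from upstream
    plankton_jitter_sd: float = 0.35    # per-taxon lognormal wobble of the water column

    # biofilm selection and temporal noise
    biofilm_selection_strength: float = 4.0
    biofilm_noise_base: float = 0.35    # AR(1) innovation sd at distance 0
    biofilm_innovation_gradient: float = 0.08  # + per km

    # soil community drift and its environmental driver
    soil_drift_sd: float = 0.7          # innovation sd multiplier (times the site factor)
    ar1_rho: float = 0.6                # mean reversion of soil/biofilm log-abundance AR(1)
    soil_env_site_sd: float = 0.6       # lognormal sd of the per-site soil-variability factor
    site_effect_sd: float = 0.8         # among-site spread of soil base log-abundances
    core_site_sd: float = 0.4           # among-site spread of the aquatic core

    # environment model
    chem_var_gradient: float = 1.0      # chemistry variance declines with relative distance
    phys_var_gradient: float = 0.9      # physical variance rises with relative distance

    # sequencing depth (log-normal, reads per sample)
    depth_log_mean: float = 8.955
    depth_log_sd: float = 0.5
    depth_min: int = 2239

    seed: int = 0
    randomize_network: bool = False

    def __post_init__(self):
        for name in ("frac_soil_guild", "frac_aquatic_guild", "upstream_mixing", "w_soil_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name}={v} must lie in [0, 1]")
        if self.frac_soil_guild + self.frac_aquatic_guild > 1:
            raise ValidationError("guild fractions exceed 1")
        if self.n_occasions > len(self.occasion_day_offsets):
            raise ValidationError("not enough occasion day offsets for n_occasions")
        if self.rain_pulse_sd < 0 or self.soil_input_decay_km <= 0:
            raise ValidationError("rain_pulse_sd >= 0 and soil_input_decay_km > 0 required")

    def guild_sizes(self) -> tuple[int, int, int]:
        n_soil = round(self.n_asv * self.frac_soil_guild)
        n_aqua = round(self.n_asv * self.frac_aquatic_guild)
        return n_soil, n_aqua, self.n_asv - n_soil - n_aqua


# default layout mirroring the study design: 5 first-order headwaters,
# 5 second-order mid-stream sites, 3 third-order downstream sites, ~10 km max
_DEFAULT_SITES = [
    ("H1", 0.4, 1), ("H2", 0.5, 1), ("H3", 0.6, 1), ("H4", 0.7, 1), ("H5", 0.8, 1),
    ("M1", 1.8, 2), ("M2", 3.0, 2), ("M3", 2.2, 2), ("M4", 3.5, 2), ("M5", 4.5, 2),
    ("D1", 6.5, 3), ("D2", 8.0, 3), ("D3", 9.8, 3),
]
_DEFAULT_PARENTS = {
    "M1": ("H1", "H2"),
    "M2": ("M1", "H3"),
    "M5": ("M2",),
    "M3": ("H4", "H5"),
    "M4": ("M3",),
    "D1": ("M5", "M4"),
    "D2": ("D1",),
    "D3": ("D2",),
}


def generate_network(config: SyntheticConfig, seed: int | None = None) -> NetworkLayout:
    """Default 13-site dendritic layout; optionally distance-jittered."""
    sites = pd.DataFrame(_DEFAULT_SITES, columns=["site_id", "dendritic_distance_km", "stream_order"])
    if config.randomize_network:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        d = sites["dendritic_distance_km"].to_numpy() * np.exp(rng.normal(0, 0.1, len(sites)))
        sites = sites.assign(dendritic_distance_km=d)
        s = sites.set_index("site_id")["dendritic_distance_km"].to_dict()
        for child in NetworkLayout(sites, {}).site_ids:  # enforce monotone paths
            for up in _DEFAULT_PARENTS.get(child, ()):
                s[child] = max(s[child], s[up] * 1.05 + 0.05)
        sites["dendritic_distance_km"] = [s[i] for i in sites["site_id"]]
    return NetworkLayout(sites, dict(_DEFAULT_PARENTS))


def generate_environment(layout: NetworkLayout, config: SyntheticConfig,
                         seed: int | None = None) -> tuple[pd.DataFrame, dict]:
    """Environment table keyed by (site, occasion) plus latent drivers.

    Returns ``(env, latents)`` where latents carries the per-site soil
    variability factor ``tau`` (which also drives soil community drift) and
    the realized chemistry/physical innovation scale factors.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    sites = layout.sites
    dmax = sites["dendritic_distance_km"].max()
    rel = sites.set_index("site_id")["dendritic_distance_km"] / dmax

    tau = pd.Series(
        np.exp(rng.normal(0.0, config.soil_env_site_sd, len(sites))),
        index=sites["site_id"], name="tau",
    )
    chem_factor = np.sqrt(np.maximum(0.15, 1.1 - config.chem_var_gradient * rel))
    phys_factor = np.sqrt(0.3 + config.phys_var_gradient * rel)

    base = {
        "pH": (6.0, 0.3), "TotP": (15.0, 5.0), "NO2NO3": (20.0, 8.0), "SUVA": (3.0, 0.5),
        "temperature": (10.0, 3.0), "water_level": (50.0, 10.0),
        "soil_pH": (5.0, 0.2), "conductivity": (100.0, 20.0),
        "TotC": (40.0, 5.0), "TotN": (1.5, 0.3),
    }
    chem = ("pH", "TotP", "NO2NO3", "SUVA")
    phys = ("temperature", "water_level")

    rows = []
    for site in layout.site_ids:
        offsets = {v: rng.normal(0, 0.5 * sd) for v, (_, sd) in base.items()}
        for t in range(1, config.n_occasions + 1):
            row = {"site_id": site, "occasion": t}
            for v, (mu, sd) in base.items():
                if v in chem:
                    scale = sd * chem_factor[site]
                elif v in phys:
                    scale = sd * phys_factor[site]
                else:
                    scale = sd * tau[site]
                row[v] = mu + offsets[v] + rng.normal(0, scale)
            rows.append(row)
    env = validate_env_table(pd.DataFrame(rows))
    latents = {"tau": tau, "chem_factor": chem_factor, "phys_factor": phys_factor}
    return env, latents


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def generate_communities(layout: NetworkLayout, latents: dict, config: SyntheticConfig,
                         seed: int | None = None) -> dict:
    """Latent relative compositions per (habitat, site, occasion).

    Returns a dict with arrays of shape (n_sites, T, n_asv) under keys
    "soil", "bacterioplankton", "biofilm" (site order = layout.site_ids),
    plus "rain_pulse" (length T) and "w_soil" (n_sites × T mixing weights).
    """
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n_soil, n_aqua, n_bio = config.guild_sizes()
    n = config.n_asv
    T = config.n_occasions
    sites = layout.site_ids
    ns = len(sites)
    dist = np.array([layout.distance(s) for s in sites])
    tau = latents["tau"]

    guild = np.repeat(np.arange(3), [n_soil, n_aqua, n_bio])  # 0 soil, 1 aquatic, 2 biofilm

    # soil habitat: site-specific base, AR(1) drift scaled by the site factor
    soil_base = np.where(guild == 0, 2.0, -6.0) + rng.normal(0, config.site_effect_sd, (ns, n))
    soil = np.empty((ns, T, n))
    walk = np.zeros((ns, n))
    for t in range(T):
        if t > 0:
            sd = config.soil_drift_sd * tau.to_numpy()[:, None]
            walk = config.ar1_rho * walk + rng.normal(0, 1.0, (ns, n)) * sd
        soil[:, t, :] = _softmax(soil_base + walk)

    # aquatic-generalist core, constant through time per site
    core_logits = np.where(guild == 1, 2.0, np.where(guild == 2, 0.0, -6.0))
    core = _softmax(core_logits + rng.normal(0, config.core_site_sd, (ns, n)))

    # network-wide rainfall pulses and the distance-decaying soil weight
    rain = np.abs(rng.normal(0.0, 1.0, T)) * config.rain_pulse_sd
    decay = np.exp(-dist / config.soil_input_decay_km)
    w_soil = np.minimum(config.w_soil_max,
                        config.soil_coupling * rain[None, :] * decay[:, None])

    plankton = np.empty((ns, T, n))
    order = layout.topological_order()
    idx = {s: i for i, s in enumerate(sites)}
    lam = config.upstream_mixing
    for t in range(T):
        for s in order:
            i = idx[s]
            parents = layout.parents.get(s, ())
            if parents:
                up = np.mean([plankton[idx[p], t] for p in parents], axis=0)
                basecomp = lam * up + (1 - lam) * core[i]
            else:
                basecomp = core[i]
            mix = w_soil[i, t] * soil[i, t] + (1 - w_soil[i, t]) * basecomp
            mix = mix * np.exp(rng.normal(0, config.plankton_jitter_sd, n))
            plankton[i, t] = mix / mix.sum()

    # biofilm: selection kernel on the local water-column pool + AR(1) noise
    trait = np.where(guild == 2, 1.0, np.where(guild == 1, 0.0, -1.0))
    kernel = np.exp(config.biofilm_selection_strength * trait)
    bio_sd = config.biofilm_noise_base + config.biofilm_innovation_gradient * dist
    biofilm = np.empty((ns, T, n))
    vwalk = np.zeros((ns, n))
    for t in range(T):
        if t > 0:
            vwalk = config.ar1_rho * vwalk + rng.normal(0, 1.0, (ns, n)) * bio_sd[:, None]
        raw = plankton[:, t, :] * kernel[None, :] * np.exp(vwalk)
        biofilm[:, t, :] = raw / raw.sum(axis=1, keepdims=True)

    for name, comp in (("soil", soil), ("bacterioplankton", plankton), ("biofilm", biofilm)):
        if not np.allclose(comp.sum(axis=2), 1.0, atol=1e-9):
            raise ValidationError(f"{name} compositions do not sum to 1")
    return {
        "soil": soil,
        "bacterioplankton": plankton,
        "biofilm": biofilm,
        "rain_pulse": rain,
        "w_soil": w_soil,
        "guild": guild,
    }


def generate_counts(compositions: dict, layout: NetworkLayout, config: SyntheticConfig,
                    seed: int | None = None) -> tuple[AsvTable, pd.DataFrame]:
    """Multinomial read counts at log-normal depths, plus sample metadata."""
    rng = np.random.default_rng(config.seed + 3 if seed is None else seed)
    sites = layout.site_ids
    sinfo = layout.sites.set_index("site_id")
    asv_ids = [f"ASV{i + 1:04d}" for i in range(config.n_asv)]
    rows, meta_rows = {}, []
    for hab in ("bacterioplankton", "biofilm", "soil"):
        comp = compositions[hab]
        for i, site in enumerate(sites):
            for t in range(1, config.n_occasions + 1):
                depth = int(round(float(rng.lognormal(config.depth_log_mean, config.depth_log_sd))))
                depth = max(depth, config.depth_min)
                sid = f"{site}_{hab[:4]}_{t}"
                rows[sid] = rng.multinomial(depth, comp[i, t - 1])
                meta_rows.append({
                    "sample_id": sid,
                    "site_id": site,
                    "habitat": hab,
                    "occasion": t,
                    "date": config.start_date + timedelta(days=int(config.occasion_day_offsets[t - 1])),
                    "dendritic_distance_km": float(sinfo.loc[site, "dendritic_distance_km"]),
                    "stream_order": int(sinfo.loc[site, "stream_order"]),
                })
    table = AsvTable(pd.DataFrame.from_dict(rows, orient="index", columns=asv_ids))
    meta = validate_metadata(pd.DataFrame(meta_rows))
    return table, meta


def generate_taxonomy(config: SyntheticConfig, seed: int | None = None) -> pd.Series:
    """Synthetic ASV → phylum map with guild-skewed phylum frequencies."""
    rng = np.random.default_rng(config.seed + 4 if seed is None else seed)
    n_soil, n_aqua, n_bio = config.guild_sizes()
    pools = {
        0: (["Acidobacteriota", "Pseudomonadota", "Actinomycetota"], [0.45, 0.35, 0.2]),
        1: (["Pseudomonadota", "Verrucomicrobiota", "Bacteroidota"], [0.5, 0.3, 0.2]),
        2: (["Cyanobacteria", "Pseudomonadota", "Bacteroidota"], [0.45, 0.35, 0.2]),
    }
    guild = np.repeat(np.arange(3), [n_soil, n_aqua, n_bio])
    phyla = [rng.choice(pools[g][0], p=pools[g][1]) for g in guild]
    return pd.Series(phyla, index=[f"ASV{i + 1:04d}" for i in range(config.n_asv)])


@dataclass(frozen=True)
class SyntheticDataset:
    table: AsvTable
    meta: pd.DataFrame = field(repr=False)
    env: pd.DataFrame = field(repr=False)
    layout: NetworkLayout
    latents: dict = field(repr=False)
    compositions: dict = field(repr=False)
    taxonomy: pd.Series = field(repr=False)
    config: SyntheticConfig = field(repr=False)


def generate_dataset(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """One full synthetic data set (counts, metadata, environment, taxonomy)."""
    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**asdict(config), "seed": seed})
    layout = generate_network(config)
    env, latents = generate_environment(layout, config)
    comps = generate_communities(layout, latents, config)
    table, meta = generate_counts(comps, layout, config)
    taxonomy = generate_taxonomy(config)
    return SyntheticDataset(table, meta, env, layout, latents, comps, taxonomy, config)
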