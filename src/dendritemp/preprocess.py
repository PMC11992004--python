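"""Count filtering, rarefaction and environmental preprocessing.

Rarefaction follows the common amplicon workflow: pick a depth (here the
lower 5th percentile of per-sample totals by default), subsample each
deeper sample without replacement (multivariate hypergeometric) to exactly
that depth, and pass shallower samples through unchanged so they are not
discarded. A single seeded draw is made per sample — the analysis operates
on one rarefied data set, not an average over draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as _date, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import VARIABLE_SETS, AsvTable, LoggerSeries, ValidationError


@dataclass(frozen=True)
class RarefactionSpec:
    """Depth, below-depth policy and seed for a rarefaction pass."""

    depth: int
    passthrough_below_depth: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValidationError("rarefaction depth must be >= 1")


def remove_singletons(table: AsvTable, exclude: Iterable[str] = ()) -> AsvTable:
    """Drop ASVs with total count 1 across the whole data set.

    ``exclude`` additionally drops a caller-supplied identifier list (the
    stand-in for mitochondria / chloroplast / unassigned removal, which is
    taxonomy-driven upstream of this package).
    """
    totals = table.counts.sum(axis=0)
    drop = set(totals.index[totals == 1]) | {str(a) for a in exclude}
    keep = [a for a in table.asv_ids if a not in drop]
    if not keep:
        raise ValidationError("singleton/exclusion filtering removed every ASV")
    return AsvTable(table.counts[keep])


def percentile_depth(table: AsvTable, q: float = 5.0) -> int:
    """q-th percentile of per-sample totals, floored to an integer depth.

    Uses linear interpolation between order statistics (numpy's default
    convention), then floors so the result is a valid subsampling depth.
    """
    if not 0 <= q <= 100:
        raise ValueError("percentile q must be in [0, 100]")
    totals = table.sample_totals().to_numpy()
    if totals.size == 0:
        raise ValidationError("empty table has no percentile depth")
    return int(np.floor(np.percentile(totals, q, method="linear")))


def rarefy(table: AsvTable, spec: RarefactionSpec) -> AsvTable:
    """Subsample each sample without replacement to ``spec.depth`` reads.

    Samples whose total is below the depth are returned unchanged when
    ``passthrough_below_depth`` is set, otherwise dropped. Deterministic for
    a given seed; each sample gets an independent substream so results do
    not depend on sample order.
    """
    totals = table.sample_totals()
    rows = {}
    seeds = np.random.SeedSequence(spec.seed).spawn(len(table.sample_ids))
    for sid, ss in zip(table.sample_ids, seeds):
        counts = table.counts.loc[sid].to_numpy()
        total = int(totals[sid])
        if total <= spec.depth:
            if spec.passthrough_below_depth or total == spec.depth:
                rows[sid] = counts
            continue
        rng = np.random.default_rng(ss)
        rows[sid] = rng.multivariate_hypergeometric(counts, spec.depth, method="marginals")
    if not rows:
        raise ValidationError(
            f"no sample reaches depth {spec.depth} and passthrough is off"
        )
    out = pd.DataFrame.from_dict(rows, orient="index", columns=table.asv_ids)
    return AsvTable(out.loc[[s for s in table.sample_ids if s in rows]])


def to_relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Row-normalize counts to proportions; every row sums to 1."""
    totals = table.sample_totals()
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"zero-total sample(s): {zero[:5]}")
    return table.counts.div(totals, axis=0)


def zscore(env: pd.DataFrame, variable_set: str | Sequence[str] | None = None) -> pd.DataFrame:
    """Standardize environment columns to mean 0, sample sd 1 (ddof=1).

    Missing values are excluded from the mean/sd and stay missing in the
    output. Standardization is global over all (site, occasion) rows.
    """
    if variable_set is None:
        cols = list(env.columns)
    elif isinstance(variable_set, str):
        cols = [c for c in VARIABLE_SETS[variable_set] if c in env.columns]
        missing = set(VARIABLE_SETS[variable_set]) - set(env.columns)
        if missing:
            raise ValidationError(f"environment table lacks variables {sorted(missing)}")
    else:
        cols = list(variable_set)
    out = env.copy()
    for c in cols:
        col = env[c]
        if col.notna().sum() < 2:
            raise ValidationError(f"variable {c!r} has fewer than 2 non-missing values")
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValidationError(f"variable {c!r} has zero variance")
        out[c] = (col - col.mean()) / sd
    return out


def suva(a254: float, doc: float, scale: float = 1.0) -> float:
    """Specific UV absorbance: absorbance at 254 nm over DOC concentration.

    ``scale`` defaults to 1 (pure ratio); pass 100 for the conventional
    L·mg⁻¹·m⁻¹ form. Downstream use is scale-invariant because variables are
    z-scored before entering any distance.
    """
    if doc <= 0:
        raise ValueError("DOC concentration must be positive")
    return scale * a254 / doc


def window_mean(series: LoggerSeries, sample_date: _date, window_days: int = 7) -> tuple[float, int]:
    """Mean logger value over the half-open window preceding the sample.

    Window is [sample_date − window_days, sample_date); returns (mean, n).
    An empty window yields (nan, 0) with a warning rather than an error so a
    single logger gap does not abort a whole preprocessing run.
    """
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    end = pd.Timestamp(sample_date)
    start = end - timedelta(days=window_days)
    ts = pd.DatetimeIndex(series.timestamps)
    mask = (ts >= start) & (ts < end)
    n = int(mask.sum())
    if n == 0:
        warnings.warn(
            f"no {series.variable} logger points for site {series.site_id} "
            f"in the {window_days} days before {sample_date}",
            stacklevel=2,
        )
        return float("nan"), 0
    return float(np.mean(np.asarray(series.values)[mask])), n


def rarefaction_curve(sample_counts: pd.Series | np.ndarray, depths: Sequence[int]) -> np.ndarray:
    """Expected richness at each subsampling depth (analytic, hypergeometric).

    E[S_d] = Σ_i [1 − C(N−N_i, d) / C(N, d)], evaluated in log space via
    gammaln so large counts do not overflow.
    """
    counts = np.asarray(sample_counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if N == 0:
        raise ValidationError("empty sample has no rarefaction curve")
    depths = np.asarray(depths, dtype=np.int64)
    if (depths < 0).any() or (depths > N).any():
        raise ValueError(f"depths must lie in [0, {N}]")
    out = np.empty(depths.shape, dtype=float)
    for k, d in enumerate(depths):
        # log C(N - N_i, d) - log C(N, d); taxa with N - N_i < d always appear
        m = N - counts
        log_denom = gammaln(N + 1) - gammaln(d + 1) - gammaln(N - d + 1)
        absent = np.full(counts.shape, -np.inf)
        ok = m >= d
        absent[ok] = gammaln(m[ok] + 1) - gammaln(d + 1) - gammaln(m[ok] - d + 1) - log_denom
        out[k] = float(np.sum(1.0 - np.exp(absent)))
    return out
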