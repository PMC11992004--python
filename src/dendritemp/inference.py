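"""Regression, PERMANOVA, NMDS and centroid distances.

PERMANOVA and NMDS are implemented from their definitions (distance-based
sum-of-squares partition with a label-permutation test; SMACOF majorization
of Kruskal stress-1 with an isotonic fit to the dissimilarity ranks).
Simple regression is delegated to :func:`scipy.stats.linregress`; the
partial regression is the classic residual-on-residual construction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression

from .core import DistanceMatrix, ValidationError

SIGNIFICANCE_ALPHA = 0.05


@dataclass(frozen=True)
class RegressionResult:
    """Slope/intercept/R²/p/n for a simple linear fit.

    ``significant`` flags p < 0.05 with no multiple-testing correction,
    mirroring the usual solid/dashed convention of regression figures; apply
    :func:`benjamini_hochberg` across a family of results when correction is
    wanted.
    """

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    stderr: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_ALPHA


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    df_among: int
    df_within: int


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame = field(repr=False)
    stress: float
    converged: bool
    n_restarts: int
    seed: int | None
    restart_stresses: tuple[float, ...] = field(default=(), repr=False)
    stress_history: tuple[float, ...] = field(default=(), repr=False)


def ols(y, x) -> RegressionResult:
    """Two-sided least-squares slope test with n−2 df."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D of equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValidationError(f"need >= 3 complete observations, have {len(y)}")
    if np.ptp(x) == 0:
        raise ValidationError("predictor is constant; slope is undefined")
    with warnings.catch_warnings():
        # R² is 0 (not undefined) when y is constant
        warnings.simplefilter("ignore")
        fit = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    p = 1.0 if np.isnan(fit.pvalue) else float(fit.pvalue)
    return RegressionResult(float(fit.slope), float(fit.intercept), r2, p, len(y),
                            float(fit.stderr))


def partial_regression(y, x, z) -> RegressionResult:
    """Association of y with x controlling for z, via residuals.

    Regress y on z and x on z separately (each with intercept), then run the
    simple regression of the y-residuals on the x-residuals.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (y.shape == x.shape == z.shape):
        raise ValueError("y, x, z must share shape")
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    y, x, z = y[ok], x[ok], z[ok]
    if len(y) < 4:
        raise ValidationError(f"partial regression needs >= 4 observations, have {len(y)}")
    fy = ols(y, z)
    fx = ols(x, z)
    ry = y - (fy.intercept + fy.slope * z)
    rx = x - (fx.intercept + fx.slope * z)
    if np.ptp(rx) == 0:
        raise ValidationError("x is collinear with z; partial predictor is constant")
    return ols(ry, rx)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; significance flags default to raw p)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# PERMANOVA

def _group_arrays(D: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, dict):
        try:
            g = np.asarray([groups[l] for l in D.labels])
        except KeyError as e:
            raise ValidationError(f"group mapping lacks label {e.args[0]!r}") from None
    else:
        g = np.asarray(list(groups))
        if len(g) != len(D.labels):
            raise ValidationError("group vector length does not match matrix labels")
    return g


def _permanova_F(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    """Pseudo-F from squared distances and integer group codes."""
    N = d2.shape[0]
    ss_total = d2[np.triu_indices(N, k=1)].sum() / N
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        n_g = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)][np.triu_indices(n_g, k=1)].sum() / n_g
    ss_among = ss_total - ss_within
    a = n_groups
    return (ss_among / (a - 1)) / (ss_within / (N - a))


def permanova(D: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None,
              method: str = "permutation") -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = (1/N) Σ_{i<j} d²_ij, SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij,
    pseudo-F = (SS_among/(a−1)) / (SS_within/(N−a)). The p-value permutes
    group labels freely over samples: with ``method='permutation'``,
    p = (#{F* ≥ F} + 1)/(n_perm + 1); with ``method='exact'`` every distinct
    label arrangement is enumerated and p = #{F* ≥ F}/K (identity included).
    """
    g = _group_arrays(D, groups)
    uniq, codes = np.unique(g, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        small = [str(uniq[i]) for i in np.where(counts < 2)[0]]
        raise ValidationError(f"group(s) of size 1: {small}")
    if np.isnan(D.values).any():
        raise ValidationError("distance matrix has missing entries")
    d2 = D.values**2
    F_obs = _permanova_F(d2, codes, a)
    N = len(codes)

    if method == "exact":
        seen = set()
        F_perm = []
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            F_perm.append(_permanova_F(d2, np.asarray(perm), a))
        F_perm = np.asarray(F_perm)
        p = float(np.sum(F_perm >= F_obs - 1e-12) / len(F_perm))
        n_used = len(F_perm)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(codes)
            if _permanova_F(d2, perm, a) >= F_obs - 1e-12:
                count += 1
        p = (count + 1) / (n_perm + 1)
        n_used = n_perm
    else:
        raise ValueError("method must be 'permutation' or 'exact'")
    return PermanovaResult(float(F_obs), float(p), n_used, a - 1, N - a)


# ---------------------------------------------------------------------------
# NMDS

def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = np.sum(d**2)
    if denom == 0:
        return 1.0
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def _config_distances(X: np.ndarray, iu) -> np.ndarray:
    diff = X[iu[0]] - X[iu[1]]
    return np.sqrt(np.sum(diff**2, axis=1))


def _isotonic_fit(d: np.ndarray, order: np.ndarray) -> np.ndarray:
    dhat = np.empty_like(d)
    dhat[order] = isotonic_regression(d[order]).x
    return dhat


def _classical_mds(values: np.ndarray, k: int) -> np.ndarray:
    n = values.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (values**2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    w = np.clip(w[idx], 0, None)
    return V[:, idx] * np.sqrt(w)


def nmds(D: DistanceMatrix, k: int = 2, n_restarts: int = 20, max_iter: int = 300,
         tol: float = 1e-7, seed: int | None = None) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Each restart runs SMACOF-style Guttman updates toward the current
    isotonic (pool-adjacent-violators) fit of configuration distances to the
    rank order of the input dissimilarities; ties are handled by the primary
    (weak) approach, ordering tied dissimilarities by their current
    configuration distance. A step that would increase stress terminates the
    restart, so the recorded stress sequence is non-increasing. Restart 0
    starts from classical (metric) scaling; the rest from seeded random
    configurations. The best final configuration is returned.
    """
    N = len(D.labels)
    if N < k + 2:
        raise ValidationError(f"need at least k+2={k+2} samples for {k}-D NMDS")
    if np.isnan(D.values).any():
        raise ValidationError("NMDS input has missing entries")
    iu = np.triu_indices(N, k=1)
    delta = D.values[iu]
    rng = np.random.default_rng(seed)

    best = None
    finals = []
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            X = _classical_mds(D.values, k)
            if np.allclose(X, 0):
                X = rng.standard_normal((N, k))
        else:
            X = rng.standard_normal((N, k))
        d = _config_distances(X, iu)
        order = np.lexsort((d, delta))
        dhat = _isotonic_fit(d, order)
        stress = _stress1(d, dhat)
        history = [stress]
        converged = False
        for _ in range(max_iter):
            # Guttman transform toward dhat
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            B = np.zeros((N, N))
            B[iu] = -ratio
            B += B.T
            np.fill_diagonal(B, -B.sum(axis=1))
            X_new = (B @ X) / N
            d_new = _config_distances(X_new, iu)
            # stress-1 is scale-invariant; renormalize to unit rms distance so
            # the configuration cannot contract toward the origin
            scale = np.sqrt(np.mean(d_new**2))
            if scale > 0:
                X_new = X_new / scale
                d_new = d_new / scale
            order = np.lexsort((d_new, delta))
            dhat_new = _isotonic_fit(d_new, order)
            stress_new = _stress1(d_new, dhat_new)
            if stress_new > stress + tol:
                break  # keep the previous (better) configuration
            improved = stress - stress_new
            X, d, dhat, stress = X_new, d_new, dhat_new, stress_new
            history.append(stress)
            if improved < tol:
                converged = True
                break
        finals.append(stress)
        if best is None or stress < best[0]:
            best = (stress, X, converged, tuple(history))

    stress, X, converged, history = best
    coords = pd.DataFrame(X, index=list(D.labels),
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    if not converged:
        warnings.warn("NMDS did not converge in any restart", stacklevel=2)
    return OrdinationResult(coords, float(stress), converged, max(1, n_restarts), seed,
                            tuple(finals), history)


def centroid_distance(ord_result: OrdinationResult | pd.DataFrame, groups) -> pd.DataFrame:
    """Euclidean distances between group centroids in ordination space."""
    coords = ord_result.coordinates if isinstance(ord_result, OrdinationResult) else ord_result
    if isinstance(groups, dict):
        try:
            g = pd.Series([groups[l] for l in coords.index], index=coords.index)
        except KeyError as e:
            raise ValidationError(f"unknown group label for sample {e.args[0]!r}") from None
    else:
        g = pd.Series(list(groups), index=coords.index)
    centroids = coords.groupby(g).mean()
    names = list(centroids.index)
    out = pd.DataFrame(0.0, index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            d = float(np.linalg.norm(centroids.loc[a] - centroids.loc[b]))
            out.loc[a, b] = out.loc[b, a] = d
    return out
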