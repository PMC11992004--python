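"""Pairwise dissimilarities: Bray–Curtis on community data, Euclidean on
standardized environment. Both return labelled :class:`DistanceMatrix`
objects; environmental pairs involving missing variables propagate as NaN
and are excluded pairwise downstream (with a logged count), never zeroed."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .core import AsvTable, DistanceMatrix, ValidationError

log = logging.getLogger(__name__)


def bray_curtis(p: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between rows.

    d_ij = Σ_k |p_ik − p_jk| / Σ_k (p_ik + p_jk); bounded in [0, 1] for
    non-negative rows. Intended for relative abundances of the rarefied
    table, though raw counts are accepted.
    """
    if isinstance(p, pd.DataFrame):
        labels = labels if labels is not None else list(p.index)
        values = p.to_numpy(dtype=float)
    else:
        values = np.asarray(p, dtype=float)
        labels = labels if labels is not None else [str(i) for i in range(values.shape[0])]
    if (values < 0).any():
        raise ValidationError("Bray-Curtis requires non-negative abundances")
    zero = np.where(values.sum(axis=1) == 0)[0]
    if zero.size:
        raise ValidationError(
            f"all-zero sample(s) make Bray-Curtis undefined: {[labels[i] for i in zero[:5]]}"
        )
    D = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(tuple(labels), D)


def euclidean(x: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> DistanceMatrix:
    """Euclidean distance between rows of a standardized variable matrix.

    Any pair in which either row has a missing variable is NaN in the
    result (missingness propagates; it is not treated as zero).
    """
    if isinstance(x, pd.DataFrame):
        labels = labels if labels is not None else [str(i) for i in x.index]
        values = x.to_numpy(dtype=float)
    else:
        values = np.asarray(x, dtype=float)
        labels = labels if labels is not None else [str(i) for i in range(values.shape[0])]
    diff = values[:, None, :] - values[None, :, :]
    D = np.sqrt(np.sum(diff**2, axis=2))
    # rows with any NaN poison their pairs; enforce a clean zero diagonal
    np.fill_diagonal(D, 0.0)
    n_missing = int(np.isnan(D[np.triu_indices_from(D, k=1)]).sum())
    if n_missing:
        log.info("euclidean: %d pair(s) missing due to incomplete variables", n_missing)
    if n_missing == D.shape[0] * (D.shape[0] - 1) // 2 and D.shape[0] > 1:
        raise ValidationError("every pair has missing variables; no usable distances")
    return DistanceMatrix(tuple(labels), D)


def submatrix(D: DistanceMatrix, keep: Sequence[str]) -> DistanceMatrix:
    """Restriction of ``D`` to ``keep`` in the given order."""
    return D.submatrix(keep)
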