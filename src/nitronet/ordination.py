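"""Bray-Curtis dissimilarity, principal coordinates, and ANOSIM.

Distance matrices are ``skbio.DistanceMatrix`` objects carrying sample
identifiers.  PCoA follows the classical Gower double-centering of
-d^2/2; negative eigenvalues (possible because Bray-Curtis is not
Euclidean-embeddable) are retained in the eigenvalue list but excluded
from the proportion-explained denominator.  No Cailliez correction is
applied.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as _skbio_anosim


@dataclass(frozen=True)
class OrdinationResult:
    """Sample coordinates with per-axis variance explained.

    ``coordinates`` columns are PC1..PCk (eigenvectors scaled by the square
    root of their eigenvalue); ``proportion_explained`` is eigenvalue over
    the sum of positive eigenvalues, so proportions over retained axes sum
    to at most 1.  ``eigenvalues`` keeps the full spectrum including any
    negative values, as a diagnostic of non-Euclidean distance input.
    """

    coordinates: pd.DataFrame
    proportion_explained: np.ndarray
    eigenvalues: np.ndarray


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sample columns.

    d(i,j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk); works on counts or
    relative abundances.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("zero-total sample(s) present")
    data = table.to_numpy(dtype=float).T
    condensed = pdist(data, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=list(table.columns))


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Double-centers -d^2/2 (Gower), eigendecomposes, and returns coordinates
    on axes with positive eigenvalues, ordered by decreasing eigenvalue.
    """
    d = dm.data
    n = d.shape[0]
    a = -0.5 * d**2
    centering = np.eye(n) - np.ones((n, n)) / n
    g = centering @ a @ centering
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigvals[0]), 1.0)
    positive = eigvals > tol
    pos_sum = eigvals[positive].sum()
    proportions = np.where(positive, eigvals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    k = int(positive.sum())
    if n_axes is not None:
        k = min(k, n_axes)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    frame = pd.DataFrame(coords, index=list(dm.ids), columns=[f"PC{i+1}" for i in range(k)])
    return OrdinationResult(frame, proportions[:k], eigvals)


def anosim(
    dm: DistanceMatrix, groups: pd.Series, n_perm: int = 999, seed: int = 0
) -> AnosimResult:
    """Analysis of similarities between labelled sample groups.

    R = (mean between-group rank - mean within-group rank) / (M/4) with
    M = n(n-1)/2 and average ranks for ties; the permutation p-value uses
    the +1 convention so it is never zero.
    """
    groups = pd.Series(groups).reindex(list(dm.ids))
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    sizes = groups.value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("ANOSIM needs >= 2 groups with >= 2 samples each")
    res = _skbio_anosim(dm, groups.to_numpy(), permutations=n_perm, seed=seed)
    return AnosimResult(float(res["test statistic"]), float(res["p-value"]), n_perm)
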