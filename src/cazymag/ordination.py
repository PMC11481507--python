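"""Community-ecology ordination statistics on MAG x family count matrices.

The stack follows the vegan conventions: square-root transform, Wisconsin
double standardization (columns scaled to their maxima, then rows to their
totals), Bray-Curtis dissimilarity, ANOSIM and PERMANOVA (ADONIS) with
label-permutation p-values, and a centered (unscaled) PCA.  A thin adapter
exposes UMAP embedding when the optional backend is installed; the embedding
internals are entirely the backend's.

Permutation p-values use the add-one estimator
``p = (1 + #{permuted statistic >= observed}) / (1 + n_permutations)`` so
they are never zero; an exhaustive mode enumerates all label permutations
for small n, where the permutation distribution is exact.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValidationError("dissimilarity matrix shape does not match labels")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0, atol=1e-12):
            raise ValidationError("dissimilarity matrix must have a zero diagonal")

    def condensed(self) -> np.ndarray:
        return squareform(self.data, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int


@dataclass
class PermanovaResult:
    pseudo_F: float
    R_squared: float
    p_value: float
    n_permutations: int


@dataclass
class PcaResult:
    scores: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray


def sqrt_wisconsin(matrix: pd.DataFrame) -> pd.DataFrame:
    """Square-root transform then Wisconsin double standardization.

    Order: element-wise sqrt; each column divided by its maximum; each row
    divided by its total.  All-zero columns and rows pass through as zeros.
    """
    x = matrix.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValidationError("count matrix must be nonnegative")
    x = np.sqrt(x)
    col_max = x.max(axis=0)
    nz = col_max > 0
    x[:, nz] = x[:, nz] / col_max[nz]
    row_sum = x.sum(axis=1)
    nz = row_sum > 0
    x[nz, :] = x[nz, :] / row_sum[nz, None]
    return pd.DataFrame(x, index=matrix.index, columns=matrix.columns)


def bray_curtis(matrix: pd.DataFrame) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity d(x, y) = sum|x-y| / sum(x+y).

    Two all-zero rows get d = 0 by convention (vegan-compatible; logged).
    """
    x = matrix.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValidationError("Bray-Curtis requires nonnegative data")
    # |xi - yi| summed via broadcasting in chunks to bound memory
    n = x.shape[0]
    d = np.zeros((n, n))
    row_sums = x.sum(axis=1)
    for i in range(n):
        num = np.abs(x[i] - x[i + 1:]).sum(axis=1)
        den = row_sums[i] + row_sums[i + 1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        if np.any(den == 0):
            logger.warning("double-zero rows: Bray-Curtis set to 0 by convention")
        d[i, i + 1:] = vals
        d[i + 1:, i] = vals
    return DissimilarityMatrix(ids=list(matrix.index), data=d)


def _check_groups(labels: np.ndarray, min_size: int = 2) -> list:
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 groups")
    if counts.min() < min_size:
        raise ValidationError(f"every group needs at least {min_size} members")
    return list(uniq)


def _anosim_r(rank_condensed: np.ndarray, within_mask: np.ndarray, m: int) -> float:
    rb = rank_condensed[~within_mask].mean()
    rw = rank_condensed[within_mask].mean()
    return (rb - rw) / (m / 2.0)


def _within_mask(labels: np.ndarray) -> np.ndarray:
    """Condensed-form boolean mask of within-group pairs."""
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    return squareform(same, checks=False).astype(bool)


def _permutation_p(
    observed: float,
    stat_fn,
    n: int,
    n_permutations: int,
    seed: Optional[int],
    exact: bool,
) -> tuple[float, int]:
    """One-sided (upper tail) permutation p for a row-relabeling statistic.

    *stat_fn* maps an index permutation (np.ndarray) to the statistic.
    """
    if exact:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            s = stat_fn(np.asarray(perm))
            if s >= observed - 1e-12:
                count += 1
            total += 1
        return count / total, total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        s = stat_fn(rng.permutation(n))
        if s >= observed - 1e-12:
            count += 1
    return (1 + count) / (1 + n_permutations), n_permutations


def anosim(
    D: DissimilarityMatrix,
    groups: Sequence,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    exact: bool = False,
) -> AnosimResult:
    """ANOSIM R with a label-permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M/2) on the
    midranked condensed distances, M = n(n-1)/2.
    """
    labels = np.asarray(groups)
    n = len(labels)
    if n != len(D.ids):
        raise ValidationError("group labels must align with distance-matrix rows")
    _check_groups(labels, min_size=2)
    condensed = D.condensed()
    ranks = stats.rankdata(condensed)
    m = len(condensed)

    def stat(perm: np.ndarray) -> float:
        return _anosim_r(ranks, _within_mask(labels[perm]), m)

    observed = _anosim_r(ranks, _within_mask(labels), m)
    p, n_used = _permutation_p(observed, stat, n, n_permutations, seed, exact)
    return AnosimResult(R=float(observed), p_value=float(p), n_permutations=n_used)


def _permanova_ss(d2_condensed: np.ndarray, labels: np.ndarray, n: int) -> tuple[float, float]:
    """(SS_total, SS_within) from squared condensed distances.

    Huygens' theorem on distances: SS_T = sum of all pairwise d^2 / n, and
    SS_W sums each group's pairwise d^2 / group size (equivalent to the
    Gower-centered inner-product partition).
    """
    ss_t = d2_condensed.sum() / n
    ss_w = 0.0
    for g in np.unique(labels):
        idx = labels == g
        ng = idx.sum()
        mask = squareform(idx[:, None] & idx[None, :], checks=False).astype(bool)
        ss_w += d2_condensed[mask].sum() / ng
    return ss_t, ss_w


def permanova(
    D: DissimilarityMatrix,
    groups: Sequence,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    exact: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA (ADONIS): pseudo-F, R^2 and permutation p."""
    labels = np.asarray(groups)
    n = len(labels)
    if n != len(D.ids):
        raise ValidationError("group labels must align with distance-matrix rows")
    uniq = _check_groups(labels, min_size=1)
    g = len(uniq)
    if g >= n:
        raise ValidationError("need fewer groups than observations")
    d2 = D.condensed() ** 2

    def f_stat(lab: np.ndarray) -> float:
        ss_t, ss_w = _permanova_ss(d2, lab, n)
        ss_b = ss_t - ss_w
        if ss_w <= 0:
            return math.inf
        return (ss_b / (g - 1)) / (ss_w / (n - g))

    def stat(perm: np.ndarray) -> float:
        return f_stat(labels[perm])

    ss_t, ss_w = _permanova_ss(d2, labels, n)
    ss_b = ss_t - ss_w
    observed = f_stat(labels)
    r2 = ss_b / ss_t if ss_t > 0 else 0.0
    p, n_used = _permutation_p(observed, stat, n, n_permutations, seed, exact)
    return PermanovaResult(
        pseudo_F=float(observed),
        R_squared=float(r2),
        p_value=float(p),
        n_permutations=n_used,
    )


def pca(matrix: pd.DataFrame, k: Optional[int] = None) -> PcaResult:
    """Centered (unscaled) PCA by SVD, prcomp-style.

    Sign convention: in each component the largest-magnitude loading is
    positive, so results are reproducible across runs and row orders.
    """
    x = matrix.to_numpy(dtype=float)
    n, p = x.shape
    if n < 2 or p < 1:
        raise ValidationError("PCA needs at least 2 rows and 1 column")
    max_k = min(n - 1, p)
    if k is None:
        k = max_k
    if not 1 <= k <= max_k:
        raise ValidationError(f"k must lie in [1, {max_k}]")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2 / (n - 1)
    total_var = xc.var(axis=0, ddof=1).sum()
    loadings = vt[:k].T
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PcaResult(
        scores=scores,
        loadings=loadings,
        variance_explained=var[:k] / total_var if total_var > 0 else np.zeros(k),
    )


def embed_umap(
    matrix: pd.DataFrame,
    n_neighbors: int = 15,
    n_epochs: int = 500,
    seed: Optional[int] = None,
    metric: str = "braycurtis",
) -> Optional[pd.DataFrame]:
    """2-D embedding through the optional umap-learn backend.

    Returns None (with a warning) when the backend is not installed; the
    surrounding pipeline treats the embedding as an optional visual aid and
    proceeds without it.
    """
    try:
        import umap  # type: ignore
    except ImportError:
        logger.warning("umap-learn not installed; skipping embedding")
        return None
    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        n_epochs=n_epochs,
        n_components=2,
        metric=metric,
        random_state=seed,
    )
    coords = reducer.fit_transform(matrix.to_numpy(dtype=float))
    return pd.DataFrame(coords, index=matrix.index, columns=["umap1", "umap2"])
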