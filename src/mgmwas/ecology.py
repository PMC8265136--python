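"""Alpha diversity, beta diversity and ordination.

Shannon diversity uses the natural logarithm (the convention of the vegan
ecosystem); Bray-Curtis dissimilarity is computed on per-sample abundance
vectors; ordination is classical principal-coordinate analysis (metric MDS)
and covariance PCA. Negative PCoA eigenvalues, which arise for
non-Euclidean dissimilarities such as Bray-Curtis, are dropped with a
warning rather than corrected — the ordinations here are descriptive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .diffabund import wilcoxon_rank_sum
from .exceptions import DataError
from .profile_io import AbundanceTable, SampleMetadata


@dataclass
class DistanceMatrix:
    """A symmetric sample-by-sample dissimilarity matrix."""

    ids: list[str]
    matrix: np.ndarray
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.matrix = m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


@dataclass
class Ordination:
    """Sample coordinates on ordination axes, with explained-variance fractions."""

    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    method: str


def shannon_index(table: AbundanceTable, base: float | None = None) -> pd.Series:
    """Shannon diversity H = -sum p_i log p_i per sample, over non-zero features.

    Abundances are closed to proportions per sample first, so raw and
    relative inputs give identical results. ``base`` switches the logarithm
    base (natural log by default).
    """
    sums = table.data.sum(axis=0)
    zero = sums.index[sums == 0].tolist()
    if zero:
        raise DataError(f"all-zero sample(s): {zero}")
    p = table.data.div(sums, axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=0)
    if base is not None:
        h = h / np.log(base)
    return pd.Series(h, index=table.samples, name="shannon")


def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x,y) = 1 - 2 sum(min(x,y)) / (sum x + sum y)."""
    x = table.data.to_numpy().T  # samples x features
    if (x.sum(axis=1) == 0).sum() >= 2:
        raise DataError("two all-zero samples: Bray-Curtis undefined")
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(table.samples, d, metric="braycurtis")


def pcoa(dist: DistanceMatrix, n_axes: int = 2) -> Ordination:
    """Classical scaling: double-centre -D^2/2, eigendecompose, scale by sqrt(eigenvalue)."""
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d = dist.matrix
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if (evals < -1e-8 * max(abs(evals).max(), 1.0)).any():
        warnings.warn(
            "negative PCoA eigenvalues dropped (non-Euclidean distances)", stacklevel=2
        )
    pos = evals > max(evals.max(), 0.0) * 1e-12
    evals, evecs = evals[pos], evecs[:, pos]
    k = min(n_axes, len(evals))
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    if k == 0:  # all samples identical
        coords = np.zeros((n, n_axes))
        evals = np.zeros(n_axes)
        k = n_axes
    frac = evals[:k] / evals.sum() if evals.sum() > 0 else np.zeros(k)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return Ordination(
        pd.DataFrame(coords, index=dist.ids, columns=cols),
        np.asarray(evals[:k], dtype=float),
        np.asarray(frac, dtype=float),
        method="pcoa",
    )


def pca(table: AbundanceTable, n_axes: int = 2) -> Ordination:
    """PCA of samples: centred SVD of the samples x features matrix."""
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    x = table.data.to_numpy().T
    n = x.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least two samples")
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    evals = s**2 / (n - 1)
    k = min(n_axes, len(evals))
    coords = u[:, :k] * s[:k]
    total = evals.sum()
    frac = evals[:k] / total if total > 0 else np.zeros(k)
    cols = [f"PC{i + 1}" for i in range(k)]
    return Ordination(
        pd.DataFrame(coords, index=table.samples, columns=cols),
        evals[:k],
        frac,
        method="pca",
    )


def diversity_group_test(
    diversity: pd.Series, metadata: SampleMetadata
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum comparison of a per-sample diversity value
    between case and control groups."""
    case = diversity.loc[[s for s in metadata.case_ids() if s in diversity.index]]
    control = diversity.loc[[s for s in metadata.control_ids() if s in diversity.index]]
    return wilcoxon_rank_sum(case.to_numpy(), control.to_numpy())
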