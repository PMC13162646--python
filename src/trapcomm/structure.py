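"""Species-level similarity structure.

Jaccard distances among species occurrence profiles and Bray-Curtis
distances among species RAI profiles (sites as the dimensions), hierarchical
clustering screened over k by mean silhouette width, and a permutation test
of the Delta statistic: the difference between mean between-group and mean
within-group dissimilarities for a candidate grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

__all__ = [
    "DistanceMatrix",
    "ClusteringSolution",
    "DeltaTestResult",
    "species_distances",
    "cluster_and_silhouette",
    "delta_test",
]


@dataclass
class DistanceMatrix:
    """Labelled symmetric dissimilarity matrix with zero diagonal."""

    labels: list
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("labels must match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.values = (v + v.T) / 2
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(labels=list(df.index), values=df.to_numpy(dtype=float))


@dataclass
class ClusteringSolution:
    k: int
    labels: np.ndarray  # group assignment per point, 1-based
    mean_silhouette: float
    linkage: str

    def __post_init__(self):
        sizes = np.bincount(self.labels)
        if (sizes[1:] == 0).any() or len(sizes) - 1 != self.k:
            raise ValueError("every group must be non-empty")


@dataclass
class DeltaTestResult:
    delta_observed: float
    null_deltas: np.ndarray
    p_value: float
    n_permutations: int


def species_distances(pa: pd.DataFrame, rai: pd.DataFrame):
    """Jaccard (occurrence) and Bray-Curtis (RAI) distances among species.

    Both inputs are sites x species; columns are the species. Species never
    observed have an undefined Jaccard distance and are excluded with a
    warning from both matrices.
    """
    common = [s for s in pa.columns if s in rai.columns]
    pa = pa[common]
    rai = rai[common]
    occ = pa.to_numpy() > 0
    empty = ~occ.any(axis=0)
    if empty.any():
        dropped = [common[j] for j in np.nonzero(empty)[0]]
        warnings.warn(f"excluding never-observed species: {dropped}", stacklevel=2)
        keep = [s for s, e in zip(common, empty) if not e]
        pa, rai = pa[keep], rai[keep]
        common = keep
    jac = DistanceMatrix(common, squareform(pdist(pa.to_numpy().T.astype(bool), "jaccard")))
    bc = DistanceMatrix(common, squareform(pdist(rai.to_numpy(dtype=float).T, "braycurtis")))
    return jac, bc


def cluster_and_silhouette(
    dm: DistanceMatrix, k_range=range(2, 17), method: str = "average"
) -> list[ClusteringSolution]:
    """Agglomerative clustering of a dissimilarity matrix, one solution per k.

    Mean silhouette width s(i) = (b_i - a_i)/max(a_i, b_i) averaged over
    points, with singletons contributing 0. k values above n-1 are skipped
    with a warning.
    """
    if dm.n < 3:
        raise ValueError("need at least 3 points to cluster")
    Zl = linkage(dm.condensed(), method=method)
    solutions = []
    for k in k_range:
        if k < 2 or k > dm.n - 1:
            warnings.warn(f"k={k} outside [2, n-1]; skipped", stacklevel=2)
            continue
        # cut by merge order (robust to tied heights), 1-based group ids
        lab = cut_tree(Zl, n_clusters=k).ravel() + 1
        sil = float(silhouette_samples(dm.values, lab, metric="precomputed").mean())
        solutions.append(ClusteringSolution(k=k, labels=lab, mean_silhouette=sil, linkage=method))
    return solutions


def _delta(values: np.ndarray, labels: np.ndarray) -> float:
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), k=1)
    within = values[iu][same[iu]]
    between = values[iu][~same[iu]]
    if len(within) == 0:
        raise ValueError("no within-group pairs (all groups singletons)")
    if len(between) == 0:
        raise ValueError("no between-group pairs (single group)")
    return float(between.mean() - within.mean())


def delta_test(
    dm: DistanceMatrix, labels, n_permutations: int = 9999, seed=None
) -> DeltaTestResult:
    """Permutation test of the Delta statistic for a grouping of the points.

    Delta = mean between-group minus mean within-group dissimilarity; larger
    values indicate stronger differentiation. The null permutes group labels
    across points (group sizes preserved); the one-sided add-one p-value is
    (1 + #{Delta_null >= Delta_obs}) / (1 + n_permutations).
    """
    labels = np.asarray(labels)
    if len(labels) != dm.n:
        raise ValueError("labels must match matrix size")
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 groups")
    obs = _delta(dm.values, labels)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(dm.n, k=1)
    dvals = dm.values[iu]
    null = np.empty(n_permutations)
    for t in range(n_permutations):
        perm = rng.permutation(labels)
        same = (perm[:, None] == perm[None, :])[iu]
        null[t] = dvals[~same].mean() - dvals[same].mean()
    p = (1 + int((null >= obs - 1e-15).sum())) / (1 + n_permutations)
    return DeltaTestResult(
        delta_observed=obs, null_deltas=null, p_value=float(p), n_permutations=n_permutations
    )
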