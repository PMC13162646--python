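"""Clustering species by their environmental response coefficients.

Posterior-mean occupancy coefficients are first pulled toward zero by an
uncertainty-weighted (empirical-Bayes flavored) shrinkage factor,

    E(beta | beta_hat) = beta_hat * tau_v^2 / (tau_v^2 + sigma_iv^2),

with tau_v^2 the across-species variance of the posterior means for
predictor v and sigma_iv^2 the posterior variance of the coefficient — noisy
coefficients are damped, precise ones kept. The shrunk matrix is column
standardized, species are compared by one-minus-Pearson-correlation
distance, clustered with the Ward method, k picked by mean silhouette, and
group separation tested with PERMANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .structure import ClusteringSolution, DistanceMatrix, cluster_and_silhouette

__all__ = [
    "PermanovaResult",
    "shrink",
    "correlation_distance",
    "permanova",
    "cluster_responses",
]


def shrink(beta_hat, sigma2, tau2=None):
    """Uncertainty-weighted shrinkage of a species x predictor matrix.

    ``tau2`` defaults to the per-predictor sample variance of the posterior
    means across species. Shrinkage never flips a coefficient's sign and
    never increases its magnitude. Degenerate predictors (tau2 = 0, all
    species identical) collapse to the common value with a warning.
    """
    is_frame = isinstance(beta_hat, pd.DataFrame)
    B = np.asarray(beta_hat, dtype=float)
    S2 = np.asarray(sigma2, dtype=float)
    if B.shape != S2.shape:
        raise ValueError("beta_hat and sigma2 must have the same shape")
    if (S2 < 0).any():
        raise ValueError("posterior variances must be non-negative")
    t2 = np.var(B, axis=0, ddof=1) if tau2 is None else np.atleast_1d(np.asarray(tau2, dtype=float))
    if (t2 < 0).any():
        raise ValueError("tau2 must be positive")
    out = np.empty_like(B)
    for v in range(B.shape[1]):
        if t2[v] == 0:
            warnings.warn(
                f"predictor column {v}: zero across-species variance; "
                "shrinking to the common value",
                stacklevel=2,
            )
            out[:, v] = B[:, v].mean()
        else:
            out[:, v] = B[:, v] * t2[v] / (t2[v] + S2[:, v])
    if is_frame:
        return pd.DataFrame(out, index=beta_hat.index, columns=beta_hat.columns)
    return out


def correlation_distance(matrix, labels=None) -> DistanceMatrix:
    """1 - Pearson correlation between row vectors, after column
    standardization of the matrix."""
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = list(labels) if labels is not None else list(range(len(X)))
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        warnings.warn("dropping zero-variance predictor columns before distances", stacklevel=2)
        X = X[:, sd > 0]
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    row_sd = X.std(axis=1)
    if (row_sd == 0).any():
        bad = [labels[i] for i in np.nonzero(row_sd == 0)[0]]
        raise ValueError(f"constant coefficient vector (correlation undefined) for: {bad}")
    d = 1.0 - np.corrcoef(X)
    d = np.clip((d + d.T) / 2, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, values=d)


@dataclass
class PermanovaResult:
    r2: float
    F: float
    p_value: float
    n_permutations: int

    def to_dict(self) -> dict:
        return {"r2": self.r2, "F": self.F, "p_value": self.p_value,
                "n_permutations": self.n_permutations}


def _permanova_stats(d2: np.ndarray, labels: np.ndarray):
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.nonzero(labels == g)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    k = len(np.unique(labels))
    ss_between = ss_total - ss_within
    F = (ss_between / (k - 1)) / (ss_within / (n - k))
    return ss_between / ss_total, F


def permanova(dm: DistanceMatrix, labels, n_permutations: int = 999, seed=None) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    SS_total = sum_{i<j} d2_ij / n; SS_within sums the analogous per-group
    terms; pseudo-F = (SS_between/(k-1)) / (SS_within/(n-k)). p is the
    add-one-corrected fraction of label permutations with F at least the
    observed.
    """
    labels = np.asarray(labels)
    if len(labels) != dm.n:
        raise ValueError("labels must match matrix size")
    d2 = dm.values**2
    r2, F = _permanova_stats(d2, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        _, Fp = _permanova_stats(d2, rng.permutation(labels))
        if Fp >= F - 1e-15:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return PermanovaResult(r2=float(r2), F=float(F), p_value=float(p),
                           n_permutations=n_permutations)


def cluster_responses(
    shrunk: pd.DataFrame,
    k_range=None,
    n_permutations: int = 999,
    seed=None,
    method: str = "ward",
) -> tuple[ClusteringSolution, PermanovaResult, list[ClusteringSolution], DistanceMatrix]:
    """Ward clustering of shrunk coefficients with silhouette k-selection.

    Returns (best solution, PERMANOVA at the best k, all screened solutions,
    the correlation distance matrix). Ties in mean silhouette go to the
    smaller k.
    """
    if len(shrunk) < 3:
        raise ValueError("need at least 3 species")
    dm = correlation_distance(shrunk)
    if k_range is None:
        k_range = range(2, min(16, dm.n - 1) + 1)
    solutions = cluster_and_silhouette(dm, k_range=k_range, method=method)
    if not solutions:
        raise ValueError("no attainable clustering solutions in k_range")
    best = max(solutions, key=lambda s: (s.mean_silhouette, -s.k))
    pv = permanova(dm, best.labels, n_permutations=n_permutations, seed=seed)
    return best, pv, solutions, dm
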