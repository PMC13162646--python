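"""Non-metric multidimensional scaling and environmental vector fitting.

NMDS minimizes Kruskal stress-1,

    stress = sqrt( sum_ij (d_ij - dhat_ij)^2 / sum_ij d_ij^2 ),

where d are configuration distances and dhat is the isotonic (monotone
non-decreasing) regression of d on the rank order of the input
dissimilarities (primary tie handling: tied dissimilarities may order their
dhat freely to reduce stress). Optimization is SMACOF-style majorization
(Guttman transform) alternated with the isotonic fit, from multiple random
starts plus one classical-scaling start.

envfit regresses a covariate on the ordination scores; the arrow direction
is the unit coefficient vector, r^2 the coefficient of determination, and
significance comes from permuting the covariate across points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

from .structure import DistanceMatrix

__all__ = ["OrdinationResult", "EnvfitResult", "nmds", "stress1", "envfit", "envfit_table"]


@dataclass
class OrdinationResult:
    scores: np.ndarray  # n_points x n_dims, centered, principal-axis rotated
    stress: float  # Kruskal stress-1
    n_starts: int
    converged: bool
    labels: list = field(default_factory=list)
    stress_history: np.ndarray | None = None  # raw-stress trace of the best start

    def to_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i+1}" for i in range(self.scores.shape[1])]
        idx = self.labels if self.labels else range(len(self.scores))
        return pd.DataFrame(self.scores, index=idx, columns=cols)


def _isotonic_dhat(d: np.ndarray, diss: np.ndarray) -> np.ndarray:
    """Monotone fit of configuration distances on dissimilarity order.

    Primary tie treatment: within tied dissimilarities, points are taken in
    order of the current configuration distances, which lets the fit track
    them exactly.
    """
    order = np.lexsort((d, diss))
    iso = IsotonicRegression(increasing=True)
    dhat_sorted = iso.fit_transform(np.arange(len(d)), d[order])
    dhat = np.empty_like(d)
    dhat[order] = dhat_sorted
    return dhat


def stress1(config: np.ndarray, dm: DistanceMatrix) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    d = pdist(np.asarray(config, dtype=float))
    dhat = _isotonic_dhat(d, dm.condensed())
    denom = float((d**2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _procrustes_rmse(A: np.ndarray, B: np.ndarray) -> float:
    """Root-mean-square disagreement of two configurations after centering,
    scaling to unit RMS, and optimal orthogonal alignment."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    A = A / np.sqrt((A**2).mean())
    B = B / np.sqrt((B**2).mean())
    R, _ = orthogonal_procrustes(B, A)
    return float(np.sqrt(((A - B @ R) ** 2).mean()))


def _classical_start(dm: DistanceMatrix, n_dims: int) -> np.ndarray:
    D2 = dm.values**2
    n = dm.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    w, v = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:n_dims]
    return v[:, idx] * np.sqrt(np.clip(w[idx], 0, None))


def _smacof_start(X, diss, max_iter, tol):
    n = X.shape[0]
    d = pdist(X)
    dhat = _isotonic_dhat(d, diss)
    raw = float(((d - dhat) ** 2).sum())
    history = [raw]
    for _ in range(max_iter):
        # Guttman transform with the current disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        Bm = -squareform(ratio)
        np.fill_diagonal(Bm, -Bm.sum(axis=1))
        X = (Bm @ X) / n
        d = pdist(X)
        dhat = _isotonic_dhat(d, diss)
        new_raw = float(((d - dhat) ** 2).sum())
        history.append(new_raw)
        if raw - new_raw < tol * max(raw, 1e-12):
            raw = new_raw
            break
        raw = new_raw
    denom = float((d**2).sum())
    s1 = np.sqrt(raw / denom) if denom > 0 else 0.0
    return X, float(s1), np.array(history)


def nmds(
    dm: DistanceMatrix,
    n_dims: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-9,
    seed=None,
) -> OrdinationResult:
    """Best NMDS configuration over random starts plus a classical-scaling
    start; scores centered and rotated to principal axes.

    Convergence is declared when a second start reproduces the best
    configuration (Procrustes RMSE < 1e-4); otherwise the best-effort result
    is returned with ``converged=False`` and a warning.
    """
    if dm.n <= n_dims + 1:
        raise ValueError("need more points than n_dims + 1")
    diss = dm.condensed()
    if np.ptp(diss) == 0:
        warnings.warn("all dissimilarities equal; degenerate ordination", stacklevel=2)
        X = _classical_start(dm, n_dims)
        return OrdinationResult(
            scores=X - X.mean(axis=0), stress=stress1(X, dm), n_starts=1,
            converged=False, labels=list(dm.labels),
        )
    rng = np.random.default_rng(seed)
    results = []
    for start in range(n_starts):
        if start == 0:
            X0 = _classical_start(dm, n_dims)
        else:
            X0 = rng.standard_normal((dm.n, n_dims)) * diss.mean()
        results.append(_smacof_start(X0, diss, max_iter, tol))
    results.sort(key=lambda r: r[1])
    X, best_stress, history = results[0]
    converged = False
    for Xo, so, _ in results[1:]:
        if so - best_stress > 1e-3:
            continue
        if best_stress < 1e-3:
            # a second start reproduced an (effectively) perfect fit; the
            # configuration itself is not unique under rank-only constraints
            converged = True
            break
        if _procrustes_rmse(X, Xo) < 1e-4:
            converged = True
            break
    if not converged:
        warnings.warn("NMDS: no two starts agreed; best-effort result", stacklevel=2)
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    # deterministic sign: largest-magnitude coordinate on each axis positive
    for j in range(n_dims):
        if X[np.argmax(np.abs(X[:, j])), j] < 0:
            X[:, j] = -X[:, j]
    return OrdinationResult(
        scores=X, stress=best_stress, n_starts=n_starts, converged=converged,
        labels=list(dm.labels), stress_history=history,
    )


@dataclass
class EnvfitResult:
    variable: str
    direction: np.ndarray  # unit vector in ordination space
    r2: float
    p_value: float
    n_permutations: int


def envfit(
    scores: np.ndarray, covariate, n_permutations: int = 999, seed=None, name: str = "env"
) -> EnvfitResult:
    """Fit one environmental vector onto ordination scores.

    r^2 is the coefficient of determination of the least-squares regression
    of the covariate on the (centered) scores; the permutation p-value is
    one-sided for large r^2, add-one corrected.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if len(y) != len(X):
        raise ValueError("covariate must have one value per ordination point")
    if np.std(y) == 0:
        raise ValueError(f"covariate {name!r} has zero variance")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    Q, _ = np.linalg.qr(Xc)
    coef, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
    proj = Q.T @ yc
    r2 = float(proj @ proj / (yc @ yc))
    nrm = np.linalg.norm(coef)
    direction = coef / nrm if nrm > 0 else coef
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for t in range(n_permutations):
        yp = yc[rng.permutation(len(yc))]
        pr = Q.T @ yp
        perms[t] = pr @ pr / (yp @ yp)
    p = (1 + int((perms >= r2 - 1e-15).sum())) / (1 + n_permutations)
    return EnvfitResult(
        variable=name, direction=direction, r2=r2, p_value=float(p),
        n_permutations=n_permutations,
    )


def envfit_table(
    scores: np.ndarray, env: pd.DataFrame, n_permutations: int = 999, seed=None
) -> pd.DataFrame:
    """envfit for every column of an environment table; one row per variable."""
    ss = np.random.SeedSequence(seed)
    rows = []
    for child, col in zip(ss.spawn(env.shape[1]), env.columns):
        r = envfit(
            scores, env[col].to_numpy(), n_permutations=n_permutations,
            seed=child, name=col,
        )
        rows.append(
            {"variable": col, "r2": r.r2, "p_value": r.p_value,
             "dir1": r.direction[0], "dir2": r.direction[1]}
        )
    return pd.DataFrame(rows).set_index("variable")
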