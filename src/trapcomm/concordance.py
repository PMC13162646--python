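"""Mantel concordance among species-level distance matrices.

The Mantel statistic is the Pearson correlation between the corresponding
upper-triangle entries of two distance matrices over the same labels; the
null permutes the rows and columns of one matrix simultaneously. The default
alternative is one-sided for positive association (concordance), with
add-one correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .structure import DistanceMatrix

__all__ = ["MantelResult", "mantel", "mantel_triplet"]


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    matrix_pair: tuple
    alternative: str = "greater"
    method: str = "pearson"

    def to_dict(self) -> dict:
        return {
            "r": self.r, "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "matrix_pair": list(self.matrix_pair),
            "alternative": self.alternative, "method": self.method,
        }


def _triangle(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_permutations: int = 9999,
    seed=None,
    alternative: str = "greater",
    method: str = "pearson",
) -> MantelResult:
    """Mantel test between two labelled distance matrices.

    Matrices must carry identical labels in identical order and n >= 4.
    ``method`` may be "pearson" (default) or "spearman" (ranked entries);
    ``alternative`` is "greater" (positive concordance) or "two-sided".
    """
    if list(dm_a.labels) != list(dm_b.labels):
        raise ValueError("distance matrices must share labels in the same order")
    n = dm_a.n
    if n < 4:
        raise ValueError("need at least 4 points for a Mantel test")
    A = dm_a.values
    B = dm_b.values
    xa = _triangle(A)
    if method == "spearman":
        xa = rankdata(xa)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    if np.std(xa) == 0 or np.std(_triangle(B)) == 0:
        raise ValueError("zero variance in a distance triangle")
    xa = (xa - xa.mean()) / xa.std()

    def corr_with(Bperm):
        xb = _triangle(Bperm)
        if method == "spearman":
            xb = rankdata(xb)
        sd = xb.std()
        if sd == 0:
            return 0.0
        xb = (xb - xb.mean()) / sd
        return float((xa * xb).mean())

    r_obs = corr_with(B)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for t in range(n_permutations):
        perm = rng.permutation(n)
        null[t] = corr_with(B[np.ix_(perm, perm)])
    if alternative == "greater":
        p = (1 + int((null >= r_obs - 1e-15).sum())) / (1 + n_permutations)
    elif alternative == "two-sided":
        p = (1 + int((np.abs(null) >= abs(r_obs) - 1e-15).sum())) / (1 + n_permutations)
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    return MantelResult(
        r=r_obs, p_value=float(p), n_permutations=n_permutations,
        matrix_pair=("A", "B"), alternative=alternative, method=method,
    )


def mantel_triplet(
    jaccard: DistanceMatrix,
    braycurtis: DistanceMatrix,
    beta_dm: DistanceMatrix,
    n_permutations: int = 9999,
    seed=None,
) -> dict[str, MantelResult]:
    """The three pairwise tests: occurrence vs activity vs response space."""
    ss = np.random.SeedSequence(seed)
    pairs = {
        "jac_bc": (jaccard, braycurtis),
        "jac_beta": (jaccard, beta_dm),
        "bc_beta": (braycurtis, beta_dm),
    }
    out = {}
    for child, (name, (a, b)) in zip(ss.spawn(len(pairs)), pairs.items()):
        res = mantel(a, b, n_permutations=n_permutations, seed=child)
        res.matrix_pair = tuple(name.split("_"))
        out[name] = res
    return out
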