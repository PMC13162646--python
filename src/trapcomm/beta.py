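"""Site-level beta diversity and a fixed-fixed randomization null.

Pairwise Jaccard dissimilarity is partitioned into its turnover and
nestedness components (Baselga family): for a site pair sharing a species,
with b and c species unique to each site,

    jac = (b + c) / (a + b + c)
    jtu = 2 min(b, c) / (a + 2 min(b, c))
    jne = jac - jtu

The null model randomizes the presence-absence matrix with sequential
checkerboard swaps, preserving every site's richness (row sums) and every
species' occurrence frequency (column sums), and compares the observed mean
pairwise Jaccard against the sampled null distribution via a standardized
effect size and a two-sided add-one-corrected p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

__all__ = ["BetaPartition", "NullModelResult", "pairwise_partition", "swap_null", "swap_samples"]


@dataclass
class BetaPartition:
    """Pairwise Jaccard / turnover / nestedness, condensed over site pairs."""

    pairs: list  # (site_i, site_j) label tuples
    jac: np.ndarray
    jtu: np.ndarray
    jne: np.ndarray

    @property
    def summary(self) -> dict:
        mean_jac = float(self.jac.mean())
        mean_jtu = float(self.jtu.mean())
        mean_jne = float(self.jne.mean())
        return {
            "mean_jac": mean_jac,
            "mean_jtu": mean_jtu,
            "mean_jne": mean_jne,
            "turnover_fraction": mean_jtu / mean_jac if mean_jac > 0 else np.nan,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_a": [p[0] for p in self.pairs],
                "site_b": [p[1] for p in self.pairs],
                "jac": self.jac,
                "jtu": self.jtu,
                "jne": self.jne,
            }
        )


def _as_binary(pa) -> tuple[np.ndarray, list]:
    if isinstance(pa, pd.DataFrame):
        m = pa.to_numpy()
        labels = list(pa.index)
    else:
        m = np.asarray(pa)
        labels = list(range(m.shape[0]))
    if not np.isin(m, (0, 1)).all():
        raise ValueError("presence-absence matrix must be binary")
    return m.astype(np.int64), labels


def pairwise_partition(pa) -> BetaPartition:
    """Partition pairwise Jaccard dissimilarity into turnover and nestedness.

    Empty sites (all-zero rows) are dropped with a warning; a pair of empty
    sites would be undefined. ``jtu + jne == jac`` holds exactly per pair.
    """
    m, labels = _as_binary(pa)
    empty = m.sum(axis=1) == 0
    if empty.any():
        dropped = [labels[i] for i in np.nonzero(empty)[0]]
        warnings.warn(f"dropping empty sites: {dropped}", stacklevel=2)
        m = m[~empty]
        labels = [l for l, e in zip(labels, empty) if not e]
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 non-empty sites")
    shared = m @ m.T  # a
    rich = m.sum(axis=1)
    iu, ju = np.triu_indices(n, k=1)
    a = shared[iu, ju].astype(float)
    b = (rich[iu] - shared[iu, ju]).astype(float)
    c = (rich[ju] - shared[iu, ju]).astype(float)
    tot = a + b + c
    jac = (b + c) / tot
    mn = np.minimum(b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        jtu = np.where(mn > 0, 2 * mn / (a + 2 * mn), 0.0)
    jne = jac - jtu
    pairs = [(labels[i], labels[j]) for i, j in zip(iu, ju)]
    return BetaPartition(pairs=pairs, jac=jac, jtu=jtu, jne=jne)


@dataclass
class NullModelResult:
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    n_randomizations: int
    seed: int | None = None
    burn_in: int | None = None
    thin: int | None = None

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "ses": self.ses,
            "p_value": self.p_value,
            "n_randomizations": self.n_randomizations,
            "seed": self.seed,
            "burn_in": self.burn_in,
            "thin": self.thin,
        }


def _mean_jaccard(m: np.ndarray) -> float:
    return float(pdist(m.astype(bool), metric="jaccard").mean())


def _swap_chain(m, rng, n_swaps, max_attempts):
    """Advance the chain by ``n_swaps`` successful checkerboard swaps in place.

    Returns False if no swap succeeded within ``max_attempts`` draws.
    """
    nr, nc = m.shape
    done = 0
    attempts = 0
    while done < n_swaps:
        if attempts >= max_attempts:
            return False
        k = min(4096, 4 * (max_attempts - attempts))
        rows = rng.integers(0, nr, size=(k, 2))
        cols = rng.integers(0, nc, size=(k, 2))
        for t in range(k):
            r1, r2 = rows[t]
            c1, c2 = cols[t]
            if r1 == r2 or c1 == c2:
                attempts += 1
                continue
            a, b = m[r1, c1], m[r1, c2]
            c_, d = m[r2, c1], m[r2, c2]
            if a == d and b == c_ and a != b:
                m[r1, c1] = b
                m[r1, c2] = a
                m[r2, c1] = d
                m[r2, c2] = c_
                done += 1
                attempts = 0
                if done >= n_swaps:
                    break
            else:
                attempts += 1
    return True


def swap_samples(pa, n_samples, burn_in=None, thin=None, seed=None):
    """Yield ``n_samples`` matrices from the checkerboard-swap chain.

    ``burn_in`` defaults to 10x the matrix fill (successful swaps) and
    ``thin`` to the fill, counted in successful swaps. Raises RuntimeError if
    the matrix admits no swappable 2x2 submatrix.
    """
    m, _ = _as_binary(pa)
    m = m.copy()
    fill = int(m.sum())
    if fill == 0 or fill == m.size:
        raise RuntimeError("matrix has no swappable 2x2 checkerboard submatrix")
    burn_in = 10 * fill if burn_in is None else burn_in
    thin = max(1, fill) if thin is None else thin
    rng = np.random.default_rng(seed)
    max_attempts = max(200_000, 200 * m.size)
    if not _swap_chain(m, rng, burn_in, max_attempts):
        raise RuntimeError("matrix has no swappable 2x2 checkerboard submatrix")
    for _ in range(n_samples):
        _swap_chain(m, rng, thin, max_attempts)
        yield m.copy()


def swap_null(
    pa,
    n_randomizations: int = 999,
    burn_in: int | None = None,
    thin: int | None = None,
    seed: int | None = None,
    statistic=_mean_jaccard,
) -> NullModelResult:
    """Fixed-fixed swap null for a community-matrix statistic.

    The default statistic is the mean pairwise Jaccard dissimilarity among
    sites. p is two-sided with add-one correction:
    ``2 * min(P(null >= obs), P(null <= obs))`` capped at 1, each tail
    estimated as (count + 1) / (n + 1). A matrix with no swappable
    checkerboard yields a degenerate result (observed returned, p = 1).
    """
    m, _ = _as_binary(pa)
    obs = statistic(m)
    try:
        null = np.array(
            [statistic(s) for s in swap_samples(m, n_randomizations, burn_in, thin, seed)]
        )
    except RuntimeError:
        warnings.warn("no swappable submatrix; degenerate null", stacklevel=2)
        return NullModelResult(obs, obs, 0.0, np.nan, 1.0, 0, seed, burn_in, thin)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    ses = (obs - null_mean) / null_sd if null_sd > 0 else np.nan
    n = len(null)
    p_hi = (np.sum(null >= obs) + 1) / (n + 1)
    p_lo = (np.sum(null <= obs) + 1) / (n + 1)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    fill = int(m.sum())
    return NullModelResult(
        observed=obs,
        null_mean=null_mean,
        null_sd=null_sd,
        ses=float(ses),
        p_value=float(p),
        n_randomizations=n,
        seed=seed,
        burn_in=10 * fill if burn_in is None else burn_in,
        thin=max(1, fill) if thin is None else thin,
    )
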