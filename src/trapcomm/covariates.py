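"""Environmental predictor preparation.

Spectral vegetation indices, covariate standardization with a quadratic
elevation term, composite water distance, and iterative VIF screening for
collinearity. This module consumes per-site covariate tables only; raster
extraction (land cover, DEM derivatives, reflectance compositing) is assumed
to have happened upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DegenerateColumnError",
    "SiteCovariateTable",
    "OCCUPANCY_PREDICTORS",
    "compute_ndvi_evi",
    "standardize",
    "composite_water_distance",
    "vif_screen",
]

#: Occupancy predictor set: linear + quadratic elevation, terrain, vegetation
#: productivity, land-cover distances, and recent anthropogenic disturbance.
OCCUPANCY_PREDICTORS = [
    "ele", "ele2", "slope", "northness", "twi", "ndvi",
    "dist_tree", "dist_shrub", "dist_grass", "dist_bare",
    "dist_crop", "dist_built", "disturb",
]


class DegenerateColumnError(ValueError):
    """A covariate column cannot be standardized (zero variance)."""


def compute_ndvi_evi(nir, red, blue):
    """Vegetation indices from surface reflectance fractions.

    NDVI = (NIR - Red) / (NIR + Red)
    EVI  = 2.5 (NIR - Red) / (NIR + 6 Red - 7.5 Blue + 1)

    Inputs are reflectance fractions in [0, 1]; scalars or arrays. A zero
    denominator yields NaN with a warning.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    blue = np.asarray(blue, dtype=float)
    for name, arr in (("nir", nir), ("red", red), ("blue", blue)):
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError(f"{name} reflectance must lie in [0, 1]")
    ndvi_den = nir + red
    evi_den = nir + 6.0 * red - 7.5 * blue + 1.0
    bad = (ndvi_den == 0) | (evi_den == 0)
    if np.any(bad):
        warnings.warn("zero denominator in NDVI/EVI; returning NaN", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(ndvi_den != 0, (nir - red) / ndvi_den, np.nan)
        evi = np.where(evi_den != 0, 2.5 * (nir - red) / evi_den, np.nan)
    if ndvi.ndim == 0:
        return float(ndvi), float(evi)
    return ndvi, evi


def standardize(table: pd.DataFrame, columns=None, ddof: int = 1) -> pd.DataFrame:
    """Center to mean 0 and scale to sample SD 1 (n-1 denominator).

    If ``ele`` is among the standardized columns, ``ele2`` is (re)computed as
    the square of standardized elevation — it is *not* re-standardized, so the
    signs of linear and quadratic elevation coefficients remain interpretable
    as response-curve shape.

    Raises
    ------
    DegenerateColumnError
        If any requested column has zero variance; the message names it.
    """
    out = table.copy()
    cols = list(columns) if columns is not None else [
        c for c in table.columns if c != "ele2" and pd.api.types.is_numeric_dtype(table[c])
    ]
    for c in cols:
        x = out[c].to_numpy(dtype=float)
        sd = np.nanstd(x, ddof=ddof)
        if not np.isfinite(sd) or sd == 0:
            raise DegenerateColumnError(f"column {c!r} has zero variance; cannot standardize")
        out[c] = (x - np.nanmean(x)) / sd
    if "ele" in cols:
        out["ele2"] = out["ele"] ** 2
    return out


def composite_water_distance(d_esa, d_river):
    """Minimum distance to water across two sources (elementwise).

    Either source may be missing (NaN) per site, in which case the other is
    used; both missing propagates NaN with a warning.
    """
    a = np.asarray(d_esa, dtype=float)
    b = np.asarray(d_river, dtype=float)
    both = np.isnan(a) & np.isnan(b)
    if np.any(both):
        warnings.warn(
            f"{int(both.sum())} site(s) missing both water-distance sources",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.fmin(a, b)


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1/(1-R^2) from regressing it on the others."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - ss_res / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif_screen(table: pd.DataFrame, predictors, threshold: float = 5.0):
    """Iteratively drop the predictor with the largest VIF while any exceeds
    the threshold.

    Ties are broken by column order (first wins); perfectly collinear columns
    have infinite VIF and are dropped first. Returns ``(retained, report)``
    where report is a list of per-round dicts ``{"vif": {name: value},
    "dropped": name or None}``.
    """
    predictors = list(predictors)
    if len(predictors) < 3:
        raise ValueError("need at least 3 predictors for VIF screening")
    if len(table) <= len(predictors):
        raise ValueError("need more sites than predictors")
    retained = predictors.copy()
    report = []
    while True:
        X = table[retained].to_numpy(dtype=float)
        vifs = {name: _vif_one(X, j) for j, name in enumerate(retained)}
        worst = max(retained, key=lambda nm: vifs[nm])
        if vifs[worst] > threshold:
            report.append({"vif": vifs, "dropped": worst})
            retained.remove(worst)
            if len(retained) < 2:
                break
        else:
            report.append({"vif": vifs, "dropped": None})
            break
    return retained, report


@dataclass
class SiteCovariateTable:
    """Per-site environmental predictors, raw and standardized.

    ``standardized`` carries mean-0 / SD-1 columns plus ``ele2``, the square
    of standardized elevation.
    """

    raw: pd.DataFrame
    standardized: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.standardized is None:
            self.standardized = standardize(self.raw.copy())

    @property
    def site_ids(self):
        return list(self.raw.index)

    @property
    def n_sites(self) -> int:
        return len(self.raw)

    def predictor_matrix(self, names=OCCUPANCY_PREDICTORS) -> np.ndarray:
        """Standardized design matrix (sites x predictors) in a fixed order."""
        missing = [n for n in names if n not in self.standardized.columns]
        if missing:
            raise KeyError(f"predictors not in covariate table: {missing}")
        return self.standardized[list(names)].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path) -> "SiteCovariateTable":
        raw = pd.read_csv(path, index_col="site_id")
        return cls(raw=raw)

    def to_csv(self, path) -> None:
        self.raw.to_csv(path, index_label="site_id")
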