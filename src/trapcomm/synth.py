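"""Synthetic camera-trap surveys with known community structure.

The generator emulates a montane reserve survey: ~109 sites spread over a
1330-4551 m elevational gradient, ~17 mammal / galliform species organized in
two guilds with contrasting occupancy responses (opposite signs on elevation
and on forest/shrub distances), imperfect detection driven by effort, water
distance and camera type, and human/livestock detections that define the
recent-disturbance covariate. Output files (records, deployments, covariates,
truth) feed the downstream analysis unchanged, so every stage is testable
without field data.

All randomness flows from a single scenario seed; a fixed seed reproduces
every emitted file bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .covariates import SiteCovariateTable, composite_water_distance, standardize
from .events import workday_matrix

__all__ = [
    "ConfigurationError",
    "SpeciesTruth",
    "SurveyScenario",
    "TruthSet",
    "DEFAULT_GUILDS",
    "generate_covariates",
    "generate_truth",
    "sample_occupancy",
    "generate_records",
    "generate_survey",
    "write_survey",
]

SURVEY_START = pd.Timestamp("2017-10-01")

#: Pseudo-species whose pooled RAI defines the recent-disturbance covariate.
DISTURBANCE_SPECIES = ("human", "livestock")

#: Occupancy predictors the generator parameterizes (order fixed).
PREDICTORS = [
    "ele", "ele2", "slope", "northness", "twi", "ndvi",
    "dist_tree", "dist_shrub", "dist_grass", "dist_bare",
    "dist_crop", "dist_built", "disturb",
]

#: Two contrasting response archetypes: a high-elevation forest guild and a
#: low-elevation open/edge guild, opposite in sign on elevation and on
#: forest/shrub distance, giving response clustering a recoverable 2-group
#: truth.
DEFAULT_GUILDS = [
    {
        "name": "montane_forest",
        "alpha": 0.2,
        "beta": {"ele": 1.3, "ele2": -0.4, "dist_tree": -0.7, "dist_shrub": -0.5,
                 "ndvi": 0.3, "disturb": -0.6},
    },
    {
        "name": "valley_edge",
        "alpha": 0.0,
        "beta": {"ele": -1.3, "ele2": -0.1, "dist_tree": 0.4, "dist_shrub": 0.6,
                 "ndvi": -0.2, "disturb": 0.3},
    },
]


class ConfigurationError(ValueError):
    """Invalid survey scenario configuration."""


@dataclass(frozen=True)
class SpeciesTruth:
    """Generative parameters for one species (all on the logit scale)."""

    species_id: str
    alpha: float
    beta: tuple  # aligned with PREDICTORS
    gamma: tuple  # (intercept, workday, dist_water, camera_type)
    event_rate: float  # expected raw bursts per detected occasion, >= 1
    guild: str

    def __post_init__(self):
        if len(self.beta) != len(PREDICTORS):
            raise ConfigurationError("beta length must equal number of predictors")
        if self.event_rate < 1:
            raise ConfigurationError("event_rate must be >= 1")


@dataclass
class SurveyScenario:
    """Design of one synthetic survey; the seed fully determines the output."""

    n_sites: int = 109
    n_species: int = 17
    survey_days: int = 336  # 24 fourteen-day occasions
    occasion_length_days: int = 14
    ele_range: tuple = (1330.0, 4551.0)
    guild_archetypes: list = field(default_factory=lambda: [dict(g) for g in DEFAULT_GUILDS])
    covariate_correlations: np.ndarray | None = None  # for (slope, northness, twi, ndvi, evi, tri)
    disturbance_rate: float = 4.0  # human+livestock events per 100 days at an average site
    coef_spread: float = 0.3  # species scatter around the guild archetype
    alpha_spread: float = 0.5  # species scatter of the occupancy intercept
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 2:
            raise ConfigurationError("n_sites must be >= 2")
        if self.occasion_length_days < 1:
            raise ConfigurationError("occasion_length_days must be >= 1")
        if self.n_species < 2:
            raise ConfigurationError("n_species must be >= 2")
        if self.disturbance_rate < 0:
            raise ConfigurationError("disturbance_rate must be >= 0")

    @property
    def n_occasions(self) -> int:
        return self.survey_days // self.occasion_length_days

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


_GAUSS_COLS = ["slope", "northness", "twi", "ndvi", "evi", "tri"]


def _default_correlations() -> np.ndarray:
    c = np.eye(len(_GAUSS_COLS))
    idx = {n: i for i, n in enumerate(_GAUSS_COLS)}
    for a, b, r in [("ndvi", "evi", 0.85), ("slope", "tri", 0.7), ("twi", "slope", -0.3)]:
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
    return c


def generate_covariates(scenario: SurveyScenario) -> SiteCovariateTable:
    """Draw per-site raw covariates and return them with standardized copies.

    Elevation is uniform over the scenario range; the terrain/vegetation
    block is multivariate Gaussian with the scenario's correlation matrix;
    land-cover distances are lognormal (non-negative); water distance is the
    composite minimum of two sources; ``disturb`` holds the latent true
    disturbance intensity (expected human+livestock events per 100 days),
    replaced downstream by the RAI measured from the generated records.
    """
    rng = scenario.rng(1)
    n = scenario.n_sites
    corr = (
        np.asarray(scenario.covariate_correlations, dtype=float)
        if scenario.covariate_correlations is not None
        else _default_correlations()
    )
    if corr.shape != (len(_GAUSS_COLS), len(_GAUSS_COLS)):
        raise ConfigurationError(
            f"covariate_correlations must be {len(_GAUSS_COLS)}x{len(_GAUSS_COLS)}"
        )
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as e:
        raise ConfigurationError("covariate correlation matrix is not positive definite") from e

    ele = rng.uniform(*scenario.ele_range, size=n)
    g = rng.standard_normal((n, len(_GAUSS_COLS))) @ chol.T
    raw = pd.DataFrame(index=pd.Index([f"C{i+1:03d}" for i in range(n)], name="site_id"))
    raw["ele"] = ele
    raw["slope"] = np.clip(22.0 + 9.0 * g[:, 0], 0.0, 70.0)
    raw["northness"] = np.clip(0.55 * g[:, 1], -1.0, 1.0)
    raw["twi"] = 6.5 + 1.8 * g[:, 2]
    raw["ndvi"] = np.clip(0.62 + 0.12 * g[:, 3], 0.0, 1.0)
    raw["evi"] = np.clip(0.45 + 0.11 * g[:, 4], 0.0, 1.0)
    raw["tri"] = np.clip(16.0 + 7.0 * g[:, 5], 0.0, None)
    for name, scale in [
        ("dist_tree", 120.0), ("dist_shrub", 260.0), ("dist_grass", 420.0),
        ("dist_crop", 2500.0), ("dist_built", 3200.0), ("dist_bare", 900.0),
    ]:
        raw[name] = scale * rng.lognormal(mean=0.0, sigma=0.8, size=n)
    d_esa = 600.0 * rng.lognormal(0.0, 0.9, size=n)
    d_river = 450.0 * rng.lognormal(0.0, 0.9, size=n)
    raw["dist_water"] = composite_water_distance(d_esa, d_river)
    # latent disturbance intensity; mean equals the scenario rate
    gd = rng.standard_normal(n)
    raw["disturb"] = scenario.disturbance_rate * np.exp(0.7 * gd - 0.245)
    if scenario.disturbance_rate == 0:
        raw["disturb"] = 0.0
        std = standardize(raw, columns=[c for c in raw.columns if c != "disturb"])
        std["disturb"] = 0.0
    else:
        std = standardize(raw)
    return SiteCovariateTable(raw=raw, standardized=std)


@dataclass
class TruthSet:
    """Species parameters plus latent occupancy for one scenario."""

    species: list  # of SpeciesTruth
    psi: np.ndarray  # n_species x n_sites occupancy probabilities
    z: np.ndarray  # n_species x n_sites latent occupancy (0/1)
    site_ids: list

    @property
    def guilds(self) -> dict[str, str]:
        return {t.species_id: t.guild for t in self.species}

    def beta_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            [t.beta for t in self.species],
            index=[t.species_id for t in self.species],
            columns=PREDICTORS,
        )


def sample_occupancy(psi: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Latent occupancy draws z ~ Bernoulli(psi)."""
    return (rng.random(psi.shape) < psi).astype(int)


def generate_truth(scenario: SurveyScenario, cov: SiteCovariateTable) -> TruthSet:
    """Species-specific occupancy/detection parameters and latent occupancy.

    psi_si = expit(alpha_s + sum_v beta_sv Z_iv) on the standardized
    predictor matrix; species are assigned to guild archetypes round-robin
    and scatter around the archetype coefficients with SD ``coef_spread``.
    """
    rng = scenario.rng(2)
    Z = cov.predictor_matrix(PREDICTORS)
    species = []
    for s in range(scenario.n_species):
        arch = scenario.guild_archetypes[s % len(scenario.guild_archetypes)]
        beta_mean = np.array([arch.get("beta", {}).get(p, 0.0) for p in PREDICTORS])
        beta = beta_mean + scenario.coef_spread * rng.standard_normal(len(PREDICTORS))
        alpha = arch.get("alpha", 0.0) + scenario.alpha_spread * rng.standard_normal()
        gamma = (
            0.0 + 0.3 * rng.standard_normal(),
            0.4 + 0.15 * rng.standard_normal(),
            -0.3 + 0.15 * rng.standard_normal(),
            0.3 + 0.15 * rng.standard_normal(),
        )
        event_rate = 1.0 + rng.exponential(0.8)
        species.append(
            SpeciesTruth(
                species_id=f"sp{s+1:02d}",
                alpha=float(alpha),
                beta=tuple(float(b) for b in beta),
                gamma=tuple(float(g) for g in gamma),
                event_rate=float(event_rate),
                guild=arch.get("name", f"guild{s % len(scenario.guild_archetypes)}"),
            )
        )
    alpha_v = np.array([t.alpha for t in species])
    beta_m = np.array([t.beta for t in species])
    psi = expit(alpha_v[:, None] + beta_m @ Z.T)
    z = sample_occupancy(psi, rng)
    return TruthSet(species=species, psi=psi, z=z, site_ids=cov.site_ids)


def _deployments(scenario: SurveyScenario, site_ids, rng) -> pd.DataFrame:
    start0 = SURVEY_START
    end0 = SURVEY_START + pd.Timedelta(days=scenario.survey_days - 1)
    rows = []
    for sid in site_ids:
        start = start0
        end = end0
        if rng.random() < 0.2:  # late deployment
            start = start0 + pd.Timedelta(days=int(rng.integers(1, 22)))
        if rng.random() < 0.15:  # early failure
            end = end0 - pd.Timedelta(days=int(rng.integers(1, 29)))
        rows.append(
            {
                "camera_id": sid,
                "start": start,
                "end": end + pd.Timedelta(hours=23, minutes=59),
                "camera_type": "A" if rng.random() < 0.5 else "B",
            }
        )
    return pd.DataFrame(rows)


def generate_records(
    scenario: SurveyScenario, truth: TruthSet, cov: SiteCovariateTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Timestamped detection records and camera deployments.

    For each occupied site-occasion with effort, detection happens with
    p_sij = expit(g0 + g1*workday_std + g2*dist_water + g3*camera_type); a
    detected occasion emits 1 + Poisson(event_rate - 1) bursts of 1-3 records
    within 5 minutes (so the 30-min independence filter is exercised), placed
    on random operational days. Human and livestock records are generated as
    Poisson streams from the latent disturbance intensity.
    """
    rng = scenario.rng(3)
    site_ids = truth.site_ids
    deployments = _deployments(scenario, site_ids, rng)
    n_occ = scenario.n_occasions
    wd = workday_matrix(
        deployments, SURVEY_START, n_occ, scenario.occasion_length_days, site_ids=site_ids
    )
    wdv = wd.to_numpy(dtype=float)
    surveyed = wdv > 0
    wstd = np.zeros_like(wdv)
    if surveyed.sum() > 1 and wdv[surveyed].std(ddof=1) > 0:
        wstd[surveyed] = (wdv[surveyed] - wdv[surveyed].mean()) / wdv[surveyed].std(ddof=1)
    dw = cov.standardized["dist_water"].to_numpy()
    ctype = deployments.set_index("camera_id").loc[site_ids, "camera_type"].to_numpy()
    ct = (ctype == "B").astype(float)

    # operational days per site and occasion, for timestamp placement
    op_days: dict[str, dict[int, list]] = {}
    for _, row in deployments.iterrows():
        days = pd.date_range(row["start"].normalize(), row["end"].normalize(), freq="D")
        by_occ: dict[int, list] = {}
        for d in days:
            j = (d - SURVEY_START).days // scenario.occasion_length_days + 1
            if 1 <= j <= n_occ:
                by_occ.setdefault(j, []).append(d)
        op_days[row["camera_id"]] = by_occ

    rows = []
    for s, tr in enumerate(truth.species):
        g0, g1, g2, g3 = tr.gamma
        logit_p = g0 + g1 * wstd + g2 * dw[:, None] + g3 * ct[:, None]
        p = expit(logit_p)
        detect = surveyed & (truth.z[s][:, None] == 1) & (rng.random(p.shape) < p)
        for i, sid in enumerate(site_ids):
            for j in np.nonzero(detect[i])[0] + 1:
                days = op_days[sid].get(int(j))
                if not days:
                    continue
                n_bursts = 1 + rng.poisson(tr.event_rate - 1.0)
                for _ in range(n_bursts):
                    day = days[rng.integers(len(days))]
                    minute = int(rng.integers(5 * 60, 21 * 60))
                    t0 = day + pd.Timedelta(minutes=minute)
                    for k in range(int(rng.integers(1, 4))):
                        rows.append((sid, tr.species_id, t0 + pd.Timedelta(minutes=2 * k)))

    # human / livestock pseudo-species from the latent disturbance intensity
    lam = cov.raw["disturb"].to_numpy()
    for i, sid in enumerate(site_ids):
        all_days = [d for ds in op_days[sid].values() for d in ds]
        if not all_days:
            continue
        for pseudo in DISTURBANCE_SPECIES:
            n_ev = rng.poisson(lam[i] / 100.0 * len(all_days) / len(DISTURBANCE_SPECIES))
            for _ in range(int(n_ev)):
                day = all_days[rng.integers(len(all_days))]
                minute = int(rng.integers(6 * 60, 20 * 60))
                rows.append((sid, pseudo, day + pd.Timedelta(minutes=minute)))

    records = pd.DataFrame(rows, columns=["camera_id", "species", "timestamp"])
    records = records.sort_values(
        ["timestamp", "camera_id", "species"], kind="mergesort"
    ).reset_index(drop=True)
    return records, deployments


def generate_survey(scenario: SurveyScenario):
    """Full synthetic survey: covariates, truth, records, deployments."""
    cov = generate_covariates(scenario)
    truth = generate_truth(scenario, cov)
    records, deployments = generate_records(scenario, truth, cov)
    return cov, truth, records, deployments


def write_survey(outdir, scenario: SurveyScenario, cov, truth, records, deployments) -> dict:
    """Write records/deployments/covariates CSV and truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": outdir / "records.csv",
        "deployments": outdir / "deployments.csv",
        "covariates": outdir / "covariates.csv",
        "truth": outdir / "truth.json",
    }
    rec = records.copy()
    rec["timestamp"] = rec["timestamp"].dt.strftime("%Y-%m-%dT%H:%M")
    rec.to_csv(paths["records"], index=False)
    dep = deployments.copy()
    dep["start"] = dep["start"].dt.strftime("%Y-%m-%dT%H:%M")
    dep["end"] = dep["end"].dt.strftime("%Y-%m-%dT%H:%M")
    dep.to_csv(paths["deployments"], index=False)
    cov.to_csv(paths["covariates"])
    blob = {
        "scenario": {
            k: v for k, v in asdict(scenario).items() if k != "covariate_correlations"
        },
        "predictors": PREDICTORS,
        "species": [asdict(t) for t in truth.species],
        "psi": truth.psi.tolist(),
        "z": truth.z.tolist(),
        "site_ids": truth.site_ids,
    }
    paths["truth"].write_text(json.dumps(blob, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
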