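"""End-to-end orchestration of the community-structure analysis.

Stages run in dependency order — simulate (optional), events, covariates,
beta, structure, ordination, occupancy, responses, concordance — with every
stage writing its outputs to disk before dependents run, so any stage can be
re-run from the upstream artifacts. One global seed is expanded into
per-stage seeds by a fixed hash derivation; identical config + seed yields a
byte-identical report body.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beta import pairwise_partition, swap_null
from .concordance import mantel_triplet
from .covariates import OCCUPANCY_PREDICTORS, SiteCovariateTable, standardize, vif_screen
from .events import (
    DetectionHistory,
    EventTable,
    apply_species_filter,
    build_detection_history,
    compute_rai,
    filter_independent_events,
    presence_absence,
    read_deployments,
    read_records,
)
from .occupancy import OccupancyModelSpec, classify_elevation_response, fit_all_species
from .ordination import envfit_table, nmds
from .responses import cluster_responses, shrink
from .structure import DistanceMatrix, cluster_and_silhouette, delta_test, species_distances
from .synth import DISTURBANCE_SPECIES, SurveyScenario, generate_survey, write_survey

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "STAGES"]

log = logging.getLogger("trapcomm")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All analysis constants in one place.

    Defaults follow the study design: 30-min independence window, 14-day
    occasions, the <30 events / <10 sites species filter, VIF threshold 5,
    k = 2-16 cluster screening, 9999 permutations, 90% credible intervals
    and 0.9 direction-probability threshold.
    """

    # inputs: either a synthetic scenario or paths to the three CSVs
    scenario: dict | None = field(default_factory=dict)
    records_path: str | None = None
    deployments_path: str | None = None
    covariates_path: str | None = None
    # events
    merge_window_minutes: float = 30.0
    occasion_length_days: int = 14
    min_events: int = 30
    min_sites: int = 10
    # covariates
    vif_threshold: float = 5.0
    # permutation analyses
    n_permutations: int = 9999
    n_swap_randomizations: int | None = None  # defaults to n_permutations
    k_range: tuple = (2, 16)
    structure_linkage: str = "average"
    response_linkage: str = "ward"
    envfit_weighting: str = "rai"  # or "occurrence"
    nmds_starts: int = 20
    # occupancy
    prior_scale: float = 2.5
    chains: int = 2
    iterations: int = 1200
    warmup: int = 1000
    thin: int = 16
    cri_level: float = 0.90
    direction_threshold: float = 0.9
    # seeding
    seed: int = 0

    def __post_init__(self):
        for name in ("merge_window_minutes", "occasion_length_days", "min_events",
                     "min_sites", "vif_threshold", "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def swap_randomizations(self) -> int:
        return self.n_swap_randomizations or self.n_permutations

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "k_range" in data:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["k_range"] = list(d["k_range"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def hash(self) -> str:
        d = self.to_dict()
        d["k_range"] = list(d["k_range"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % 2**31

    def ks(self, n: int) -> range:
        return range(self.k_range[0], min(self.k_range[1], n - 1) + 1)


def _json_dump(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: PipelineConfig, wd: Path) -> dict:
    sc = dict(cfg.scenario or {})
    sc.setdefault("seed", cfg.stage_seed("simulate"))
    sc.setdefault("occasion_length_days", cfg.occasion_length_days)
    scenario = SurveyScenario(**sc)
    cov, truth, records, deployments = generate_survey(scenario)
    paths = write_survey(wd / "survey", scenario, cov, truth, records, deployments)
    return {
        "n_sites": scenario.n_sites,
        "n_species": scenario.n_species,
        "n_records": int(len(records)),
        "paths": {k: str(Path(v).relative_to(wd)) for k, v in paths.items()},
    }


def _input_paths(cfg: PipelineConfig, wd: Path) -> dict:
    if cfg.records_path:
        return {
            "records": cfg.records_path,
            "deployments": cfg.deployments_path,
            "covariates": cfg.covariates_path,
        }
    return {
        "records": wd / "survey" / "records.csv",
        "deployments": wd / "survey" / "deployments.csv",
        "covariates": wd / "survey" / "covariates.csv",
    }


def stage_events(cfg: PipelineConfig, wd: Path) -> dict:
    paths = _input_paths(cfg, wd)
    records = read_records(paths["records"])
    deployments = read_deployments(paths["deployments"])
    out = wd / "events"
    out.mkdir(parents=True, exist_ok=True)
    ev = filter_independent_events(records, deployments, cfg.merge_window_minutes)
    rai = compute_rai(ev)
    animal = ev.events[~ev.events["species"].isin(DISTURBANCE_SPECIES)]
    retained = apply_species_filter(
        EventTable(animal, ev.effective_days, deployments),
        min_events=cfg.min_events,
        min_sites=cfg.min_sites,
    )
    disturb = (
        rai.rai[[s for s in DISTURBANCE_SPECIES if s in rai.rai.columns]].sum(axis=1)
        if any(s in rai.rai.columns for s in DISTURBANCE_SPECIES)
        else pd.Series(0.0, index=rai.rai.index)
    )
    history = build_detection_history(
        ev, deployments, occasion_length_days=cfg.occasion_length_days, species=retained
    )
    ev.events.to_csv(out / "events.csv", index=False)
    rai.rai.to_csv(out / "rai.csv", index_label="site_id")
    rai.effective_days.to_csv(out / "effective_days.csv", index_label="site_id")
    disturb.rename("disturb").to_csv(out / "disturbance.csv", index_label="site_id")
    history.workday.to_csv(out / "workday.csv", index_label="site_id")
    for s in retained:
        history.histories[s].to_csv(out / f"history_{s}.csv", index_label="site_id")
    summary = {
        "n_cameras": int(len(rai.effective_days)),
        "effective_days_total": int(rai.effective_days.sum()),
        "n_records": int(len(records)),
        "n_events": int(ev.n_events),
        "retained_species": retained,
        "per_species_events": {
            k: int(v) for k, v in ev.counts().sum(axis=0).items()
        },
        "survey_start": str(history.survey_start.date()),
        "n_occasions": int(history.n_occasions),
    }
    _json_dump(out / "summary.json", summary)
    return summary


def stage_covariates(cfg: PipelineConfig, wd: Path) -> dict:
    paths = _input_paths(cfg, wd)
    raw = pd.read_csv(paths["covariates"], index_col="site_id")
    disturb = pd.read_csv(wd / "events" / "disturbance.csv", index_col="site_id")["disturb"]
    # the analysis-side disturbance covariate is the measured human/livestock RAI
    raw["disturb"] = disturb.reindex(raw.index).fillna(0.0)
    if raw["disturb"].nunique() == 1:
        std = standardize(raw, columns=[c for c in raw.columns if c != "disturb"])
        std["disturb"] = 0.0
    else:
        std = standardize(raw)
    cov = SiteCovariateTable(raw=raw, standardized=std)
    candidates = [
        "ele", "slope", "northness", "twi", "ndvi", "evi", "tri",
        "dist_tree", "dist_shrub", "dist_grass", "dist_crop", "dist_built",
        "dist_bare", "dist_water",
    ]
    if raw["disturb"].nunique() > 1:
        candidates.append("disturb")
    candidates = [c for c in candidates if c in std.columns]
    retained, report = vif_screen(std, candidates, threshold=cfg.vif_threshold)
    out = wd / "covariates"
    out.mkdir(parents=True, exist_ok=True)
    raw.to_csv(out / "raw.csv", index_label="site_id")
    std.to_csv(out / "standardized.csv", index_label="site_id")
    _json_dump(
        out / "vif_report.json",
        {
            "threshold": cfg.vif_threshold,
            "rounds": [
                {"vif": {k: (v if np.isfinite(v) else "inf") for k, v in r["vif"].items()},
                 "dropped": r["dropped"]}
                for r in report
            ],
            "retained": retained,
            "occupancy_predictors": OCCUPANCY_PREDICTORS,
        },
    )
    return {"vif_retained": retained, "occupancy_predictors": OCCUPANCY_PREDICTORS}


def _load_rai(wd: Path) -> pd.DataFrame:
    return pd.read_csv(wd / "events" / "rai.csv", index_col="site_id")


def _retained(wd: Path) -> list[str]:
    return json.loads((wd / "events" / "summary.json").read_text())["retained_species"]


def stage_beta(cfg: PipelineConfig, wd: Path) -> dict:
    rai = _load_rai(wd)
    retained = _retained(wd)
    pa = (rai[retained] > 0).astype(int)
    pa = pa.loc[pa.sum(axis=1) > 0]
    part = pairwise_partition(pa)
    null = swap_null(
        pa,
        n_randomizations=cfg.swap_randomizations,
        seed=cfg.stage_seed("beta"),
    )
    out = wd / "beta"
    out.mkdir(parents=True, exist_ok=True)
    pa.to_csv(out / "presence_absence.csv", index_label="site_id")
    part.to_frame().to_csv(out / "partition.csv", index=False)
    _json_dump(out / "null_model.json", null.to_dict())
    summary = {**part.summary, "null_model": null.to_dict(), "n_sites": int(pa.shape[0])}
    _json_dump(out / "summary.json", summary)
    return summary


def stage_structure(cfg: PipelineConfig, wd: Path) -> dict:
    rai = _load_rai(wd)[_retained(wd)]
    pa = (rai > 0).astype(int)
    jac, bc = species_distances(pa, rai)
    out = wd / "structure"
    out.mkdir(parents=True, exist_ok=True)
    jac.to_frame().to_csv(out / "jaccard.csv", index_label="species")
    bc.to_frame().to_csv(out / "braycurtis.csv", index_label="species")
    report = {}
    seed0 = cfg.stage_seed("structure")
    for name, dm in (("jaccard", jac), ("braycurtis", bc)):
        sols = cluster_and_silhouette(dm, k_range=cfg.ks(dm.n), method=cfg.structure_linkage)
        rows = []
        for i, sol in enumerate(sols):
            dt = delta_test(
                dm, sol.labels, n_permutations=cfg.n_permutations, seed=seed0 + i
            )
            rows.append(
                {"k": sol.k, "mean_silhouette": sol.mean_silhouette,
                 "delta": dt.delta_observed, "delta_p": dt.p_value}
            )
        tab = pd.DataFrame(rows)
        tab.to_csv(out / f"screening_{name}.csv", index=False)
        best = tab.loc[tab["mean_silhouette"].idxmax()]
        report[name] = {
            "best_k": int(best["k"]),
            "best_silhouette": float(best["mean_silhouette"]),
            "delta_p_at_best_k": float(best["delta_p"]),
            "max_delta": float(tab["delta"].max()),
        }
        seed0 += 1000
    _json_dump(out / "summary.json", report)
    return report


def _species_env_values(cfg: PipelineConfig, wd: Path, species) -> pd.DataFrame:
    """Per-species environmental values: weighted mean of site covariates.

    Weights are the species' RAI across sites (default) or its occurrence
    indicator; ordination points are species, so envfit needs one value per
    species and variable.
    """
    rai = _load_rai(wd)[list(species)]
    std = pd.read_csv(wd / "covariates" / "standardized.csv", index_col="site_id")
    w = rai if cfg.envfit_weighting == "rai" else (rai > 0).astype(float)
    w = w.reindex(std.index).fillna(0.0)
    vals = (w.T @ std) / w.sum(axis=0).to_numpy()[:, None]
    return vals


def stage_ordination(cfg: PipelineConfig, wd: Path) -> dict:
    out = wd / "ordination"
    out.mkdir(parents=True, exist_ok=True)
    report = {}
    seed0 = cfg.stage_seed("ordination")
    for i, name in enumerate(("jaccard", "braycurtis")):
        dm = DistanceMatrix.from_frame(
            pd.read_csv(wd / "structure" / f"{name}.csv", index_col="species")
        )
        ordn = nmds(dm, n_dims=2, n_starts=cfg.nmds_starts, seed=seed0 + i)
        env = _species_env_values(cfg, wd, dm.labels)
        fit = envfit_table(
            ordn.scores, env, n_permutations=cfg.n_permutations, seed=seed0 + 100 + i
        )
        ordn.to_frame().to_csv(out / f"scores_{name}.csv", index_label="species")
        fit.to_csv(out / f"envfit_{name}.csv")
        report[name] = {
            "stress": ordn.stress,
            "converged": bool(ordn.converged),
            "envfit_top": fit["r2"].idxmax(),
            "envfit_r2_ele": float(fit.loc["ele", "r2"]) if "ele" in fit.index else None,
        }
    _json_dump(out / "summary.json", report)
    return report


def stage_occupancy(cfg: PipelineConfig, wd: Path) -> dict:
    retained = _retained(wd)
    std = pd.read_csv(wd / "covariates" / "standardized.csv", index_col="site_id")
    raw = pd.read_csv(wd / "covariates" / "raw.csv", index_col="site_id")
    cov = SiteCovariateTable(raw=raw, standardized=std)
    wdmat = pd.read_csv(wd / "events" / "workday.csv", index_col="site_id")
    wdmat.columns = wdmat.columns.astype(int)
    histories = {
        s: pd.read_csv(wd / "events" / f"history_{s}.csv", index_col="site_id").set_axis(
            wdmat.columns, axis=1
        )
        for s in retained
    }
    summary_json = json.loads((wd / "events" / "summary.json").read_text())
    history = DetectionHistory(
        histories=histories,
        workday=wdmat,
        survey_start=pd.Timestamp(summary_json["survey_start"]),
        occasion_length_days=cfg.occasion_length_days,
    )
    deployments = read_deployments(_input_paths(cfg, wd)["deployments"])
    ctypes = deployments.drop_duplicates("camera_id").set_index("camera_id")["camera_type"]
    spec = OccupancyModelSpec(
        prior_scale=cfg.prior_scale,
        chains=cfg.chains,
        iterations=cfg.iterations,
        warmup=cfg.warmup,
        thin=cfg.thin,
        cri_level=cfg.cri_level,
        direction_threshold=cfg.direction_threshold,
        seed=cfg.stage_seed("occupancy"),
    )
    fits = fit_all_species(spec, history, cov, ctypes)
    out = wd / "occupancy"
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for s, f in fits.items():
        df = f.summary.reset_index()
        df.insert(0, "species", s)
        frames.append(df)
    full = pd.concat(frames, ignore_index=True)
    full.to_csv(out / "summary.csv", index=False)
    beta_names = [f"beta_{p}" for p in spec.occ_predictors]
    beta_mean = pd.DataFrame(
        {s: fits[s].summary.loc[beta_names, "mean"] for s in retained}
    ).T.set_axis(list(spec.occ_predictors), axis=1)
    beta_var = pd.DataFrame(
        {s: fits[s].summary.loc[beta_names, "sd"] ** 2 for s in retained}
    ).T.set_axis(list(spec.occ_predictors), axis=1)
    beta_mean.to_csv(out / "beta_mean.csv", index_label="species")
    beta_var.to_csv(out / "beta_var.csv", index_label="species")
    sig = pd.DataFrame(
        {
            s: np.where(
                fits[s].summary.loc[beta_names, "significant"],
                np.where(fits[s].summary.loc[beta_names, "mean"] > 0, "+", "-"),
                "0",
            )
            for s in retained
        }
    ).T.set_axis(list(spec.occ_predictors), axis=1)
    sig.to_csv(out / "significance_heatmap.csv", index_label="species")
    direction = pd.DataFrame(
        {s: fits[s].summary.loc[beta_names, "direction"] for s in retained}
    ).T.set_axis(list(spec.occ_predictors), axis=1)
    direction.to_csv(out / "direction_heatmap.csv", index_label="species")
    elev = {s: classify_elevation_response(fits[s]) for s in retained}
    _json_dump(out / "elevation_response.json", elev)
    report = {
        "n_species_fit": len(fits),
        "max_rhat": float(full["rhat"].max()),
        "all_converged": bool(all(f.converged for f in fits.values())),
        "n_species_with_significant_effect": int(
            (full.loc[full["parameter"].str.startswith("beta_"), :]
             .groupby("species")["significant"].any()).sum()
        ),
        "elevation_response": elev,
    }
    _json_dump(out / "summary.json", report)
    return report


def stage_responses(cfg: PipelineConfig, wd: Path) -> dict:
    beta_mean = pd.read_csv(wd / "occupancy" / "beta_mean.csv", index_col="species")
    beta_var = pd.read_csv(wd / "occupancy" / "beta_var.csv", index_col="species")
    shrunk = shrink(beta_mean, beta_var)
    best, pv, sols, dm = cluster_responses(
        shrunk,
        k_range=cfg.ks(len(shrunk)),
        n_permutations=cfg.n_permutations,
        seed=cfg.stage_seed("responses"),
        method=cfg.response_linkage,
    )
    out = wd / "responses"
    out.mkdir(parents=True, exist_ok=True)
    shrunk.to_csv(out / "shrunk_coefficients.csv", index_label="species")
    dm.to_frame().to_csv(out / "beta_distance.csv", index_label="species")
    pd.DataFrame(
        {"k": [s.k for s in sols], "mean_silhouette": [s.mean_silhouette for s in sols]}
    ).to_csv(out / "silhouettes.csv", index=False)
    pd.DataFrame(
        {"species": shrunk.index, "cluster": best.labels}
    ).to_csv(out / "clusters.csv", index=False)
    _json_dump(out / "permanova.json", pv.to_dict())
    report = {
        "selected_k": best.k,
        "mean_silhouette": best.mean_silhouette,
        "permanova": pv.to_dict(),
        "cluster_sizes": np.bincount(best.labels)[1:].tolist(),
    }
    _json_dump(out / "summary.json", report)
    return report


def stage_concordance(cfg: PipelineConfig, wd: Path) -> dict:
    jac = DistanceMatrix.from_frame(
        pd.read_csv(wd / "structure" / "jaccard.csv", index_col="species")
    )
    bc = DistanceMatrix.from_frame(
        pd.read_csv(wd / "structure" / "braycurtis.csv", index_col="species")
    )
    beta_dm = DistanceMatrix.from_frame(
        pd.read_csv(wd / "responses" / "beta_distance.csv", index_col="species")
    )
    order = jac.labels
    beta_df = beta_dm.to_frame().loc[order, order]
    beta_dm = DistanceMatrix.from_frame(beta_df)
    res = mantel_triplet(
        jac, bc, beta_dm, n_permutations=cfg.n_permutations,
        seed=cfg.stage_seed("concordance"),
    )
    out = wd / "concordance"
    out.mkdir(parents=True, exist_ok=True)
    report = {k: v.to_dict() for k, v in res.items()}
    _json_dump(out / "mantel.json", report)
    return report


STAGES = {
    "simulate": stage_simulate,
    "events": stage_events,
    "covariates": stage_covariates,
    "beta": stage_beta,
    "structure": stage_structure,
    "ordinate": stage_ordination,
    "occupancy": stage_occupancy,
    "responses": stage_responses,
    "mantel": stage_concordance,
}


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage in order and assemble the analysis report.

    The ``simulate`` stage is skipped when the config points at external
    records/deployments/covariates files.
    """
    wd = Path(outdir)
    wd.mkdir(parents=True, exist_ok=True)
    report = {
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s) for s in STAGES},
        "version": __version__,
        "stages": {},
    }
    for name, fn in STAGES.items():
        if name == "simulate" and cfg.records_path:
            continue
        t0 = time.monotonic()
        log.info("stage %s ...", name)
        try:
            report["stages"][name] = fn(cfg, wd)
        except Exception as e:  # noqa: BLE001 - abort with stage context
            raise PipelineStageError(name, e) from e
        log.info("stage %s done in %.1fs", name, time.monotonic() - t0)
    _json_dump(wd / "report.json", report)
    return report
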