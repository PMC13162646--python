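"""From raw timestamped detections to independent events, RAI, and
detection histories.

Consecutive records of the same species at the same camera within the merge
window (default 30 min, boundary inclusive: a gap of exactly 30 min still
merges) are collapsed into one independent event, with the gap measured to
the *previous record* of the stream. The relative abundance index (RAI) is
independent events per 100 effective camera-trap days, where an effective
day is any calendar day with operational coverage. Detection histories use
consecutive occasions (default 14 days) aligned to a single global survey
start so that occasion j means the same calendar block at every site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Deployment",
    "EventTable",
    "RAIMatrix",
    "DetectionHistory",
    "read_records",
    "read_deployments",
    "effective_days",
    "filter_independent_events",
    "compute_rai",
    "apply_species_filter",
    "workday_matrix",
    "build_detection_history",
    "presence_absence",
]


@dataclass(frozen=True)
class Deployment:
    camera_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    camera_type: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"deployment for {self.camera_id}: start >= end")


def read_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    need = {"camera_id", "species", "timestamp"}
    if not need.issubset(df.columns):
        raise ValueError(f"records CSV must have columns {sorted(need)}")
    return df


def read_deployments(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["start", "end"])
    need = {"camera_id", "start", "end", "camera_type"}
    if not need.issubset(df.columns):
        raise ValueError(f"deployments CSV must have columns {sorted(need)}")
    _check_deployments(df)
    return df


def _check_deployments(deployments: pd.DataFrame) -> None:
    for cam, grp in deployments.groupby("camera_id"):
        if (grp["start"] >= grp["end"]).any():
            raise ValueError(f"deployment for {cam}: start >= end")
        g = grp.sort_values("start")
        if (g["start"].iloc[1:].to_numpy() < g["end"].iloc[:-1].to_numpy()).any():
            raise ValueError(f"overlapping deployments for camera {cam}")


def effective_days(deployments: pd.DataFrame) -> pd.Series:
    """Calendar days with any operational coverage, per camera.

    Partial days count as one full effective day.
    """
    out = {}
    for cam, grp in deployments.groupby("camera_id"):
        days = set()
        for _, row in grp.iterrows():
            d = pd.date_range(row["start"].normalize(), row["end"].normalize(), freq="D")
            days.update(d.date)
        out[cam] = len(days)
    return pd.Series(out, name="effective_days").sort_index()


@dataclass
class EventTable:
    """Independent detection events plus per-camera effort."""

    events: pd.DataFrame  # columns: camera_id, species, timestamp
    effective_days: pd.Series  # indexed by camera_id
    deployments: pd.DataFrame = None  # type: ignore[assignment]

    @property
    def n_events(self) -> int:
        return len(self.events)

    def counts(self) -> pd.DataFrame:
        """Event counts per (camera, species), cameras x species."""
        tab = self.events.groupby(["camera_id", "species"]).size().unstack(fill_value=0)
        return tab.reindex(self.effective_days.index, fill_value=0)


def filter_independent_events(
    records: pd.DataFrame,
    deployments: pd.DataFrame | None = None,
    merge_window_minutes: float = 30.0,
    outside_deployment: str = "keep",
) -> EventTable:
    """Collapse bursts into independent events with the gap-to-previous rule.

    A record opens a new event iff its gap to the previous record of the same
    (camera, species) stream strictly exceeds ``merge_window_minutes``; the
    first record of a stream is always an event. Records falling outside all
    deployment intervals of their camera trigger a warning and are kept or
    dropped per ``outside_deployment`` ("keep" | "drop").
    """
    if outside_deployment not in ("keep", "drop"):
        raise ValueError("outside_deployment must be 'keep' or 'drop'")
    rec = records.copy()
    rec["timestamp"] = pd.to_datetime(rec["timestamp"])
    if deployments is not None and len(rec):
        _check_deployments(deployments)
        ok = np.zeros(len(rec), dtype=bool)
        for cam, grp in deployments.groupby("camera_id"):
            m = (rec["camera_id"] == cam).to_numpy()
            if not m.any():
                continue
            t = rec.loc[m, "timestamp"]
            inside = np.zeros(m.sum(), dtype=bool)
            for _, row in grp.iterrows():
                inside |= ((t >= row["start"]) & (t <= row["end"])).to_numpy()
            ok[m] = inside
        n_out = int((~ok).sum())
        if n_out:
            warnings.warn(
                f"{n_out} record(s) outside all deployments ({outside_deployment})",
                stacklevel=2,
            )
            if outside_deployment == "drop":
                rec = rec.loc[ok]
    rec = rec.sort_values(["camera_id", "species", "timestamp"], kind="mergesort")
    gap = rec.groupby(["camera_id", "species"])["timestamp"].diff()
    new_event = gap.isna() | (gap > pd.Timedelta(minutes=merge_window_minutes))
    ev = rec.loc[new_event, ["camera_id", "species", "timestamp"]].reset_index(drop=True)
    eff = (
        effective_days(deployments)
        if deployments is not None
        else pd.Series(dtype=int, name="effective_days")
    )
    return EventTable(events=ev, effective_days=eff, deployments=deployments)


@dataclass
class RAIMatrix:
    """Relative abundance index: events per 100 effective days."""

    rai: pd.DataFrame  # sites x species
    effective_days: pd.Series

    def __post_init__(self):
        if (self.rai.to_numpy() < 0).any():
            raise ValueError("RAI entries must be non-negative")


def compute_rai(events: EventTable) -> RAIMatrix:
    """RAI = 100 * n_events / effective_days per (site, species).

    Cameras with zero effective days are excluded with a warning.
    """
    eff = events.effective_days
    zero = eff[eff <= 0].index.tolist()
    if zero:
        warnings.warn(f"excluding zero-effort cameras: {zero}", stacklevel=2)
        eff = eff[eff > 0]
    counts = events.counts().reindex(eff.index, fill_value=0)
    rai = counts.div(eff, axis=0) * 100.0
    return RAIMatrix(rai=rai, effective_days=eff)


def apply_species_filter(
    events: EventTable, min_events: int = 30, min_sites: int = 10
) -> list[str]:
    """Species retained for analysis: at least ``min_events`` independent
    events AND detected at at least ``min_sites`` cameras ("fewer than" is
    strict, so the boundary values are retained)."""
    counts = events.counts()
    total = counts.sum(axis=0)
    n_sites = (counts > 0).sum(axis=0)
    keep = (total >= min_events) & (n_sites >= min_sites)
    return [s for s in counts.columns if keep[s]]


def workday_matrix(
    deployments: pd.DataFrame,
    survey_start: pd.Timestamp,
    n_occasions: int,
    occasion_length_days: int = 14,
    site_ids=None,
) -> pd.DataFrame:
    """Operational calendar days per site x occasion (0..occasion length)."""
    survey_start = pd.Timestamp(survey_start).normalize()
    sites = list(site_ids) if site_ids is not None else sorted(deployments["camera_id"].unique())
    wd = pd.DataFrame(0, index=pd.Index(sites, name="site_id"), columns=range(1, n_occasions + 1))
    occ_starts = [survey_start + pd.Timedelta(days=occasion_length_days * j) for j in range(n_occasions)]
    for cam, grp in deployments.groupby("camera_id"):
        if cam not in wd.index:
            continue
        days = set()
        for _, row in grp.iterrows():
            d = pd.date_range(row["start"].normalize(), row["end"].normalize(), freq="D")
            days.update(d)
        for j, os in enumerate(occ_starts, start=1):
            oe = os + pd.Timedelta(days=occasion_length_days)
            wd.loc[cam, j] = sum(1 for d in days if os <= d < oe)
    return wd


@dataclass
class DetectionHistory:
    """Occasion-structured detection data for the occupancy model.

    ``histories[s]`` is a sites x occasions matrix: 1 detected, 0 surveyed
    without detection, NaN no effort. ``workday`` holds operational days per
    site x occasion; a cell is NaN in the history exactly where workday is 0.
    """

    histories: dict[str, pd.DataFrame]
    workday: pd.DataFrame
    survey_start: pd.Timestamp
    occasion_length_days: int = 14

    @property
    def species(self) -> list[str]:
        return list(self.histories)

    @property
    def n_occasions(self) -> int:
        return self.workday.shape[1]


def build_detection_history(
    events: EventTable,
    deployments: pd.DataFrame,
    occasion_length_days: int = 14,
    survey_start=None,
    survey_end=None,
    species=None,
) -> DetectionHistory:
    """Binary site x occasion histories over consecutive calendar occasions.

    Occasions are ``occasion_length_days`` blocks counted from a single
    global ``survey_start`` (default: earliest deployment start), shared by
    every site. An event in an occasion the workday matrix says had no effort
    raises a consistency error.
    """
    if survey_start is None:
        survey_start = deployments["start"].min()
    survey_start = pd.Timestamp(survey_start).normalize()
    if survey_end is None:
        survey_end = deployments["end"].max()
    total_days = (pd.Timestamp(survey_end).normalize() - survey_start).days + 1
    n_occ = int(np.ceil(total_days / occasion_length_days))
    sites = sorted(deployments["camera_id"].unique())
    wd = workday_matrix(deployments, survey_start, n_occ, occasion_length_days, site_ids=sites)
    ev = events.events
    if species is None:
        species = sorted(ev["species"].unique())
    histories: dict[str, pd.DataFrame] = {}
    occ_of = ((pd.to_datetime(ev["timestamp"]).dt.normalize() - survey_start).dt.days
              // occasion_length_days + 1)
    for s in species:
        h = pd.DataFrame(
            np.where(wd.to_numpy() > 0, 0.0, np.nan), index=wd.index, columns=wd.columns
        )
        sel = ev["species"] == s
        for cam, occ in zip(ev.loc[sel, "camera_id"], occ_of[sel]):
            if occ < 1 or occ > n_occ:
                raise ValueError(f"event for {s} at {cam} outside the survey window")
            if wd.loc[cam, occ] == 0:
                raise ValueError(
                    f"event for {s} at {cam} in occasion {occ} with zero recorded effort"
                )
            h.loc[cam, occ] = 1.0
        histories[s] = h
    return DetectionHistory(
        histories=histories,
        workday=wd,
        survey_start=survey_start,
        occasion_length_days=occasion_length_days,
    )


def presence_absence(rai: RAIMatrix, species=None) -> pd.DataFrame:
    """Sites x species binary occurrence matrix from the RAI matrix."""
    m = rai.rai if species is None else rai.rai[list(species)]
    return (m > 0).astype(int)
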