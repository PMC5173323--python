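"""Per-track and per-cohort motility statistics.

The four statistics used throughout intravital T-cell imaging studies:

* mean velocity — total path length divided by elapsed duration (µm/min);
  at uniform sampling this equals the arithmetic mean of the instantaneous
  speeds, an identity the test suite asserts;
* arrest coefficient — percentage of a track's time spent in steps whose
  instantaneous speed is strictly below the arrest threshold (default
  2 µm/min); each step's time weight is its own Δt, which handles irregular
  sampling;
* confinement ratio — maximum displacement from the track's first position
  divided by path length, in (0, 1] for any moving cell (undefined, not 0,
  for a cell that never moved);
* immotile flag — mean velocity strictly below 2 µm/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, InsufficientDataError, TrackValidationError
from .tracks import Track, TrackSet

#: Speed threshold (µm/min) below which a step counts as arrested and a
#: cell's mean velocity marks it immotile.
DEFAULT_SPEED_THRESHOLD = 2.0

#: Per-track metric columns summarised at cohort level.
SUMMARY_METRICS = (
    "mean_velocity_um_min",
    "confinement_ratio",
    "arrest_coefficient_pct",
    "path_length_um",
    "max_displacement_um",
)


@dataclass(frozen=True)
class TrackMetrics:
    """Motility statistics bundle for a single cell."""

    track_id: str
    duration_min: float
    n_points: int
    path_length_um: float
    max_displacement_um: float
    mean_velocity_um_min: float
    confinement_ratio: float  # NaN when path length is zero (undefined)
    arrest_coefficient_pct: float
    immotile: bool


def instantaneous_velocities(track: Track) -> np.ndarray:
    """Speeds (µm/min) of each inter-frame step, length ``n_points - 1``."""
    if track.n_points < 2:
        raise InsufficientDataError(
            f"track {track.track_id!r}: need >= 2 points for velocities"
        )
    disp = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    dt = np.diff(track.times)
    return disp / dt


def track_metrics(
    track: Track,
    arrest_threshold: float = DEFAULT_SPEED_THRESHOLD,
    immotile_threshold: float = DEFAULT_SPEED_THRESHOLD,
) -> TrackMetrics:
    """Compute the full per-track statistics bundle.

    Arrest uses a strict ``<`` comparison at the threshold; the immotile flag
    likewise.  A track whose cell never moved has an undefined (NaN)
    confinement ratio rather than zero, so cohort summaries are not biased
    by 0/0 artefacts.
    """
    if track.n_points < 2:
        raise InsufficientDataError(
            f"track {track.track_id!r}: need >= 2 points for metrics"
        )
    duration = track.duration
    if duration <= 0:
        raise TrackValidationError(
            f"track {track.track_id!r}: zero duration with multiple points"
        )
    step_disp = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    dt = np.diff(track.times)
    speeds = step_disp / dt
    path_length = float(step_disp.sum())
    max_disp = float(
        np.linalg.norm(track.positions - track.positions[0], axis=1).max()
    )
    mean_velocity = path_length / duration
    arrest = 100.0 * float(dt[speeds < arrest_threshold].sum()) / duration
    confinement = max_disp / path_length if path_length > 0 else math.nan
    return TrackMetrics(
        track_id=track.track_id,
        duration_min=duration,
        n_points=track.n_points,
        path_length_um=path_length,
        max_displacement_um=max_disp,
        mean_velocity_um_min=mean_velocity,
        confinement_ratio=confinement,
        arrest_coefficient_pct=arrest,
        immotile=mean_velocity < immotile_threshold,
    )


def _moments(values: np.ndarray) -> tuple[float, float, float, int]:
    """(mean, sd, sem, n); a single observation reports sd = sem = 0."""
    n = len(values)
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if n > 1 else 0.0
    sem = sd / math.sqrt(n)
    return mean, sd, sem, n


@dataclass(frozen=True)
class CohortMetrics:
    """Per-track metric table plus cell-level cohort summary.

    ``per_track`` has one row per retained track (each data point is one
    cell) with its labels appended; ``summary`` is indexed by metric name
    with columns mean/sd/sem/n.  Tracks with fewer than two points are
    excluded and counted in ``n_excluded_short``; tracks with undefined
    confinement ratio are excluded from that metric's summary only and
    counted in ``n_confinement_undefined``.
    """

    per_track: pd.DataFrame
    summary: pd.DataFrame
    n_excluded_short: int
    n_confinement_undefined: int


def summarize_metric_table(per_track: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary (mean, sd, sem, n) of each metric column, NaNs dropped."""
    rows = {}
    for metric in SUMMARY_METRICS:
        vals = per_track[metric].dropna().to_numpy(dtype=float)
        if len(vals) == 0:
            rows[metric] = {"mean": math.nan, "sd": math.nan, "sem": math.nan, "n": 0}
        else:
            mean, sd, sem, n = _moments(vals)
            rows[metric] = {"mean": mean, "sd": sd, "sem": sem, "n": n}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "metric"
    out["n"] = out["n"].astype(int)
    return out


def cohort_metrics(
    trackset: TrackSet,
    arrest_threshold: float = DEFAULT_SPEED_THRESHOLD,
    immotile_threshold: float = DEFAULT_SPEED_THRESHOLD,
    project_2d: bool = True,
) -> CohortMetrics:
    """Per-track metrics and cell-level summary for a cohort.

    ``project_2d`` (default on) drops the z coordinate of 3-D tracks before
    metric computation, matching the planar convention of displayed
    intravital analyses; pass ``False`` to use full 3-D path lengths.
    """
    ts = trackset.project_2d() if project_2d else trackset
    retained: list[TrackMetrics] = []
    labels: list[dict] = []
    n_short = 0
    for t in ts:
        if t.n_points < 2:
            n_short += 1
            continue
        retained.append(track_metrics(t, arrest_threshold, immotile_threshold))
        labels.append(dict(t.labels))
    if not retained:
        raise EmptyCohortError("no tracks with >= 2 points in cohort")
    per_track = pd.DataFrame([m.__dict__ for m in retained])
    label_keys = sorted({k for d in labels for k in d})
    for k in label_keys:
        per_track[k] = [d.get(k, "") for d in labels]
    n_undefined = int(per_track["confinement_ratio"].isna().sum())
    return CohortMetrics(
        per_track=per_track,
        summary=summarize_metric_table(per_track),
        n_excluded_short=n_short,
        n_confinement_undefined=n_undefined,
    )


def summarize_by(
    per_track: pd.DataFrame, by: list[str] | tuple[str, ...]
) -> pd.DataFrame:
    """Stratified cohort summaries: one summary block per label combination."""
    missing = [c for c in by if c not in per_track.columns]
    if missing:
        raise KeyError(f"grouping column(s) not in metric table: {missing}")
    blocks = []
    for keys, grp in per_track.groupby(list(by), sort=True):
        block = summarize_metric_table(grp).reset_index()
        if not isinstance(keys, tuple):
            keys = (keys,)
        for col, val in zip(by, keys):
            block.insert(0, col, val)
        blocks.append(block)
    return pd.concat(blocks, ignore_index=True)
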