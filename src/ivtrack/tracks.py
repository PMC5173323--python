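"""Core data model for cell-migration tracks and delimited-table I/O.

A :class:`Track` is one cell's time-ordered positions (µm) with timestamps
(minutes) plus optional string metadata labels (group, day, region,
phenotype).  A :class:`TrackSet` is a cohort of tracks with unique ids and,
when sampling is uniform, a nominal frame interval.

Tables are long-format delimited text, one row per (track, timepoint).  The
canonical dialect uses columns ``track_id, t_min, x_um, y_um[, z_um]``
followed by label columns; an Imaris-style column remapping is bundled and
arbitrary remappings can be supplied.  Coordinates are continuous µm in the
image plane — tracking itself happens upstream, this package never touches
pixels.
"""

from __future__ import annotations

from collections.abc import Callable, Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import FormatError, TrackValidationError

#: Tolerance (minutes) for deciding that consecutive timestamps are on a
#: uniform grid.  Timestamps in exported tables are written values, not
#: measurements, so this is tight.
FRAME_INTERVAL_TOL = 1e-6

_ROLES = ("track_id", "time", "x", "y", "z")


@dataclass(frozen=True)
class Dialect:
    """Column-name mapping for a track-table dialect.

    ``columns`` maps the roles ``track_id``, ``time``, ``x``, ``y`` and
    optionally ``z`` to the column names used in the file; any further
    columns are treated as per-track labels.
    """

    columns: Mapping[str, str]
    delimiter: str = ","

    def __post_init__(self) -> None:
        missing = {"track_id", "time", "x", "y"} - set(self.columns)
        if missing:
            raise FormatError(f"dialect lacks required roles: {sorted(missing)}")


CANONICAL = Dialect(
    {"track_id": "track_id", "time": "t_min", "x": "x_um", "y": "y_um", "z": "z_um"}
)
#: Column names as exported by Imaris "Position" statistics tables.
IMARIS = Dialect(
    {
        "track_id": "TrackID",
        "time": "Time",
        "x": "Position X",
        "y": "Position Y",
        "z": "Position Z",
    }
)


@dataclass(frozen=True)
class Track:
    """One cell's trajectory: strictly increasing times (min), positions (µm)."""

    track_id: str
    times: np.ndarray
    positions: np.ndarray
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if times.ndim != 1 or len(times) < 1:
            raise TrackValidationError(
                f"track {self.track_id!r}: times must be a non-empty 1-D sequence"
            )
        if positions.ndim != 2 or positions.shape[0] != len(times):
            raise TrackValidationError(
                f"track {self.track_id!r}: positions must be (n_points, dim) "
                "with one row per timepoint"
            )
        if positions.shape[1] not in (2, 3):
            raise TrackValidationError(
                f"track {self.track_id!r}: coordinates must be 2-D or 3-D, "
                f"got dim={positions.shape[1]}"
            )
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(positions)):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite time or coordinate"
            )
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: times must be strictly increasing"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "labels", dict(self.labels))

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Elapsed time in minutes between first and last observation."""
        return float(self.times[-1] - self.times[0])

    def project_2d(self) -> "Track":
        """Drop the z coordinate (no-op for planar tracks)."""
        if self.ndim == 2:
            return self
        return Track(self.track_id, self.times, self.positions[:, :2], self.labels)


@dataclass(frozen=True)
class TrackSet:
    """A cohort of tracks with unique ids and one shared dimensionality.

    ``frame_interval`` is the nominal uniform sampling interval in minutes,
    or ``None`` for irregular sampling.
    """

    tracks: tuple[Track, ...]
    frame_interval: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        tracks = tuple(self.tracks)
        ids = [t.track_id for t in tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TrackValidationError(f"duplicate track ids: {dupes}")
        dims = {t.ndim for t in tracks}
        if len(dims) > 1:
            raise TrackValidationError(
                f"mixed track dimensionality in one set: {sorted(dims)}"
            )
        if self.frame_interval is not None:
            if self.frame_interval <= 0:
                raise TrackValidationError("frame_interval must be positive")
            for t in tracks:
                if t.n_points < 2:
                    continue
                dt = np.diff(t.times)
                if np.any(np.abs(dt - self.frame_interval) > FRAME_INTERVAL_TOL):
                    raise TrackValidationError(
                        f"track {t.track_id!r}: sampling deviates from declared "
                        f"frame interval {self.frame_interval} min"
                    )
        object.__setattr__(self, "tracks", tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def get(self, track_id: str) -> Track:
        for t in self.tracks:
            if t.track_id == track_id:
                return t
        raise KeyError(track_id)

    @property
    def ndim(self) -> int | None:
        return self.tracks[0].ndim if self.tracks else None

    def project_2d(self) -> "TrackSet":
        return TrackSet(
            tuple(t.project_2d() for t in self.tracks),
            frame_interval=self.frame_interval,
            provenance=self.provenance,
        )


def infer_frame_interval(tracks: tuple[Track, ...]) -> float | None:
    """Return the common sampling interval if all steps agree within tolerance."""
    diffs: list[np.ndarray] = [np.diff(t.times) for t in tracks if t.n_points >= 2]
    if not diffs:
        return None
    all_dt = np.concatenate(diffs)
    first = all_dt[0]
    if np.all(np.abs(all_dt - first) <= FRAME_INTERVAL_TOL):
        return float(first)
    return None


def read_tracks(path: str | Path, dialect: Dialect = CANONICAL) -> TrackSet:
    """Read a long-format delimited track table into a validated TrackSet.

    Rows are grouped by track id and sorted by time; duplicate (track, time)
    pairs, non-monotone times and mixed 2-D/3-D coordinates are rejected.
    Columns not named in the dialect are treated as per-track labels and must
    be constant within each track.
    """
    path = Path(path)
    # round_trip parsing keeps coordinates bit-exact under write→read
    df = pd.read_csv(path, sep=dialect.delimiter, float_precision="round_trip")
    cols = dialect.columns
    required = [cols[r] for r in ("track_id", "time", "x", "y")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {missing}")

    z_col = cols.get("z")
    has_z = z_col is not None and z_col in df.columns and df[z_col].notna().any()
    if has_z and df[z_col].isna().any():
        raise TrackValidationError(
            f"{path.name}: mixed dimensionality — column {z_col!r} has both "
            "missing and present values"
        )
    coord_cols = [cols["x"], cols["y"]] + ([z_col] if has_z else [])
    known = set(required) | ({z_col} if z_col else set())
    label_cols = [c for c in df.columns if c not in known]

    tracks: list[Track] = []
    for tid, grp in df.groupby(cols["track_id"], sort=False):
        grp = grp.sort_values(cols["time"], kind="stable")
        times = grp[cols["time"]].to_numpy(dtype=float)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise TrackValidationError(
                f"{path.name}: track {tid!r} has duplicate or non-monotone times"
            )
        labels: dict[str, str] = {}
        for c in label_cols:
            vals = grp[c].dropna().unique()
            if len(vals) > 1:
                raise TrackValidationError(
                    f"{path.name}: track {tid!r} label {c!r} is not constant"
                )
            if len(vals) == 1:
                labels[c] = str(vals[0])
        tracks.append(
            Track(
                track_id=str(tid),
                times=times,
                positions=grp[coord_cols].to_numpy(dtype=float),
                labels=labels,
            )
        )
    return TrackSet(
        tuple(tracks),
        frame_interval=infer_frame_interval(tuple(tracks)),
        provenance=f"read from {path.name}",
    )


def write_tracks(
    trackset: TrackSet, path: str | Path, dialect: Dialect = CANONICAL
) -> Path:
    """Write a TrackSet as a long-format delimited table (lossless round trip).

    Column order: track id, time, x, y, [z], then label columns sorted by
    name.  Floats are written with shortest round-trip representation, so
    ``read_tracks(write_tracks(ts)) == ts`` bit-exactly for coordinates.
    """
    path = Path(path)
    cols = dialect.columns
    has_z = any(t.ndim == 3 for t in trackset)
    label_keys = sorted({k for t in trackset for k in t.labels})
    rows: list[dict] = []
    for t in trackset:
        for i in range(t.n_points):
            row: dict = {
                cols["track_id"]: t.track_id,
                cols["time"]: t.times[i],
                cols["x"]: t.positions[i, 0],
                cols["y"]: t.positions[i, 1],
            }
            if has_z:
                row[cols["z"]] = t.positions[i, 2]
            for k in label_keys:
                row[k] = t.labels.get(k, "")
            rows.append(row)
    header = [cols["track_id"], cols["time"], cols["x"], cols["y"]]
    if has_z:
        header.append(cols["z"])
    header += label_keys
    pd.DataFrame(rows, columns=header).to_csv(
        path, sep=dialect.delimiter, index=False
    )
    return path


@dataclass(frozen=True)
class FilterResult:
    trackset: TrackSet
    n_removed: int


def filter_tracks(
    trackset: TrackSet,
    min_points: int = 1,
    label_query: Mapping[str, str] | Callable[[Mapping[str, str]], bool] | None = None,
) -> FilterResult:
    """Return a subset with at least ``min_points`` points matching the query.

    ``label_query`` may be a mapping of required label equalities or a
    predicate over the label dict.  The input set is never mutated; an empty
    result is legal.
    """
    if min_points < 1:
        raise TrackValidationError("min_points must be >= 1")
    if label_query is None:
        pred: Callable[[Mapping[str, str]], bool] = lambda labels: True
    elif callable(label_query):
        pred = label_query
    else:
        wanted = dict(label_query)
        pred = lambda labels: all(labels.get(k) == v for k, v in wanted.items())
    kept = tuple(
        t for t in trackset if t.n_points >= min_points and pred(t.labels)
    )
    out = TrackSet(
        kept, frame_interval=trackset.frame_interval, provenance=trackset.provenance
    )
    return FilterResult(out, n_removed=len(trackset) - len(kept))
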