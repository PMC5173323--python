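"""Synthetic track cohorts and labeled point patterns.

The simulator is a statistical emulator of intravital two-photon track
exports, not an agent-based model: it reproduces the sampling structure
(0.5-min frames, 10–15-min movies, cohorts of tens to hundreds of cells)
and the per-regime motility statistics, with no mechanistic immunology.

Motion models
-------------
``random_walk``
    Independent uniformly distributed direction each frame; per-frame step
    length either constant (``step_um``) or i.i.d. uniform on
    ``step_range_um = (lo, hi)``.  A constant step s at frame interval Δt
    gives every track a mean velocity of exactly s/Δt.
``confined``
    Mean-reverting walk around each track's starting point:
    x_{k+1} = x_k + tether·(x_0 − x_k) + step·u_k with tether ∈ (0, 1].
``directed``
    Random walk plus a constant per-frame drift vector (``drift_um``).
``stop_and_go``
    Two-state Markov chain over per-frame speeds (µm/min) with uniformly
    random directions; the initial state is drawn from the stationary
    distribution, so the expected fraction of arrested time equals the
    stationary slow-state occupancy.

Reproducibility: one ``numpy`` SeedSequence per simulate call, spawned into
independent per-track substreams, so output is identical for a given seed
regardless of platform or track order.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, GeometryError
from .spatial import DiscGeometry, PointPattern
from .tracks import Track, TrackSet

#: Sampling interval (minutes) of the emulated time-lapse exports.
DEFAULT_FRAME_INTERVAL = 0.5
#: Frames per track: a 15-minute movie at 0.5-min sampling.
DEFAULT_N_FRAMES = 31

MODELS = ("random_walk", "confined", "directed", "stop_and_go")


@dataclass(frozen=True)
class SimConfig:
    """Declarative specification of one synthetic cohort."""

    model: str
    params: Mapping[str, object]
    n_tracks: int
    n_frames: int = DEFAULT_N_FRAMES
    frame_interval: float = DEFAULT_FRAME_INTERVAL
    seed: int = 0
    dim: int = 2
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ConfigError(
                f"unknown motion model {self.model!r}; choose one of {MODELS}"
            )
        if self.n_tracks < 1:
            raise ConfigError("n_tracks must be >= 1")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.frame_interval <= 0:
            raise ConfigError("frame_interval must be positive (minutes)")
        if self.dim not in (2, 3):
            raise ConfigError("dim must be 2 or 3")
        object.__setattr__(self, "params", dict(self.params))
        object.__setattr__(self, "labels", dict(self.labels))

    def replace(self, **kwargs) -> "SimConfig":
        data = {**self.__dict__, **kwargs}
        return SimConfig(**data)


def _directions(rng: np.random.Generator, n: int, dim: int) -> np.ndarray:
    if dim == 2:
        theta = rng.uniform(0.0, 2.0 * math.pi, n)
        return np.column_stack([np.cos(theta), np.sin(theta)])
    v = rng.normal(size=(n, 3))
    norms = np.linalg.norm(v, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return v / norms


def _require_nonneg(params: Mapping[str, object], key: str) -> float:
    if key not in params:
        raise ConfigError(f"model parameter {key!r} is required")
    val = float(params[key])  # type: ignore[arg-type]
    if not math.isfinite(val) or val < 0:
        raise ConfigError(f"model parameter {key!r} must be a finite value >= 0")
    return val


def _step_lengths(
    rng: np.random.Generator, params: Mapping[str, object], n_steps: int
) -> np.ndarray:
    if "step_um" in params and "step_range_um" in params:
        raise ConfigError("give either step_um or step_range_um, not both")
    if "step_um" in params:
        return np.full(n_steps, _require_nonneg(params, "step_um"))
    if "step_range_um" in params:
        lo, hi = (float(v) for v in params["step_range_um"])  # type: ignore[misc]
        if lo < 0 or hi < lo:
            raise ConfigError("step_range_um must satisfy 0 <= lo <= hi")
        return rng.uniform(lo, hi, n_steps)
    raise ConfigError("model requires step_um or step_range_um")


def _simulate_steps(
    config: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-frame displacement vectors of one track, shape (n_frames-1, dim)."""
    n_steps = config.n_frames - 1
    p = config.params
    if config.model == "random_walk":
        return _step_lengths(rng, p, n_steps)[:, None] * _directions(
            rng, n_steps, config.dim
        )
    if config.model == "directed":
        drift = np.asarray(p.get("drift_um", (0.0,) * config.dim), dtype=float)
        if drift.shape != (config.dim,):
            raise ConfigError(
                f"drift_um must be a length-{config.dim} vector (µm per frame)"
            )
        step = _require_nonneg(p, "step_um") if "step_um" in p else 0.0
        noise = step * _directions(rng, n_steps, config.dim)
        return noise + drift
    if config.model == "stop_and_go":
        v_slow = _require_nonneg(p, "speed_slow_um_min")
        v_fast = _require_nonneg(p, "speed_fast_um_min")
        p_sf = _require_nonneg(p, "p_slow_to_fast")
        p_fs = _require_nonneg(p, "p_fast_to_slow")
        if p_sf > 1 or p_fs > 1:
            raise ConfigError("transition probabilities must lie in [0, 1]")
        if p_sf + p_fs == 0:
            raise ConfigError(
                "stop_and_go needs at least one positive transition probability"
            )
        pi_slow = p_fs / (p_sf + p_fs)
        states = np.empty(n_steps, dtype=np.int8)  # 0 = slow, 1 = fast
        u = rng.uniform(size=n_steps)
        states[0] = 0 if u[0] < pi_slow else 1
        for k in range(1, n_steps):
            if states[k - 1] == 0:
                states[k] = 1 if u[k] < p_sf else 0
            else:
                states[k] = 0 if u[k] < p_fs else 1
        speeds = np.where(states == 0, v_slow, v_fast)
        lengths = speeds * config.frame_interval
        return lengths[:, None] * _directions(rng, n_steps, config.dim)
    # confined
    step = _require_nonneg(p, "step_um")
    tether = float(p.get("tether", 0.5))  # type: ignore[arg-type]
    if not 0 < tether <= 1:
        raise ConfigError("tether must lie in (0, 1]")
    kicks = step * _directions(rng, n_steps, config.dim)
    steps = np.empty_like(kicks)
    offset = np.zeros(config.dim)  # x_k − x_0
    for k in range(n_steps):
        steps[k] = -tether * offset + kicks[k]
        offset = offset + steps[k]
    return steps


def simulate_trackset(config: SimConfig) -> TrackSet:
    """Simulate a cohort of tracks; deterministic given ``config.seed``."""
    times = np.arange(config.n_frames) * config.frame_interval
    substreams = np.random.SeedSequence(config.seed).spawn(config.n_tracks)
    tracks = []
    for i, ss in enumerate(substreams):
        rng = np.random.default_rng(ss)
        steps = _simulate_steps(config, rng)
        positions = np.vstack(
            [np.zeros((1, config.dim)), np.cumsum(steps, axis=0)]
        )
        tracks.append(
            Track(
                track_id=f"sim{i:05d}",
                times=times,
                positions=positions,
                labels=config.labels,
            )
        )
    return TrackSet(
        tuple(tracks),
        frame_interval=config.frame_interval,
        provenance=f"simulated: model={config.model} seed={config.seed}",
    )


# ---------------------------------------------------------------------------
# Labeled point patterns: tumor disc, peri-tumoral ring, exterior field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentIntensity:
    """Poisson intensities (cells/mm²) of one label per compartment."""

    interior: float = 0.0
    ring: float = 0.0
    exterior: float = 0.0

    def __post_init__(self) -> None:
        for name in ("interior", "ring", "exterior"):
            if getattr(self, name) < 0:
                raise ConfigError(f"intensity {name!r} must be >= 0")


@dataclass(frozen=True)
class PatternSpec:
    """Synthetic field: rectangular field (µm), central tumor disc, annular ring.

    ``intensities`` maps each point label to its per-compartment Poisson
    intensity.  Compartments are the tumor interior (disc of
    ``tumor_radius_um``), the boundary annulus of width ``ring_width_um``
    just outside the disc, and the remaining exterior field.
    """

    field_width_um: float
    field_height_um: float
    tumor_radius_um: float
    ring_width_um: float
    intensities: Mapping[str, CompartmentIntensity]
    center_um: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise GeometryError("field dimensions must be positive")
        if self.tumor_radius_um <= 0 or self.ring_width_um < 0:
            raise GeometryError("tumor radius must be > 0 and ring width >= 0")
        center = (
            np.array([self.field_width_um / 2.0, self.field_height_um / 2.0])
            if self.center_um is None
            else np.asarray(self.center_um, dtype=float)
        )
        outer = self.tumor_radius_um + self.ring_width_um
        if (
            center[0] - outer < 0
            or center[1] - outer < 0
            or center[0] + outer > self.field_width_um
            or center[1] + outer > self.field_height_um
        ):
            raise GeometryError(
                "tumor disc plus ring annulus must lie inside the field"
            )
        object.__setattr__(self, "center_um", center)
        object.__setattr__(self, "intensities", dict(self.intensities))

    @property
    def field_area_mm2(self) -> float:
        return self.field_width_um * self.field_height_um / 1e6


_UM2_PER_MM2 = 1e6


def _sample_disc(rng, center, r_in, r_out, n):
    """Uniform points in the annulus r_in <= r < r_out (r_in = 0: full disc)."""
    u = rng.uniform(size=n)
    r = np.sqrt(u * (r_out**2 - r_in**2) + r_in**2)
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    return center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_point_pattern(spec: PatternSpec) -> PointPattern:
    """Poisson point pattern per (label, compartment); deterministic given seed."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    center = np.asarray(spec.center_um, dtype=float)
    r_t = spec.tumor_radius_um
    r_o = r_t + spec.ring_width_um
    area_int = math.pi * r_t**2 / _UM2_PER_MM2
    area_ring = math.pi * (r_o**2 - r_t**2) / _UM2_PER_MM2
    area_ext = spec.field_area_mm2 - area_int - area_ring

    points: list[np.ndarray] = []
    labels: list[str] = []
    for label in sorted(spec.intensities):
        inten = spec.intensities[label]
        n_int = rng.poisson(inten.interior * area_int)
        n_ring = rng.poisson(inten.ring * area_ring)
        n_ext = rng.poisson(inten.exterior * area_ext)
        if n_int:
            points.append(_sample_disc(rng, center, 0.0, r_t, n_int))
            labels += [label] * n_int
        if n_ring:
            points.append(_sample_disc(rng, center, r_t, r_o, n_ring))
            labels += [label] * n_ring
        # exterior: rejection from the bounding rectangle
        got = 0
        chunks = []
        while got < n_ext:
            cand = rng.uniform(
                [0.0, 0.0],
                [spec.field_width_um, spec.field_height_um],
                size=(max(2 * (n_ext - got), 16), 2),
            )
            keep = np.linalg.norm(cand - center, axis=1) >= r_o
            cand = cand[keep][: n_ext - got]
            chunks.append(cand)
            got += len(cand)
        if n_ext:
            points.append(np.vstack(chunks))
            labels += [label] * n_ext
    pts = np.vstack(points) if points else np.empty((0, 2))
    return PointPattern(
        points=pts,
        labels=np.asarray(labels, dtype=object),
        field_area_mm2=spec.field_area_mm2,
        geometry=DiscGeometry(center_um=tuple(center), radius_um=r_t),
        field_bounds_um=(0.0, 0.0, spec.field_width_um, spec.field_height_um),
    )
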