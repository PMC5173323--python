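"""Cohort mean-displacement curves and the random-walk classification.

For each cell the displacement from its own starting position is evaluated
on the cohort's common time grid (multiples of the frame interval).  The
mean over cells at each elapsed time gives the MD curve; cells contribute
only while observed, so ``n_cells`` is non-increasing as shorter tracks
drop out.

A population executing an unbiased random walk has mean displacement
proportional to the square root of elapsed time, so an ordinary
least-squares fit of MD against √t with a coefficient of determination
strictly above 0.95 classifies the cohort as random-walking.  The t = 0
point (MD ≡ 0) is excluded from the fit to avoid an artificial anchor, and
grid points supported by fewer than ``min_cells_per_point`` cells are
dropped to guard against late-time noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, TrackValidationError
from .tracks import Track, TrackSet

#: R² above which (strictly) a cohort is classified as random-walking.
RANDOM_WALK_R2 = 0.95


@dataclass(frozen=True)
class MDCurve:
    """Mean displacement over cells versus elapsed time on a common grid."""

    times: np.ndarray       # elapsed minutes, starting at 0
    sqrt_times: np.ndarray  # min^(1/2)
    md: np.ndarray          # µm
    n_cells: np.ndarray     # contributing cells per grid point


@dataclass(frozen=True)
class RandomWalkFit:
    """OLS fit of MD against √t and the resulting classification."""

    slope: float       # µm · min^(-1/2)
    intercept: float   # µm
    r_squared: float
    is_random_walk: bool
    n_points: int


def displacement_from_origin(track: Track) -> tuple[np.ndarray, np.ndarray]:
    """(elapsed times, Euclidean distances from the first position)."""
    t_rel = track.times - track.times[0]
    d = np.linalg.norm(track.positions - track.positions[0], axis=1)
    return t_rel, d


def mean_displacement_curve(trackset: TrackSet) -> MDCurve:
    """Average displacement-from-origin over the cohort on the common grid.

    Requires a uniform frame interval (tracks are aligned by elapsed time
    from their own start, so the grid is 0, Δt, 2Δt, … up to the longest
    track).  Cohorts with irregular sampling must be resampled upstream.
    """
    if len(trackset) == 0:
        raise InsufficientDataError("empty cohort: no mean displacement curve")
    if trackset.frame_interval is None:
        raise TrackValidationError(
            "cohort sampling is irregular; resample tracks to a uniform frame "
            "interval before computing the mean displacement curve"
        )
    dt = trackset.frame_interval
    max_len = max(t.n_points for t in trackset)
    sums = np.zeros(max_len)
    counts = np.zeros(max_len, dtype=int)
    for t in trackset:
        _, d = displacement_from_origin(t)
        sums[: t.n_points] += d
        counts[: t.n_points] += 1
    md = np.divide(sums, counts, out=np.zeros(max_len), where=counts > 0)
    times = np.arange(max_len) * dt
    return MDCurve(
        times=times, sqrt_times=np.sqrt(times), md=md, n_cells=counts
    )


def fit_md_sqrt_time(
    curve: MDCurve,
    min_cells_per_point: int = 5,
    r2_threshold: float = RANDOM_WALK_R2,
) -> RandomWalkFit:
    """OLS of MD against √t (free intercept) over well-supported grid points.

    The t = 0 anchor is excluded; at least 3 usable points are required.
    When the retained MD values have zero variance the fit explains nothing
    and R² is reported as 0 (degenerate-case guard).
    """
    keep = (curve.times > 0) & (curve.n_cells >= min_cells_per_point)
    x = curve.sqrt_times[keep]
    y = curve.md[keep]
    if len(x) < 3:
        raise InsufficientDataError(
            f"only {len(x)} usable grid points (need >= 3) with at least "
            f"{min_cells_per_point} cells each"
        )
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return RandomWalkFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r_squared,
        is_random_walk=bool(r_squared > r2_threshold),
        n_points=int(len(x)),
    )


def md_random_walk_expectation(step_um: float, n_steps: int | np.ndarray) -> float | np.ndarray:
    """Asymptotic mean displacement of a 2-D fixed-step random walk.

    After k independent uniform-direction steps of length s the displacement
    is approximately Rayleigh with mean s·sqrt(πk)/2 (exact in the k → ∞
    Gaussian limit).  Used as an analytic cross-check, not by the fit.
    """
    return step_um * np.sqrt(math.pi * np.asarray(n_steps, dtype=float)) / 2.0
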