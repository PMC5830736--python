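"""Trajectory metrics for singer tracks: interpolation, separation distances,
meander ratio, and the pairwise solo-singer spatial null.

Separation between two singers is evaluated at the start and end of the
45-min analysis window; the change in distance (end minus start, negative =
approach) is the headline spatial statistic.  Its null distribution comes
from superimposing the tracks of solo singers recorded at non-overlapping
times, as though they had sung simultaneously: such pairs cannot have been
interacting, so their relative movement is random.

The meander ratio measures directionality: total path length over the
straight-line (chord) distance between the first and last positions,
accumulated over 5-min bin boundaries to avoid oversampling noisy
localizations.  A straight-line traveller scores 1; a milling singer scores
much higher.  The ratio is undefined (and flagged, not fabricated) when the
chord is shorter than 1 m, which is far below localization error.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CoverageError, ValidationError
from .io import SoloEndpoint
from .types import SingerTrack

__all__ = [
    "SpatialPair",
    "NullSpatialDistribution",
    "MeanderResult",
    "interpolate_track",
    "position_at",
    "separation",
    "dyad_spatial",
    "meander_ratio",
    "solo_pairwise_null",
]

#: If a track does not cover a window endpoint, the nearest covered time
#: within this many seconds is used instead (surfacing gaps); beyond it,
#: an error.
ENDPOINT_TOLERANCE_S = 300.0

#: Chord length below which the meander ratio is reported as undefined.
CHORD_EPSILON_M = 1.0


@dataclass(frozen=True)
class SpatialPair:
    """Start/end separation and change in distance for one pair of singers."""

    id_a: str
    id_b: str
    start_sep_m: float
    end_sep_m: float
    delta_m: float  # end - start; negative = approach

    def __post_init__(self) -> None:
        if self.start_sep_m < 0 or self.end_sep_m < 0:
            raise ValidationError("separations must be non-negative")


@dataclass(frozen=True)
class NullSpatialDistribution:
    """All pairwise SpatialPairs over a set of non-interacting solo singers."""

    pairs: tuple[SpatialPair, ...]
    n_singers: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def start_seps(self) -> np.ndarray:
        return np.array([p.start_sep_m for p in self.pairs])

    @property
    def end_seps(self) -> np.ndarray:
        return np.array([p.end_sep_m for p in self.pairs])

    @property
    def deltas(self) -> np.ndarray:
        return np.array([p.delta_m for p in self.pairs])


@dataclass(frozen=True)
class MeanderResult:
    """Path length, chord, and their ratio for one singer over one window.

    ``ratio`` is ``None`` when the chord is below :data:`CHORD_EPSILON_M`.
    """

    singer_id: str
    period_label: str
    path_m: float
    chord_m: float
    ratio: float | None


def interpolate_track(track: SingerTrack, grid_interval_s: float = 150.0) -> SingerTrack:
    """Linearly interpolate a track onto a regular grid within its span.

    The grid starts at the first sample time and never extrapolates; the
    operation is idempotent on its own output grid.
    """
    if len(track) < 2:
        raise ValidationError("interpolation needs at least 2 samples")
    if grid_interval_s <= 0:
        raise ValidationError("grid_interval_s must be positive")
    t0, t1 = track.span
    n = int(math.floor((t1 - t0) / grid_interval_s + 1e-9)) + 1
    grid = t0 + grid_interval_s * np.arange(n)
    x = np.interp(grid, track.times_s, track.x_m)
    y = np.interp(grid, track.times_s, track.y_m)
    return SingerTrack(track.singer_id, grid, x, y)


def position_at(track: SingerTrack, t_s: float) -> tuple[float, float]:
    """Linearly interpolated position at ``t_s``; errors outside the span."""
    t0, t1 = track.span
    if t_s < t0 - 1e-9 or t_s > t1 + 1e-9:
        raise CoverageError(
            f"t={t_s} outside track span [{t0}, {t1}] for singer {track.singer_id!r}"
        )
    x = float(np.interp(t_s, track.times_s, track.x_m))
    y = float(np.interp(t_s, track.times_s, track.y_m))
    return x, y


def separation(track_a: SingerTrack, track_b: SingerTrack, t_s: float) -> float:
    """Euclidean distance between two singers' interpolated positions."""
    xa, ya = position_at(track_a, t_s)
    xb, yb = position_at(track_b, t_s)
    return math.hypot(xa - xb, ya - yb)


def _snap_time(track: SingerTrack, t_s: float, tolerance_s: float) -> float:
    """Nearest covered time within tolerance (surfacing gaps at window ends)."""
    t0, t1 = track.span
    if t0 - 1e-9 <= t_s <= t1 + 1e-9:
        return t_s
    if t_s < t0 and t0 - t_s <= tolerance_s:
        return t0
    if t_s > t1 and t_s - t1 <= tolerance_s:
        return t1
    raise CoverageError(
        f"singer {track.singer_id!r} does not cover t={t_s} "
        f"(span [{t0}, {t1}], tolerance {tolerance_s} s)"
    )


def dyad_spatial(
    track_a: SingerTrack,
    track_b: SingerTrack,
    window_start_s: float,
    window_end_s: float,
    tolerance_s: float = ENDPOINT_TOLERANCE_S,
) -> SpatialPair:
    """Start/end separation and change in distance over an analysis window."""
    if window_end_s <= window_start_s:
        raise ValidationError("window end must be after start")
    start = math.hypot(
        *(
            np.array(position_at(track_a, _snap_time(track_a, window_start_s, tolerance_s)))
            - np.array(position_at(track_b, _snap_time(track_b, window_start_s, tolerance_s)))
        )
    )
    end = math.hypot(
        *(
            np.array(position_at(track_a, _snap_time(track_a, window_end_s, tolerance_s)))
            - np.array(position_at(track_b, _snap_time(track_b, window_end_s, tolerance_s)))
        )
    )
    return SpatialPair(track_a.singer_id, track_b.singer_id, start, end, end - start)


def meander_ratio(
    track: SingerTrack,
    window_start_s: float,
    window_end_s: float,
    bin_s: float = 300.0,
    *,
    period_label: str = "",
    tolerance_s: float = ENDPOINT_TOLERANCE_S,
    chord_eps_m: float = CHORD_EPSILON_M,
) -> MeanderResult:
    """Path length over chord length, accumulated at 5-min bin boundaries.

    The path is the sum of Euclidean distances between positions at
    consecutive bin boundaries; the chord joins the first and last boundary
    positions.  A trailing partial bin shorter than ``bin_s`` still
    contributes its boundary at the window end.
    """
    if bin_s <= 0:
        raise ValidationError("bin_s must be positive")
    if window_end_s - window_start_s < bin_s:
        raise ValidationError("window shorter than one bin")
    ws = _snap_time(track, window_start_s, tolerance_s)
    we = _snap_time(track, window_end_s, tolerance_s)
    bounds = list(np.arange(ws, we + 1e-9, bin_s))
    if we - bounds[-1] > 1e-6:
        bounds.append(we)
    pts = np.array([position_at(track, t) for t in bounds])
    steps = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    path = float(steps.sum())
    chord = float(math.hypot(pts[-1, 0] - pts[0, 0], pts[-1, 1] - pts[0, 1]))
    ratio = path / chord if chord >= chord_eps_m else None
    return MeanderResult(track.singer_id, period_label, path, chord, ratio)


def solo_pairwise_null(endpoints: Sequence[SoloEndpoint]) -> NullSpatialDistribution:
    """Superimpose solo singers pairwise to build the spatial null.

    Each unordered pair of solo singers (recorded at non-overlapping times)
    contributes one :class:`SpatialPair` computed from their start and end
    positions; n singers give C(n, 2) pairs.
    """
    ids = [sid for sid, _, _ in endpoints]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate singer_id in solo endpoints")
    if len(ids) < 2:
        raise ValidationError("need at least 2 solo singers")
    pairs = []
    for (ia, sa, ea), (ib, sb, eb) in itertools.combinations(endpoints, 2):
        start = math.hypot(sa[0] - sb[0], sa[1] - sb[1])
        end = math.hypot(ea[0] - eb[0], ea[1] - eb[1])
        pairs.append(SpatialPair(ia, ib, start, end, end - start))
    return NullSpatialDistribution(tuple(pairs), n_singers=len(ids))
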