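"""Synthetic song sequences, dyads, and movement tracks with the statistical
structure the analysis assumes, so every pipeline stage is testable without
field recordings.

Song model
----------
A singer cycles through a shared repertoire (default 10 phrase types) with
*eventual variety*: each phrase repeats the current type, and at each phrase
start the singer switches to the next theme with probability ``switch_prob``.
Adjacent phrases therefore differ independently with that probability, so the
expected switching rate equals ``switch_prob`` — a clean recovery target.
Phrase durations are truncated normal with a 3-s floor (song is continuous:
pauses between phrases are no longer than pauses between notes), with
occasional surfacing gaps.

Dyad model
----------
The focal singer sings across the whole BEFORE + DURING span; the second
singer starts at the scenario onset.  A coupling parameter ``coupling_m``
models song matching: at each of his phrase starts, the second singer adopts
the focal's concurrent phrase type with probability ``coupling_m`` (he always
finishes his current phrase first).  With ``coupling_m = 0`` the two label
processes are independent; with 1 the second singer always matches.

Movement model
--------------
A correlated random walk: constant speed, heading perturbed each step by
Gaussian noise of s.d. ``turn_sd_rad``, optionally biased toward an
attraction point.  ``turn_sd_rad = 0`` with no target gives exactly straight
travel (meander ratio 1); large values give milling.  An optional quit rule
truncates one singer's annotations at the first moment the pair closes
within a threshold distance, emulating song cessation on close approach.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .io import SoloEndpoint
from .types import DyadScenario, PhraseAnnotation, SingerTrack

__all__ = [
    "SongGenParams",
    "TrackGenParams",
    "QuitRule",
    "DyadGenParams",
    "simulate_song",
    "simulate_track",
    "simulate_dyad",
    "simulate_solo_population",
    "DEFAULT_REPERTOIRE",
]

#: Shared population repertoire (at most ~10 types are present at one time).
DEFAULT_REPERTOIRE: tuple[str, ...] = tuple(f"P{i:02d}" for i in range(1, 11))

#: Heading correction toward the attraction point, radians of the remaining
#: bearing error applied per step.
TARGET_ATTRACTION_GAIN = 0.3

#: Minimum phrase duration; truncated-normal durations are resampled below it.
MIN_PHRASE_DUR_S = 3.0

#: Deployment footprint over which solo singers are scattered (meters).
DEFAULT_FOOTPRINT_M = (6000.0, 3000.0)


@dataclass(frozen=True)
class SongGenParams:
    """Parameters of the eventual-variety song generator."""

    repertoire: tuple[str, ...] = DEFAULT_REPERTOIRE
    phrase_dur_mean_s: float = 15.0
    phrase_dur_sd_s: float = 4.0
    switch_prob: float = 0.12  # expected switching rate
    cycle_order: bool = True  # themes follow repertoire order cyclically
    gap_prob: float = 0.05  # per-phrase probability of a surfacing gap
    gap_dur_s: float = 45.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.repertoire)) < 2:
            raise ValidationError("repertoire needs at least 2 distinct types")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValidationError("switch_prob must lie in [0, 1]")
        if self.phrase_dur_mean_s <= 0 or self.phrase_dur_sd_s < 0:
            raise ValidationError("phrase durations must be positive")
        if not 0.0 <= self.gap_prob <= 1.0 or self.gap_dur_s < 0:
            raise ValidationError("invalid gap model")


@dataclass(frozen=True)
class TrackGenParams:
    """Parameters of the correlated-random-walk track generator."""

    start_xy: tuple[float, float] = (0.0, 0.0)
    speed_mps: float = 1.0
    turn_sd_rad: float = 0.3
    target_xy: tuple[float, float] | None = None
    step_s: float = 60.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.speed_mps < 0:
            raise ValidationError("speed must be >= 0")
        if self.step_s <= 0:
            raise ValidationError("step_s must be positive")
        if self.turn_sd_rad < 0:
            raise ValidationError("turn_sd_rad must be >= 0")


@dataclass(frozen=True)
class QuitRule:
    """Stop one singer's song at the first separation below a threshold."""

    threshold_m: float
    who: str = "second"  # "focal" or "second"

    def __post_init__(self) -> None:
        if self.threshold_m <= 0:
            raise ValidationError("threshold_m must be positive")
        if self.who not in ("focal", "second"):
            raise ValidationError("who must be 'focal' or 'second'")


@dataclass(frozen=True)
class DyadGenParams:
    """Everything needed to synthesise one focal/second dyad."""

    focal_song: SongGenParams = field(default_factory=SongGenParams)
    second_song: SongGenParams = field(default_factory=SongGenParams)
    coupling_m: float = 0.0
    focal_track: TrackGenParams = field(default_factory=TrackGenParams)
    second_track: TrackGenParams = field(
        default_factory=lambda: TrackGenParams(start_xy=(3000.0, 1500.0))
    )
    quit_rule: QuitRule | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_m <= 1.0:
            raise ValidationError("coupling_m must lie in [0, 1]")


def _phrase_duration(params: SongGenParams, rng: np.random.Generator) -> float:
    """Truncated-normal duration with a hard floor (resampling truncation)."""
    for _ in range(1000):
        d = rng.normal(params.phrase_dur_mean_s, params.phrase_dur_sd_s)
        if d >= MIN_PHRASE_DUR_S:
            return d
    return MIN_PHRASE_DUR_S


def _next_type(current_idx: int, params: SongGenParams, rng: np.random.Generator) -> int:
    """Theme transition: next in cyclic order, or a uniform different type."""
    n = len(params.repertoire)
    if params.cycle_order:
        return (current_idx + 1) % n
    step = int(rng.integers(1, n))
    return (current_idx + step) % n


def simulate_song(
    params: SongGenParams,
    span_s: float,
    *,
    singer_id: str = "singer",
    start_s: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[PhraseAnnotation]:
    """Generate an eventual-variety phrase sequence tiling [start_s, start_s + span_s).

    Phrases are contiguous except for sampled surfacing gaps; the final
    phrase is clipped at the span end.
    """
    if span_s <= 0:
        raise ValidationError("span_s must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    end_of_span = start_s + span_s
    idx = int(rng.integers(len(params.repertoire)))
    t = start_s
    out: list[PhraseAnnotation] = []
    while t < end_of_span - 1e-9:
        dur = _phrase_duration(params, rng)
        end = min(t + dur, end_of_span)
        if end - t >= 0.5:  # drop a sliver phrase at the very end
            out.append(PhraseAnnotation(singer_id, t, end, params.repertoire[idx]))
        t = end
        if params.gap_prob > 0 and rng.random() < params.gap_prob:
            t += params.gap_dur_s
        if rng.random() < params.switch_prob:
            idx = _next_type(idx, params, rng)
    if not out:
        raise ValidationError("span too short to fit any phrase")
    return out


def simulate_track(
    params: TrackGenParams,
    span_s: float,
    *,
    singer_id: str = "singer",
    start_t_s: float = 0.0,
    rng: np.random.Generator | None = None,
) -> SingerTrack:
    """Correlated-random-walk track sampled every ``step_s`` seconds."""
    if span_s < 2 * params.step_s:
        raise ValidationError("span_s must cover at least two steps")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_steps = int(math.floor(span_s / params.step_s + 1e-9))
    times = start_t_s + params.step_s * np.arange(n_steps + 1)
    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    x, y = params.start_xy
    xs[0], ys[0] = x, y
    heading = float(rng.uniform(0.0, 2.0 * math.pi))
    for i in range(1, n_steps + 1):
        if params.target_xy is not None:
            bearing = math.atan2(params.target_xy[1] - y, params.target_xy[0] - x)
            err = (bearing - heading + math.pi) % (2.0 * math.pi) - math.pi
            heading += TARGET_ATTRACTION_GAIN * err
        if params.turn_sd_rad > 0:
            heading += float(rng.normal(0.0, params.turn_sd_rad))
        x += params.speed_mps * params.step_s * math.cos(heading)
        y += params.speed_mps * params.step_s * math.sin(heading)
        xs[i], ys[i] = x, y
    return SingerTrack(singer_id, times, xs, ys)


def _phrase_type_at(annotations: list[PhraseAnnotation], t_s: float) -> str | None:
    """Phrase type covering ``t_s`` in a sorted non-overlapping sequence."""
    for a in annotations:
        if a.begin_s <= t_s < a.end_s:
            return a.phrase_type
        if a.begin_s > t_s:
            break
    return None


def simulate_dyad(
    params: DyadGenParams, scenario: DyadScenario
) -> tuple[list[PhraseAnnotation], dict[str, SingerTrack]]:
    """Synthesise annotations and tracks for one focal/second dyad.

    The focal singer sings over [onset - before_len, onset + during_len); the
    second singer starts at the onset.  Returns the combined, time-sorted
    annotation list and a track per singer id.
    """
    rng = np.random.default_rng(params.seed if params.seed is not None else scenario.seed)
    before_start = scenario.before_start_s
    span_total = scenario.before_len_s + scenario.during_len_s

    focal_ann = simulate_song(
        params.focal_song,
        span_total,
        singer_id=scenario.focal_id,
        start_s=before_start,
        rng=rng,
    )

    # Second singer: his own eventual-variety process, overridden at each
    # phrase start by the focal's concurrent type with probability coupling_m.
    sp = params.second_song
    idx = int(rng.integers(len(sp.repertoire)))
    t = scenario.onset_s
    second_ann: list[PhraseAnnotation] = []
    while t < scenario.during_end_s - 1e-9:
        phrase_type = sp.repertoire[idx]
        if params.coupling_m > 0 and rng.random() < params.coupling_m:
            concurrent = _phrase_type_at(focal_ann, t)
            if concurrent is not None:
                phrase_type = concurrent
                if concurrent in sp.repertoire:
                    idx = sp.repertoire.index(concurrent)
        dur = _phrase_duration(sp, rng)
        end = min(t + dur, scenario.during_end_s)
        if end - t >= 0.5:
            second_ann.append(PhraseAnnotation(scenario.second_id, t, end, phrase_type))
        t = end
        if sp.gap_prob > 0 and rng.random() < sp.gap_prob:
            t += sp.gap_dur_s
        if rng.random() < sp.switch_prob:
            idx = _next_type(idx, sp, rng)

    tracks = {
        scenario.focal_id: simulate_track(
            params.focal_track,
            span_total,
            singer_id=scenario.focal_id,
            start_t_s=before_start,
            rng=rng,
        ),
        scenario.second_id: simulate_track(
            params.second_track,
            span_total,
            singer_id=scenario.second_id,
            start_t_s=before_start,
            rng=rng,
        ),
    }

    if params.quit_rule is not None:
        t_quit = _first_close_time(
            tracks[scenario.focal_id],
            tracks[scenario.second_id],
            params.quit_rule.threshold_m,
            from_t=scenario.onset_s,
        )
        if t_quit is not None:
            who = (
                scenario.focal_id
                if params.quit_rule.who == "focal"
                else scenario.second_id
            )
            if who == scenario.focal_id:
                focal_ann = _truncate(focal_ann, t_quit)
            else:
                second_ann = _truncate(second_ann, t_quit)

    annotations = sorted(focal_ann + second_ann, key=lambda a: (a.begin_s, a.singer_id))
    return annotations, tracks


def _first_close_time(
    a: SingerTrack, b: SingerTrack, threshold_m: float, from_t: float
) -> float | None:
    """First shared sample time >= from_t with separation below threshold."""
    common = np.intersect1d(a.times_s, b.times_s)
    common = common[common >= from_t]
    for t in common:
        xa = np.interp(t, a.times_s, a.x_m)
        ya = np.interp(t, a.times_s, a.y_m)
        xb = np.interp(t, b.times_s, b.x_m)
        yb = np.interp(t, b.times_s, b.y_m)
        if math.hypot(xa - xb, ya - yb) < threshold_m:
            return float(t)
    return None


def _truncate(annotations: list[PhraseAnnotation], t_s: float) -> list[PhraseAnnotation]:
    out = []
    for a in annotations:
        if a.begin_s >= t_s - 1e-9:
            break
        out.append(a if a.end_s <= t_s else replace(a, end_s=t_s))
    return out


def simulate_solo_population(
    n: int,
    params: TrackGenParams,
    span_s: float,
    seed: int | None = None,
    footprint_m: tuple[float, float] = DEFAULT_FOOTPRINT_M,
) -> list[SoloEndpoint]:
    """Start/end positions of ``n`` independent solo singers.

    Start points are scattered uniformly over the deployment footprint
    (default ~6 km x 3 km); each singer then follows an independent
    correlated random walk for ``span_s`` seconds.
    """
    if n < 2:
        raise ValidationError("need at least 2 solo singers")
    rng = np.random.default_rng(seed)
    endpoints: list[SoloEndpoint] = []
    for i in range(n):
        start = (
            float(rng.uniform(0.0, footprint_m[0])),
            float(rng.uniform(0.0, footprint_m[1])),
        )
        track = simulate_track(
            replace(params, start_xy=start),
            span_s,
            singer_id=f"solo{i + 1:02d}",
            rng=rng,
        )
        endpoints.append(
            (
                track.singer_id,
                (float(track.x_m[0]), float(track.y_m[0])),
                (float(track.x_m[-1]), float(track.y_m[-1])),
            )
        )
    return endpoints
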