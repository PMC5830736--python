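"""Core domain types: phrase annotations, singer tracks, dyad scenarios.

Times are seconds from a per-scenario epoch (recording start) and are stored
as floats with at least millisecond precision.  Coordinates are planar meters
in a local projection centred on the recording array; geographic conversion
is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import ValidationError

__all__ = ["PhraseAnnotation", "SingerTrack", "DyadScenario"]


@dataclass(frozen=True, order=True)
class PhraseAnnotation:
    """One sung phrase: a labelled time interval produced by one singer.

    Song is a non-overlapping sequence of phrases, so two annotations from
    the same singer may touch but never overlap (enforced at file-read time,
    not per annotation).
    """

    singer_id: str
    begin_s: float
    end_s: float
    phrase_type: str

    def __post_init__(self) -> None:
        if self.end_s <= self.begin_s:
            raise ValidationError(
                f"phrase end ({self.end_s}) must be after begin ({self.begin_s})"
            )
        if self.begin_s < 0:
            raise ValidationError(f"phrase begin must be >= 0, got {self.begin_s}")
        if not self.phrase_type:
            raise ValidationError("phrase_type must be a non-empty label")

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.begin_s + self.end_s)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.begin_s


@dataclass(frozen=True)
class SingerTrack:
    """Time-ordered planar positions for one singer.

    A track may hold a single sample, but every movement metric requires at
    least two.
    """

    singer_id: str
    times_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        x = np.asarray(self.x_m, dtype=float)
        y = np.asarray(self.y_m, dtype=float)
        if not (t.ndim == x.ndim == y.ndim == 1) or not (len(t) == len(x) == len(y)):
            raise ValidationError("times_s, x_m, y_m must be 1-d and equal length")
        if len(t) == 0:
            raise ValidationError("a track needs at least one sample")
        if np.any(np.diff(t) <= 0):
            raise ValidationError(
                f"track times for {self.singer_id!r} must be strictly increasing"
            )
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "x_m", x)
        object.__setattr__(self, "y_m", y)

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times_s[0]), float(self.times_s[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SingerTrack):
            return NotImplemented
        return (
            self.singer_id == other.singer_id
            and np.array_equal(self.times_s, other.times_s)
            and np.array_equal(self.x_m, other.x_m)
            and np.array_equal(self.y_m, other.y_m)
        )


@dataclass(frozen=True)
class DyadScenario:
    """Analysis parameters for one focal/second singer pair.

    Defaults encode the study design: up to 45 min of solo singing before the
    second singer's onset (BEFORE) and up to 45 min of joint singing after it
    (DURING), each tiled into 15-min windows; phrase-type overlap sampled on
    an 8-s grid and tested against 1000 Monte Carlo time shifts.
    """

    focal_id: str
    second_id: str
    onset_s: float
    before_len_s: float = 2700.0
    during_len_s: float = 2700.0
    window_len_s: float = 900.0
    grid_interval_s: float = 8.0
    mc_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.focal_id == self.second_id:
            raise ValidationError("focal_id and second_id must differ")
        if self.window_len_s <= 0:
            raise ValidationError("window_len_s must be positive")
        if self.before_len_s <= 0 or self.during_len_s <= 0:
            raise ValidationError("period lengths must be positive")
        for name in ("before_len_s", "during_len_s"):
            length = getattr(self, name)
            if abs(length / self.window_len_s - round(length / self.window_len_s)) > 1e-9:
                raise ValidationError(
                    f"window_len_s ({self.window_len_s}) must divide {name} ({length})"
                )
        if self.grid_interval_s <= 0:
            raise ValidationError("grid_interval_s must be positive")
        if self.mc_reps < 1:
            raise ValidationError("mc_reps must be >= 1")

    @property
    def before_start_s(self) -> float:
        """Nominal start of the BEFORE period (onset minus its full length)."""
        return self.onset_s - self.before_len_s

    @property
    def during_end_s(self) -> float:
        return self.onset_s + self.during_len_s

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))
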