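"""Per-window song-pattern metrics: switching rate and relative song evenness.

The analysis design tiles each period (BEFORE = focal singing alone, DURING =
both singers present) into fixed 15-min windows, computes switching rate (SR)
and relative song evenness (J') within each window, and averages defined
windows per period.

Switching rate
    SR = Tn / (Pn - 1), the number of transitions between different adjacent
    phrase types divided by one less than the number of phrases.  SR is 0 for
    a singer repeating one type and 1 for a singer switching at every phrase.

Relative song evenness
    A Shannon index normalised by the repertoire size k,

        J' = -sum_i p_i * log(p_i) / log(k),

    where p_i is the proportion of phrases of type i among the k phrase
    types in the singer's current repertoire.  J' = 1 when every repertoire
    type is sung equally often and 0 when a single type is sung exclusively.
    The log base cancels; natural logs are used internally.

The repertoire k for J' is the set of phrase types the singer used across
his analysed span (BEFORE + DURING for the focal singer, DURING for the
second singer): song changes over seasons, so only types present at the time
of recording count.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import UndefinedMetricError, ValidationError
from .types import DyadScenario, PhraseAnnotation

__all__ = [
    "WindowSpec",
    "WindowMetrics",
    "PeriodMetrics",
    "segment_windows",
    "phrase_sequence_in_window",
    "switching_rate",
    "song_evenness",
    "observed_repertoire",
    "window_metrics",
    "period_metrics",
    "window_metrics_table",
]

BEFORE = "BEFORE"
DURING = "DURING"

# A leading partial BEFORE window is kept only if it spans at least this
# fraction of a full window, so windows stay comparable.
PARTIAL_WINDOW_MIN_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class WindowSpec:
    """One analysis window [start_s, end_s) within a period."""

    start_s: float
    end_s: float
    period_label: str  # BEFORE or DURING
    index: int  # ordinal within the period, in time order

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValidationError("window end must be after start")
        if self.period_label not in (BEFORE, DURING):
            raise ValidationError(f"period_label must be BEFORE or DURING, got {self.period_label!r}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class WindowMetrics:
    """Song-pattern metrics for one singer in one window.

    ``switching_rate`` and ``evenness`` are ``None`` when undefined (fewer
    than two phrases, or an empty window); undefined windows are excluded
    from period averages but still reported.
    """

    window: WindowSpec
    singer_id: str
    n_phrases: int
    n_transitions: int
    switching_rate: float | None
    evenness: float | None
    k_repertoire: int
    phrase_proportions: dict[str, float]


@dataclass(frozen=True)
class PeriodMetrics:
    singer_id: str
    period_label: str
    mean_switching_rate: float | None
    mean_evenness: float | None
    windows: tuple[WindowMetrics, ...]


def segment_windows(
    scenario: DyadScenario, actual_before_start_s: float
) -> list[WindowSpec]:
    """Tile the BEFORE and DURING periods into analysis windows.

    DURING windows tile forward from the second singer's onset; BEFORE
    windows tile backward from the onset, clipped to the time the focal
    singer's solo recording actually starts.  A leading partial BEFORE
    window is kept only if it spans at least 2/3 of a full window.
    """
    if actual_before_start_s >= scenario.onset_s:
        raise ValidationError("actual_before_start_s must precede onset_s")
    w = scenario.window_len_s
    onset = scenario.onset_s

    before: list[tuple[float, float]] = []
    n_before_max = int(round(scenario.before_len_s / w))
    for i in range(n_before_max):
        hi = onset - i * w
        lo = hi - w
        if lo >= actual_before_start_s - 1e-9:
            before.append((lo, hi))
        else:
            if hi - actual_before_start_s >= PARTIAL_WINDOW_MIN_FRACTION * w - 1e-9:
                before.append((actual_before_start_s, hi))
            break
    if not before:
        raise ValidationError("insufficient before period: no window meets the minimum span")
    before.sort()

    n_during = int(round(scenario.during_len_s / w))
    during = [(onset + i * w, onset + (i + 1) * w) for i in range(n_during)]

    windows = [
        WindowSpec(lo, hi, BEFORE, i) for i, (lo, hi) in enumerate(before)
    ] + [WindowSpec(lo, hi, DURING, i) for i, (lo, hi) in enumerate(during)]
    return windows


def phrase_sequence_in_window(
    annotations: Iterable[PhraseAnnotation], singer_id: str, window: WindowSpec
) -> list[str]:
    """Time-ordered phrase types whose midpoints fall in [start_s, end_s).

    Assignment by midpoint is unambiguous and symmetric at window
    boundaries; an empty list is a valid result.
    """
    picked = [
        a
        for a in annotations
        if a.singer_id == singer_id and window.start_s <= a.midpoint_s < window.end_s
    ]
    picked.sort(key=lambda a: a.begin_s)
    return [a.phrase_type for a in picked]


def switching_rate(sequence: Sequence[str]) -> float:
    """SR = (# adjacent unequal pairs) / (len - 1); undefined for len < 2."""
    n = len(sequence)
    if n < 2:
        raise UndefinedMetricError("switching rate needs at least 2 phrases")
    transitions = sum(a != b for a, b in zip(sequence, sequence[1:]))
    return transitions / (n - 1)


def song_evenness(sequence: Sequence[str], repertoire: Iterable[str]) -> float:
    """Normalised Shannon evenness of phrase-type use over a repertoire.

    ``0 * log 0`` is taken as 0, so types in the repertoire that go unsung
    contribute nothing to the entropy but still enlarge ``k``.
    """
    rep = set(repertoire)
    k = len(rep)
    if k < 2:
        raise UndefinedMetricError("evenness needs a repertoire of at least 2 types")
    if len(sequence) == 0:
        raise UndefinedMetricError("evenness of an empty sequence is undefined")
    outside = set(sequence) - rep
    if outside:
        raise ValidationError(f"phrase types outside the repertoire: {sorted(outside)}")
    n = len(sequence)
    counts = Counter(sequence)
    h = -sum(
        (c / n) * math.log(c / n) for c in counts.values() if c > 0
    )
    return h / math.log(k)


def observed_repertoire(
    annotations: Iterable[PhraseAnnotation], singer_id: str
) -> list[str]:
    """Sorted phrase types a singer used anywhere in his annotations."""
    return sorted({a.phrase_type for a in annotations if a.singer_id == singer_id})


def window_metrics(
    annotations: Iterable[PhraseAnnotation],
    singer_id: str,
    window: WindowSpec,
    repertoire: Iterable[str],
) -> WindowMetrics:
    seq = phrase_sequence_in_window(annotations, singer_id, window)
    n = len(seq)
    transitions = sum(a != b for a, b in zip(seq, seq[1:]))
    rep = sorted(set(repertoire))
    try:
        sr: float | None = switching_rate(seq)
    except UndefinedMetricError:
        sr = None
    try:
        j: float | None = song_evenness(seq, rep)
    except UndefinedMetricError:
        j = None
    proportions = {p: c / n for p, c in Counter(seq).items()} if n else {}
    return WindowMetrics(
        window=window,
        singer_id=singer_id,
        n_phrases=n,
        n_transitions=transitions,
        switching_rate=sr,
        evenness=j,
        k_repertoire=len(rep),
        phrase_proportions=proportions,
    )


def period_metrics(
    annotations: Iterable[PhraseAnnotation],
    singer_id: str,
    windows: Sequence[WindowSpec],
    repertoire: Iterable[str],
) -> PeriodMetrics:
    """Average per-window SR and J' over the windows where each is defined."""
    annotations = list(annotations)
    labels = {w.period_label for w in windows}
    if len(labels) != 1:
        raise ValidationError("period_metrics expects windows from a single period")
    wms = tuple(window_metrics(annotations, singer_id, w, repertoire) for w in windows)
    srs = [m.switching_rate for m in wms if m.switching_rate is not None]
    js = [m.evenness for m in wms if m.evenness is not None]
    if not srs and not js:
        raise UndefinedMetricError(
            f"all {len(wms)} windows undefined for singer {singer_id!r}"
        )
    return PeriodMetrics(
        singer_id=singer_id,
        period_label=labels.pop(),
        mean_switching_rate=sum(srs) / len(srs) if srs else None,
        mean_evenness=sum(js) / len(js) if js else None,
        windows=wms,
    )


def window_metrics_table(metrics: Iterable[WindowMetrics]) -> pd.DataFrame:
    """Per-window metrics as a tidy frame (the TSV report layout)."""
    rows = [
        {
            "singer_id": m.singer_id,
            "period": m.window.period_label,
            "window_index": m.window.index,
            "n_phrases": m.n_phrases,
            "n_transitions": m.n_transitions,
            "switching_rate": m.switching_rate,
            "evenness": m.evenness,
            "k": m.k_repertoire,
        }
        for m in metrics
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "singer_id",
            "period",
            "window_index",
            "n_phrases",
            "n_transitions",
            "switching_rate",
            "evenness",
            "k",
        ],
    )
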