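"""Phrase-type overlap between two simultaneous singers and its Monte Carlo
time-shift null.

Humpback song is continuous and cyclical and all males in a population sing
from a shared repertoire, so some overlap between coincident songs is
expected by chance.  The test therefore compares the observed overlap to a
null built by re-starting the second singer's entire phrase sequence (order
and durations preserved) at random times within the BEFORE period:

1.  Both singers' phrase types are sampled every 8 s across the DURING
    period; grid points where an annotation covers the sample time get its
    label, others are gaps (surfacing, or span not covered).
2.  The observed statistic is the proportion of co-sampled grid points
    (both singers non-gap) at which the two labels agree.
3.  For each of ``mc_reps`` replicates a uniform start time is drawn in the
    BEFORE period, the second singer's sequence is translated there, and the
    overlap proportion is recomputed on the same grid.  Replicates whose
    shifted sequence co-covers less than a minimum fraction of the grid are
    redrawn (the statistic is unstable on a sliver of shared coverage).
4.  Right- and left-tail p-values use the add-one Monte Carlo correction,
    p = (1 + #{null >= observed}) / (1 + reps), so neither can be exactly 0.

The proportion (rather than the raw match count) is reported because shifted
sequences cover the grid unevenly; both tails are reported because a dyad
may match more *or less* than chance (avoidance).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import UndefinedMetricError, ValidationError
from .types import DyadScenario, PhraseAnnotation

__all__ = [
    "GAP",
    "CategoricalSeries",
    "MatchTestResult",
    "sample_phrase_grid",
    "overlap_proportion",
    "shift_sequence",
    "mc_overlap_test",
]

#: Sentinel label for grid samples not covered by any phrase.
GAP = None

#: Default minimum fraction of the grid that must be co-sampled for a null
#: replicate to count, and the redraw budget per replicate.
MIN_CO_COVERAGE = 0.25
MAX_REDRAWS = 10


@dataclass(frozen=True)
class CategoricalSeries:
    """Phrase-type labels sampled on a fixed-interval grid (GAP = no phrase)."""

    grid_start_s: float
    interval_s: float
    labels: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if self.interval_s <= 0:
            raise ValidationError("interval_s must be positive")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def times_s(self) -> np.ndarray:
        return self.grid_start_s + self.interval_s * np.arange(len(self.labels))


@dataclass(frozen=True)
class MatchTestResult:
    """Observed overlap, its Monte Carlo null, and add-one tail p-values."""

    observed_overlap: float
    null_overlaps: np.ndarray
    p_right: float
    p_left: float
    n_co_samples: int
    seed: int
    n_missing_reps: int = 0

    @property
    def mean_expected_overlap(self) -> float:
        return float(np.mean(self.null_overlaps))


def _intervals(
    annotations: Iterable[PhraseAnnotation], singer_id: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Sorted (begins, ends, labels) arrays for one singer."""
    anns = sorted(
        (a for a in annotations if a.singer_id == singer_id), key=lambda a: a.begin_s
    )
    begins = np.array([a.begin_s for a in anns], dtype=float)
    ends = np.array([a.end_s for a in anns], dtype=float)
    labels = [a.phrase_type for a in anns]
    return begins, ends, labels


def _grid_times(window_start_s: float, window_end_s: float, interval_s: float) -> np.ndarray:
    n = int(np.floor((window_end_s - window_start_s) / interval_s + 1e-9))
    return window_start_s + interval_s * np.arange(n)


def _sample_codes(
    begins: np.ndarray, ends: np.ndarray, codes: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Integer phrase codes at grid times; -1 where no phrase covers t.

    Relies on same-singer phrases being non-overlapping, so ``ends`` is
    sorted whenever ``begins`` is.
    """
    out = np.full(times.shape, -1, dtype=np.int64)
    if len(begins) == 0:
        return out
    idx = np.searchsorted(begins, times, side="right") - 1
    valid = idx >= 0
    hit = np.zeros_like(valid)
    hit[valid] = times[valid] < ends[idx[valid]]
    out[hit] = codes[idx[hit]]
    return out


def sample_phrase_grid(
    annotations: Iterable[PhraseAnnotation],
    singer_id: str,
    window_start_s: float,
    window_end_s: float,
    interval_s: float = 8.0,
) -> CategoricalSeries:
    """Sample one singer's phrase type every ``interval_s`` seconds.

    The label at grid time t is the phrase type of the annotation with
    ``begin_s <= t < end_s``, else :data:`GAP`.
    """
    if interval_s <= 0:
        raise ValidationError("interval_s must be positive")
    begins, ends, labels = _intervals(annotations, singer_id)
    times = _grid_times(window_start_s, window_end_s, interval_s)
    codes = _sample_codes(begins, ends, np.arange(len(labels)), times)
    out = tuple(labels[c] if c >= 0 else GAP for c in codes)
    return CategoricalSeries(window_start_s, interval_s, out)


def overlap_proportion(
    a: CategoricalSeries, b: CategoricalSeries
) -> tuple[float, int]:
    """Proportion of co-sampled grid points where both labels agree.

    Co-samples are grid points at which neither series is a gap.  Raises
    :class:`UndefinedMetricError` when there are none.
    """
    if (
        abs(a.grid_start_s - b.grid_start_s) > 1e-9
        or abs(a.interval_s - b.interval_s) > 1e-9
        or len(a) != len(b)
    ):
        raise ValidationError("series must share the same grid (start, interval, length)")
    co = 0
    matches = 0
    for la, lb in zip(a.labels, b.labels):
        if la is not GAP and lb is not GAP:
            co += 1
            if la == lb:
                matches += 1
    if co == 0:
        raise UndefinedMetricError("no co-sampled grid points")
    return matches / co, co


def shift_sequence(
    annotations: Iterable[PhraseAnnotation], singer_id: str, new_start_s: float
) -> list[PhraseAnnotation]:
    """Translate a singer's whole sequence so its first phrase begins at
    ``new_start_s``; order, durations, and internal gaps are preserved."""
    anns = sorted(
        (a for a in annotations if a.singer_id == singer_id), key=lambda a: a.begin_s
    )
    if not anns:
        raise ValidationError(f"no annotations for singer {singer_id!r}")
    delta = new_start_s - anns[0].begin_s
    return [replace(a, begin_s=a.begin_s + delta, end_s=a.end_s + delta) for a in anns]


def mc_overlap_test(
    focal_annotations: Sequence[PhraseAnnotation],
    second_annotations: Sequence[PhraseAnnotation],
    scenario: DyadScenario,
    *,
    before_start_s: float | None = None,
    min_co_fraction: float = MIN_CO_COVERAGE,
    max_redraws: int = MAX_REDRAWS,
    rng: np.random.Generator | None = None,
) -> MatchTestResult:
    """Monte Carlo time-shift test for phrase-type overlap in a dyad.

    Parameters
    ----------
    before_start_s
        Start of the BEFORE period in which null start times are drawn;
        defaults to ``scenario.onset_s - scenario.before_len_s``.  No
        wrap-around: the shifted sequence simply extends forward from the
        drawn start.
    min_co_fraction, max_redraws
        A null replicate whose shifted sequence co-covers fewer than
        ``min_co_fraction * grid length`` samples is redrawn up to
        ``max_redraws`` times, then recorded as missing.

    Results are reproducible for a given ``scenario.seed``.
    """
    if before_start_s is None:
        before_start_s = scenario.before_start_s
    if before_start_s >= scenario.onset_s:
        raise ValidationError("before period must precede the onset")
    ws, we = scenario.onset_s, scenario.during_end_s
    interval = scenario.grid_interval_s

    focal = sample_phrase_grid(focal_annotations, scenario.focal_id, ws, we, interval)
    second = sample_phrase_grid(second_annotations, scenario.second_id, ws, we, interval)
    observed, n_co = overlap_proportion(focal, second)

    # Fast path for the replicate loop: integer-coded labels on shared codes.
    f_begins, f_ends, f_labels = _intervals(focal_annotations, scenario.focal_id)
    s_begins, s_ends, s_labels = _intervals(second_annotations, scenario.second_id)
    vocab = {lab: i for i, lab in enumerate(sorted(set(f_labels) | set(s_labels)))}
    f_codes = np.array([vocab[l] for l in f_labels], dtype=np.int64)
    s_codes = np.array([vocab[l] for l in s_labels], dtype=np.int64)
    times = _grid_times(ws, we, interval)
    f_grid = _sample_codes(f_begins, f_ends, f_codes, times)
    f_ok = f_grid >= 0

    min_co = int(np.ceil(min_co_fraction * len(times)))
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    s_first = s_begins[0]

    nulls: list[float] = []
    n_missing = 0
    for _ in range(scenario.mc_reps):
        for _attempt in range(max_redraws + 1):
            start = rng.uniform(before_start_s, scenario.onset_s)
            delta = start - s_first
            s_grid = _sample_codes(s_begins + delta, s_ends + delta, s_codes, times)
            co = f_ok & (s_grid >= 0)
            n = int(co.sum())
            if n >= min_co:
                nulls.append(float((f_grid[co] == s_grid[co]).sum() / n))
                break
        else:
            n_missing += 1

    null = np.asarray(nulls, dtype=float)
    if len(null) == 0:
        raise UndefinedMetricError("every null replicate lacked co-coverage")
    p_right = (1 + int(np.sum(null >= observed - 1e-12))) / (1 + len(null))
    p_left = (1 + int(np.sum(null <= observed + 1e-12))) / (1 + len(null))
    return MatchTestResult(
        observed_overlap=observed,
        null_overlaps=null,
        p_right=p_right,
        p_left=p_left,
        n_co_samples=n_co,
        seed=scenario.seed,
        n_missing_reps=n_missing,
    )
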