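"""Readers and writers for phrase tables, singer tracks, solo-singer
endpoints, and scenario configs.

Formats
-------
Phrase table
    UTF-8 TSV with header ``singer_id  begin_s  end_s  phrase_type``.  On
    read, Raven selection-table headers ("Begin Time (s)", "End Time (s)"
    plus a named annotation column) are accepted and mapped onto the
    canonical columns.
Track file
    UTF-8 CSV with header ``singer_id,time_s,x_m,y_m``.
Solo endpoints
    UTF-8 CSV with header ``singer_id,start_x_m,start_y_m,end_x_m,end_y_m``.
Scenario config
    YAML (or JSON, a YAML subset) whose keys are exactly the
    :class:`~songdyad.types.DyadScenario` field names; unspecified keys take
    the study defaults.

Parsers never silently drop rows: every input row becomes an output record
or raises an error naming the offending row.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError, ValidationError
from .types import DyadScenario, PhraseAnnotation, SingerTrack

__all__ = [
    "read_phrase_table",
    "write_phrase_table",
    "read_track",
    "write_track",
    "read_solo_endpoints",
    "write_solo_endpoints",
    "load_scenario",
    "save_scenario",
]

# Raven selection-table header names accepted as synonyms on read.
_BEGIN_SYNONYMS = ("begin_s", "Begin Time (s)")
_END_SYNONYMS = ("end_s", "End Time (s)")
_SINGER_SYNONYMS = ("singer_id", "Singer", "singer")
_PHRASE_SYNONYMS = ("phrase_type", "Phrase Type", "Annotation", "Tags")


def _pick_column(columns: Sequence[str], synonyms: Sequence[str], what: str) -> str:
    for name in synonyms:
        if name in columns:
            return name
    raise FormatError(f"phrase table is missing a {what} column (one of {synonyms})")


def read_phrase_table(
    path: str | Path,
    *,
    phrase_column: str | None = None,
    default_singer: str | None = None,
) -> list[PhraseAnnotation]:
    """Read a phrase-annotation TSV (canonical or Raven dialect).

    Parameters
    ----------
    phrase_column
        Explicit name of the annotation column holding the phrase-type label
        (Raven tables name this freely).  Defaults to the first recognised
        synonym.
    default_singer
        Singer id assigned to every row when the table has no singer column
        (Raven tables are usually per-singer files).

    Returns annotations sorted by ``(singer_id, begin_s)``.  Overlapping
    phrases from the same singer are rejected: song is a non-overlapping
    phrase sequence.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    begin_col = _pick_column(cols, _BEGIN_SYNONYMS, "begin-time")
    end_col = _pick_column(cols, _END_SYNONYMS, "end-time")
    if phrase_column is not None:
        if phrase_column not in cols:
            raise FormatError(f"phrase table is missing column {phrase_column!r}")
        phrase_col = phrase_column
    else:
        phrase_col = _pick_column(cols, _PHRASE_SYNONYMS, "phrase-type")
    singer_col = next((c for c in _SINGER_SYNONYMS if c in cols), None)
    if singer_col is None and default_singer is None:
        raise FormatError(
            "phrase table is missing a singer_id column and no default_singer given"
        )

    annotations: list[PhraseAnnotation] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rec = dict(zip(cols, row))
        singer = str(rec[singer_col]) if singer_col else str(default_singer)
        try:
            begin = float(rec[begin_col])
            end = float(rec[end_col])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"row {i}: non-numeric time value") from exc
        phrase = rec[phrase_col]
        if phrase is None or (isinstance(phrase, float) and math.isnan(phrase)):
            raise ValidationError(f"row {i}: empty phrase type")
        try:
            annotations.append(PhraseAnnotation(singer, begin, end, str(phrase)))
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from exc

    annotations.sort(key=lambda a: (a.singer_id, a.begin_s, a.end_s))
    for prev, cur in zip(annotations, annotations[1:]):
        if cur.singer_id == prev.singer_id and cur.begin_s < prev.end_s - 1e-9:
            raise ValidationError(
                f"overlapping phrases for singer {cur.singer_id!r}: "
                f"[{prev.begin_s}, {prev.end_s}) and [{cur.begin_s}, {cur.end_s})"
            )
    return annotations


def write_phrase_table(annotations: Sequence[PhraseAnnotation], path: str | Path) -> None:
    """Write annotations as a canonical TSV (times at millisecond precision)."""
    df = pd.DataFrame(
        {
            "singer_id": [a.singer_id for a in annotations],
            "begin_s": [f"{a.begin_s:.3f}" for a in annotations],
            "end_s": [f"{a.end_s:.3f}" for a in annotations],
            "phrase_type": [a.phrase_type for a in annotations],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_track(path: str | Path, singer_id: str | None = None) -> SingerTrack:
    """Read one singer's track from a ``singer_id,time_s,x_m,y_m`` CSV.

    If the file holds several singers, ``singer_id`` selects one; a file with
    exactly one singer needs no selector.  Duplicate timestamps for a singer
    are rejected.
    """
    df = pd.read_csv(path)
    for col in ("singer_id", "time_s", "x_m", "y_m"):
        if col not in df.columns:
            raise FormatError(f"track file is missing column {col!r}")
    ids = df["singer_id"].astype(str).unique()
    if singer_id is None:
        if len(ids) != 1:
            raise FormatError(
                f"track file holds singers {sorted(ids)}; pass singer_id to select one"
            )
        singer_id = str(ids[0])
    sub = df[df["singer_id"].astype(str) == singer_id]
    if sub.empty:
        raise FormatError(f"no rows for singer {singer_id!r}")
    sub = sub.sort_values("time_s", kind="stable")
    t = sub["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) == 0):
        raise ValidationError(f"duplicate timestamp in track for singer {singer_id!r}")
    return SingerTrack(
        singer_id, t, sub["x_m"].to_numpy(dtype=float), sub["y_m"].to_numpy(dtype=float)
    )


def write_track(track: SingerTrack, path: str | Path, *, mode: str = "w") -> None:
    df = pd.DataFrame(
        {
            "singer_id": track.singer_id,
            "time_s": track.times_s,
            "x_m": track.x_m,
            "y_m": track.y_m,
        }
    )
    df.to_csv(path, index=False, mode=mode, header=(mode == "w"), float_format="%.3f")


SoloEndpoint = tuple[str, tuple[float, float], tuple[float, float]]


def read_solo_endpoints(path: str | Path) -> list[SoloEndpoint]:
    """Read solo-singer start/end positions (one row per singer)."""
    df = pd.read_csv(path)
    required = ("singer_id", "start_x_m", "start_y_m", "end_x_m", "end_y_m")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"endpoints file is missing column {col!r}")
    out: list[SoloEndpoint] = []
    for row in df.itertuples(index=False):
        out.append(
            (
                str(row.singer_id),
                (float(row.start_x_m), float(row.start_y_m)),
                (float(row.end_x_m), float(row.end_y_m)),
            )
        )
    return out


def write_solo_endpoints(endpoints: Sequence[SoloEndpoint], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "singer_id": sid,
                "start_x_m": s[0],
                "start_y_m": s[1],
                "end_x_m": e[0],
                "end_y_m": e[1],
            }
            for sid, s, e in endpoints
        ],
        columns=["singer_id", "start_x_m", "start_y_m", "end_x_m", "end_y_m"],
    )
    df.to_csv(path, index=False, float_format="%.3f")


def load_scenario(path: str | Path) -> DyadScenario:
    """Load a dyad scenario from YAML or JSON.

    Unknown keys raise :class:`ConfigError`; unspecified keys take the study
    defaults (45-min periods, 15-min windows, 8-s grid, 1000 reps).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"scenario config {path} must be a mapping")
    return scenario_from_dict(raw)


def scenario_from_dict(raw: dict) -> DyadScenario:
    allowed = set(DyadScenario.field_names())
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
    missing = {"focal_id", "second_id", "onset_s"} - set(raw)
    if missing:
        raise ConfigError(f"scenario config missing required keys: {sorted(missing)}")
    return DyadScenario(**raw)


def save_scenario(scenario: DyadScenario, path: str | Path) -> None:
    data = {name: getattr(scenario, name) for name in DyadScenario.field_names()}
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
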