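"""Study orchestration: run every analysis for a set of dyads plus a solo
population and emit the report tables.

The report mirrors the study's structure:

``table1``
    Per-dyad and pooled switching rate / evenness for focal (BEFORE vs
    DURING) and second (DURING) singers, with paired t-tests on
    arcsine-transformed values.
``table2``
    Per-dyad phrase-type overlap vs its Monte Carlo null.
``spatial``
    Per-dyad start/end separations and change in distance, tested against
    the solo pairwise null with two-sample K-S tests.
``quit_analysis``
    Mann-Whitney U on change in distance, grouped by whether both singers
    kept singing or one quit.
``meander``
    Per-singer meander ratios, with a Wilcoxon signed-rank test (focal
    BEFORE vs DURING) and a Mann-Whitney U (focal vs second, DURING).

A dyad that fails a stage is excluded from that table with a logged reason
and the run continues; every input dyad appears either in each applicable
table or in the exclusion list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import matching, movement, song_metrics
from .errors import SongDyadError
from .io import SoloEndpoint
from .song_metrics import BEFORE, DURING
from .stats import (
    TestResult,
    arcsine_sqrt,
    ks_two_sample,
    mann_whitney_u,
    paired_t,
    wilcoxon_signed_rank,
)
from .types import DyadScenario, PhraseAnnotation, SingerTrack

__all__ = [
    "DyadInputs",
    "StudyReport",
    "classify_dyad_outcome",
    "run_study",
    "BOTH_CONTINUED",
    "FOCAL_QUIT",
    "SECOND_QUIT",
]

BOTH_CONTINUED = "both_continued"
FOCAL_QUIT = "focal_quit"
SECOND_QUIT = "second_quit"

#: A singer "quit" if his last phrase ends more than this long before the
#: DURING window's end (separates surfacing gaps from cessation).
QUIT_TOLERANCE_S = 120.0

#: A singer who quit before this fraction of the DURING period is excluded
#: from the song-pattern tables.
SONG_PATTERN_MIN_FRACTION = 0.5


@dataclass(frozen=True)
class DyadInputs:
    """One dyad's data and configuration as fed to :func:`run_study`."""

    dyad_id: str
    scenario: DyadScenario
    annotations: tuple[PhraseAnnotation, ...]
    tracks: dict[str, SingerTrack]
    before_start_s: float | None = None  # actual solo-recording start
    exclude_matching: bool = False  # manual poor-quality flag

    @property
    def actual_before_start_s(self) -> float:
        if self.before_start_s is not None:
            return self.before_start_s
        return self.scenario.before_start_s


@dataclass
class StudyReport:
    table1: pd.DataFrame
    table2: pd.DataFrame
    spatial: pd.DataFrame
    quit_analysis: pd.DataFrame
    meander: pd.DataFrame
    tests: dict[str, TestResult]
    exclusions: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def _last_sung_end(annotations: Sequence[PhraseAnnotation], singer_id: str) -> float:
    ends = [a.end_s for a in annotations if a.singer_id == singer_id]
    if not ends:
        raise SongDyadError(f"no annotations for singer {singer_id!r}")
    return max(ends)


def classify_dyad_outcome(
    focal_annotations: Sequence[PhraseAnnotation],
    second_annotations: Sequence[PhraseAnnotation],
    scenario: DyadScenario,
    quit_tolerance_s: float = QUIT_TOLERANCE_S,
) -> str:
    """Did both singers keep singing through DURING, or did one quit?

    A singer quit if his last phrase ends more than ``quit_tolerance_s``
    before the DURING window's end.  A quitting focal takes precedence in
    the label.
    """
    end = scenario.during_end_s
    focal_quit = _last_sung_end(focal_annotations, scenario.focal_id) < end - quit_tolerance_s
    second_quit = _last_sung_end(second_annotations, scenario.second_id) < end - quit_tolerance_s
    if focal_quit:
        return FOCAL_QUIT
    if second_quit:
        return SECOND_QUIT
    return BOTH_CONTINUED


def _sung_fraction(
    annotations: Sequence[PhraseAnnotation], singer_id: str, scenario: DyadScenario
) -> float:
    last = _last_sung_end(annotations, singer_id)
    return min(1.0, (last - scenario.onset_s) / scenario.during_len_s)


def run_study(
    dyads: Sequence[DyadInputs],
    solo_endpoints: Sequence[SoloEndpoint],
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Run the full analysis for every dyad and write the report tables.

    Deterministic for fixed inputs: every Monte Carlo stage is seeded from
    its dyad's scenario.  With ``out_dir`` set, all tables are written as
    TSV plus a JSON manifest of parameters, seeds, and exclusions.
    """
    if not dyads:
        raise SongDyadError("need at least one dyad")
    exclusions: list[dict] = []
    t1_rows: list[dict] = []
    t2_rows: list[dict] = []
    sp_rows: list[dict] = []
    me_rows: list[dict] = []
    tests: dict[str, TestResult] = {}

    null = movement.solo_pairwise_null(solo_endpoints)

    for d in dyads:
        sc = d.scenario
        anns = list(d.annotations)
        outcome = classify_dyad_outcome(anns, anns, sc)
        focal_frac = _sung_fraction(anns, sc.focal_id, sc)
        second_frac = _sung_fraction(anns, sc.second_id, sc)

        # --- song-pattern metrics (Table 1) -----------------------------
        if focal_frac < SONG_PATTERN_MIN_FRACTION:
            exclusions.append(
                {
                    "dyad_id": d.dyad_id,
                    "table": "table1",
                    "reason": f"focal quit after {focal_frac:.0%} of DURING",
                }
            )
        else:
            try:
                windows = song_metrics.segment_windows(sc, d.actual_before_start_s)
                bwins = [w for w in windows if w.period_label == BEFORE]
                dwins = [w for w in windows if w.period_label == DURING]
                focal_rep = song_metrics.observed_repertoire(anns, sc.focal_id)
                second_rep = sorted(
                    {
                        a.phrase_type
                        for a in anns
                        if a.singer_id == sc.second_id and a.begin_s >= sc.onset_s
                    }
                )
                fb = song_metrics.period_metrics(anns, sc.focal_id, bwins, focal_rep)
                fd = song_metrics.period_metrics(anns, sc.focal_id, dwins, focal_rep)
                row = {
                    "dyad_id": d.dyad_id,
                    "focal_id": sc.focal_id,
                    "second_id": sc.second_id,
                    "focal_sr_before": fb.mean_switching_rate,
                    "focal_sr_during": fd.mean_switching_rate,
                    "focal_j_before": fb.mean_evenness,
                    "focal_j_during": fd.mean_evenness,
                    "second_sr_during": None,
                    "second_j_during": None,
                }
                if second_frac >= SONG_PATTERN_MIN_FRACTION and not d.exclude_matching:
                    sd = song_metrics.period_metrics(anns, sc.second_id, dwins, second_rep)
                    row["second_sr_during"] = sd.mean_switching_rate
                    row["second_j_during"] = sd.mean_evenness
                else:
                    exclusions.append(
                        {
                            "dyad_id": d.dyad_id,
                            "table": "table1_second",
                            "reason": "second singer quit early or flagged unreliable",
                        }
                    )
                t1_rows.append(row)
            except SongDyadError as exc:
                exclusions.append(
                    {"dyad_id": d.dyad_id, "table": "table1", "reason": str(exc)}
                )

        # --- matching (Table 2) ------------------------------------------
        if d.exclude_matching:
            exclusions.append(
                {
                    "dyad_id": d.dyad_id,
                    "table": "table2",
                    "reason": "flagged: unreliable phrase delineation",
                }
            )
        elif focal_frac < SONG_PATTERN_MIN_FRACTION or second_frac < SONG_PATTERN_MIN_FRACTION:
            exclusions.append(
                {
                    "dyad_id": d.dyad_id,
                    "table": "table2",
                    "reason": "a singer quit before half of DURING",
                }
            )
        else:
            try:
                res = matching.mc_overlap_test(
                    anns, anns, sc, before_start_s=d.actual_before_start_s
                )
                t2_rows.append(
                    {
                        "dyad_id": d.dyad_id,
                        "mean_expected_overlap": res.mean_expected_overlap,
                        "observed_overlap": res.observed_overlap,
                        "p_right": res.p_right,
                        "p_left": res.p_left,
                        "n_reps_used": len(res.null_overlaps),
                        "seed": res.seed,
                    }
                )
            except SongDyadError as exc:
                exclusions.append(
                    {"dyad_id": d.dyad_id, "table": "table2", "reason": str(exc)}
                )

        # --- spatial and meander ------------------------------------------
        try:
            ta = d.tracks[sc.focal_id]
            tb = d.tracks[sc.second_id]
            pair = movement.dyad_spatial(ta, tb, sc.onset_s, sc.during_end_s)
            sp_rows.append(
                {
                    "dyad_id": d.dyad_id,
                    "start_sep_m": pair.start_sep_m,
                    "end_sep_m": pair.end_sep_m,
                    "delta_m": pair.delta_m,
                    "outcome": outcome,
                }
            )
        except (SongDyadError, KeyError) as exc:
            exclusions.append(
                {"dyad_id": d.dyad_id, "table": "spatial", "reason": str(exc)}
            )
        try:
            ta = d.tracks[sc.focal_id]
            tb = d.tracks[sc.second_id]
            mb = movement.meander_ratio(
                ta, sc.onset_s - sc.before_len_s, sc.onset_s, period_label=BEFORE
            )
            mdur = movement.meander_ratio(
                ta, sc.onset_s, sc.during_end_s, period_label=DURING
            )
            m2 = movement.meander_ratio(
                tb, sc.onset_s, sc.during_end_s, period_label=DURING
            )
            for role, m in (("focal", mb), ("focal", mdur), ("second", m2)):
                me_rows.append(
                    {
                        "dyad_id": d.dyad_id,
                        "singer_id": m.singer_id,
                        "role": role,
                        "period": m.period_label,
                        "path_m": m.path_m,
                        "chord_m": m.chord_m,
                        "ratio": m.ratio,
                    }
                )
        except (SongDyadError, KeyError) as exc:
            exclusions.append(
                {"dyad_id": d.dyad_id, "table": "meander", "reason": str(exc)}
            )

    table1 = pd.DataFrame(t1_rows)
    table2 = pd.DataFrame(t2_rows)
    spatial = pd.DataFrame(sp_rows)
    meander = pd.DataFrame(me_rows)

    # --- pooled tests ------------------------------------------------------
    if len(table1) >= 3:
        for metric, col_b, col_d in (
            ("sr", "focal_sr_before", "focal_sr_during"),
            ("j", "focal_j_before", "focal_j_during"),
        ):
            sub = table1.dropna(subset=[col_b, col_d])
            if len(sub) >= 3:
                tests[f"focal_{metric}_before_vs_during"] = paired_t(
                    [arcsine_sqrt(v) for v in sub[col_b]],
                    [arcsine_sqrt(v) for v in sub[col_d]],
                    direction="greater",
                )
        for metric, col_f, col_s in (
            ("sr", "focal_sr_during", "second_sr_during"),
            ("j", "focal_j_during", "second_j_during"),
        ):
            sub = table1.dropna(subset=[col_f, col_s])
            if len(sub) >= 3:
                tests[f"focal_vs_second_{metric}_during"] = paired_t(
                    [arcsine_sqrt(v) for v in sub[col_f]],
                    [arcsine_sqrt(v) for v in sub[col_s]],
                    direction="less",
                )

    if len(spatial) >= 2:
        tests["start_sep_vs_null"] = ks_two_sample(spatial["start_sep_m"], null.start_seps)
        tests["end_sep_vs_null"] = ks_two_sample(spatial["end_sep_m"], null.end_seps)
        tests["delta_vs_null"] = ks_two_sample(spatial["delta_m"], null.deltas)

    quit_rows = []
    if not spatial.empty:
        quit_deltas = spatial.loc[spatial["outcome"] != BOTH_CONTINUED, "delta_m"]
        cont_deltas = spatial.loc[spatial["outcome"] == BOTH_CONTINUED, "delta_m"]
        quit_rows = [
            {"group": "quit", "n": len(quit_deltas), "mean_delta_m": quit_deltas.mean()},
            {
                "group": "both_continued",
                "n": len(cont_deltas),
                "mean_delta_m": cont_deltas.mean(),
            },
        ]
        if len(quit_deltas) >= 1 and len(cont_deltas) >= 1 and len(spatial) >= 4:
            tests["delta_quit_vs_continued"] = mann_whitney_u(
                quit_deltas.to_numpy(), cont_deltas.to_numpy(), direction="less"
            )
    quit_analysis = pd.DataFrame(quit_rows)

    if not meander.empty:
        fb = meander.query("role == 'focal' and period == @BEFORE").set_index("dyad_id")["ratio"]
        fd = meander.query("role == 'focal' and period == @DURING").set_index("dyad_id")["ratio"]
        common = fb.dropna().index.intersection(fd.dropna().index)
        if len(common) >= 5:
            try:
                tests["focal_meander_before_vs_during"] = wilcoxon_signed_rank(
                    fb.loc[common].to_numpy(), fd.loc[common].to_numpy()
                )
            except SongDyadError:
                pass
        s2 = meander.query("role == 'second'")["ratio"].dropna()
        fd_all = fd.dropna()
        if len(s2) >= 2 and len(fd_all) >= 2 and len(s2) + len(fd_all) >= 4:
            try:
                tests["meander_focal_vs_second_during"] = mann_whitney_u(
                    fd_all.to_numpy(), s2.to_numpy(), direction="greater"
                )
            except SongDyadError:
                pass

    manifest = {
        "n_dyads": len(dyads),
        "n_solo_singers": null.n_singers,
        "n_null_pairs": null.n_pairs,
        "seeds": {d.dyad_id: d.scenario.seed for d in dyads},
        "scenarios": {
            d.dyad_id: {k: getattr(d.scenario, k) for k in DyadScenario.field_names()}
            for d in dyads
        },
        "exclusions": exclusions,
        "tests": {
            name: {
                "statistic": t.statistic,
                "p_two": t.p_two,
                "p_one": t.p_one,
                "n": list(t.n),
                "direction": t.direction,
            }
            for name, t in tests.items()
        },
    }
    report = StudyReport(
        table1=table1,
        table2=table2,
        spatial=spatial,
        quit_analysis=quit_analysis,
        meander=meander,
        tests=tests,
        exclusions=pd.DataFrame(exclusions, columns=["dyad_id", "table", "reason"]),
        manifest=manifest,
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _write_report(report: StudyReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("table1", "table2", "spatial", "quit_analysis", "meander", "exclusions"):
        df = getattr(report, name)
        df.to_csv(out_dir / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(report.manifest, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
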