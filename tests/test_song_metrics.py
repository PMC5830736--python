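"""Window tiling, switching rate, and relative song evenness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songdyad import simulate, song_metrics
from songdyad.errors import UndefinedMetricError, ValidationError
from songdyad.song_metrics import (
    BEFORE,
    DURING,
    WindowSpec,
    period_metrics,
    phrase_sequence_in_window,
    segment_windows,
    song_evenness,
    switching_rate,
    window_metrics,
)
from songdyad.types import DyadScenario, PhraseAnnotation


class TestSegmentWindows:
    def test_full_ninety_minutes_tiles_three_plus_three(self, scenario):
        windows = segment_windows(scenario, actual_before_start_s=0.0)
        before = [(w.start_s, w.end_s) for w in windows if w.period_label == BEFORE]
        during = [(w.start_s, w.end_s) for w in windows if w.period_label == DURING]
        assert before == [(0.0, 900.0), (900.0, 1800.0), (1800.0, 2700.0)]
        assert during == [(2700.0, 3600.0), (3600.0, 4500.0), (4500.0, 5400.0)]

    def test_short_before_drops_sub_threshold_partial(self, scenario):
        # solo recording starts 35.3 min before onset: two full windows fit,
        # the leading 318-s remainder is below the 600-s minimum.
        windows = segment_windows(scenario, actual_before_start_s=582.0)
        before = [(w.start_s, w.end_s) for w in windows if w.period_label == BEFORE]
        assert before == [(900.0, 1800.0), (1800.0, 2700.0)]

    def test_long_enough_partial_is_kept(self, scenario):
        windows = segment_windows(scenario, actual_before_start_s=250.0)
        before = [(w.start_s, w.end_s) for w in windows if w.period_label == BEFORE]
        assert before[0] == (250.0, 900.0)  # 650 s >= 600 s threshold
        assert len(before) == 3

    def test_window_equal_to_period_gives_one_during_window(self):
        sc = DyadScenario("F", "S", onset_s=2700.0, window_len_s=2700.0)
        windows = segment_windows(sc, 0.0)
        assert [w.period_label for w in windows] == [BEFORE, DURING]

    def test_insufficient_before_period_errors(self, scenario):
        with pytest.raises(ValidationError, match="insufficient before period"):
            segment_windows(scenario, actual_before_start_s=2400.0)

    def test_indices_are_ordinal_within_period(self, scenario):
        windows = segment_windows(scenario, 0.0)
        for label in (BEFORE, DURING):
            idx = [w.index for w in windows if w.period_label == label]
            assert idx == [0, 1, 2]


class TestPhraseSequenceInWindow:
    @pytest.mark.parametrize(
        "begin,end,expected", [(890.0, 920.0, []), (880.0, 910.0, ["A"])]
    )
    def test_midpoint_rule_at_boundary(self, begin, end, expected):
        w = WindowSpec(0.0, 900.0, BEFORE, 0)
        anns = [PhraseAnnotation("F", begin, end, "A")]
        assert phrase_sequence_in_window(anns, "F", w) == expected

    def test_counts_match_brute_force_midpoint_filter(self, rng, scenario):
        anns = simulate.simulate_song(
            simulate.SongGenParams(seed=7), 5400.0, singer_id="F"
        )
        windows = segment_windows(scenario, 0.0)
        total = sum(len(phrase_sequence_in_window(anns, "F", w)) for w in windows)
        span_lo = min(w.start_s for w in windows)
        span_hi = max(w.end_s for w in windows)
        brute = sum(1 for a in anns if span_lo <= a.midpoint_s < span_hi)
        assert total == brute

    def test_other_singers_ignored(self, simple_annotations):
        w = WindowSpec(0.0, 900.0, BEFORE, 0)
        assert phrase_sequence_in_window(simple_annotations, "S", w) == []


class TestSwitchingRate:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            (list("AAABBC"), 0.4),
            (list("AAAA"), 0.0),
            (list("ABCD"), 1.0),
            (list("AB"), 1.0),
        ],
    )
    def test_hand_counted_examples(self, seq, expected):
        assert switching_rate(seq) == pytest.approx(expected)

    def test_undefined_below_two_phrases(self):
        for seq in ([], ["A"]):
            with pytest.raises(UndefinedMetricError):
                switching_rate(seq)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from("ABCDE"), min_size=2, max_size=100))
    def test_matches_brute_force_adjacent_count(self, seq):
        brute = sum(1 for i in range(len(seq) - 1) if seq[i] != seq[i + 1])
        assert switching_rate(seq) == pytest.approx(brute / (len(seq) - 1))
        assert 0.0 <= switching_rate(seq) <= 1.0

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.sampled_from("ABCDE"), min_size=2, max_size=50))
    def test_invariant_to_relabeling(self, seq):
        relabeled = [chr(ord(c) + 10) for c in seq]
        assert switching_rate(relabeled) == switching_rate(seq)


class TestSongEvenness:
    def test_complete_evenness_scores_one(self):
        assert song_evenness(["A"] * 5 + ["B"] * 5, "AB") == pytest.approx(1.0)

    def test_nine_one_split(self):
        assert song_evenness(["A"] * 9 + ["B"], "AB") == pytest.approx(0.4690, abs=1e-3)

    def test_single_type_scores_zero(self):
        assert song_evenness(["A"] * 10, "AB") == pytest.approx(0.0)

    def test_unsung_repertoire_types_lower_evenness(self):
        even = song_evenness(list("AABB"), "AB")
        padded = song_evenness(list("AABB"), "ABC")
        assert padded < even

    def test_repertoire_below_two_undefined(self):
        with pytest.raises(UndefinedMetricError):
            song_evenness(["A", "A"], "A")

    def test_element_outside_repertoire_rejected(self):
        with pytest.raises(ValidationError):
            song_evenness(["A", "Z"], "AB")

    def test_empty_sequence_undefined(self):
        with pytest.raises(UndefinedMetricError):
            song_evenness([], "AB")

    def test_label_permutation_invariance(self, rng):
        seq = list(rng.choice(list("ABCD"), size=60))
        swapped = [{"A": "B", "B": "A", "C": "D", "D": "C"}[c] for c in seq]
        assert song_evenness(swapped, "ABCD") == pytest.approx(
            song_evenness(seq, "ABCD")
        )

    def test_majorization_moving_mass_to_common_type_decreases_j(self):
        # Moving one phrase from the rarer to the more common category must
        # strictly lower evenness.
        prev = song_evenness(["A"] * 5 + ["B"] * 5, "AB")
        for a in range(6, 10):
            cur = song_evenness(["A"] * a + ["B"] * (10 - a), "AB")
            assert cur < prev
            prev = cur

    def test_log_base_cancels(self):
        # J' from base-2 entropy equals the natural-log implementation.
        seq = list("AAABBC")
        k = 3
        counts = {c: seq.count(c) for c in "ABC"}
        h2 = -sum(
            (v / 6) * math.log2(v / 6) for v in counts.values() if v
        ) / math.log2(k)
        assert song_evenness(seq, "ABC") == pytest.approx(h2)


class TestPeriodMetrics:
    def _windows(self, n=3):
        return [WindowSpec(900.0 * i, 900.0 * (i + 1), BEFORE, i) for i in range(n)]

    def test_mean_over_defined_windows(self):
        anns = []
        seqs = [list("AAAAAAAAAB"), list("AAAAAAAAAB"), list("ABABABABAB")]
        for wi, seq in enumerate(seqs):  # SRs 1/9, 1/9, 1
            for i, label in enumerate(seq):
                t = 900.0 * wi + 10.0 * i
                anns.append(PhraseAnnotation("F", t, t + 10.0, label))
        pm = period_metrics(anns, "F", self._windows(), "AB")
        assert pm.mean_switching_rate == pytest.approx((1 / 9 + 1 / 9 + 1.0) / 3)

    def test_single_defined_window_is_the_mean(self):
        anns = [
            PhraseAnnotation("F", 0.0, 10.0, "A"),
            PhraseAnnotation("F", 10.0, 20.0, "B"),
        ]
        pm = period_metrics(anns, "F", self._windows(), "AB")
        assert pm.mean_switching_rate == pytest.approx(1.0)
        undefined = [w for w in pm.windows if w.switching_rate is None]
        assert len(undefined) == 2  # recorded but excluded from the mean

    def test_all_windows_undefined_errors(self):
        with pytest.raises(UndefinedMetricError):
            period_metrics([], "F", self._windows(), "AB")

    def test_generator_switching_rate_recovered(self):
        # ~80 phrases per 15-min window at a 10-s phrase scale; the realized
        # per-period mean SR should recover the generator's target.
        vals = []
        for seed in range(10):
            params = simulate.SongGenParams(
                switch_prob=0.15,
                phrase_dur_mean_s=11.0,
                phrase_dur_sd_s=2.0,
                gap_prob=0.0,
                seed=seed,
            )
            anns = simulate.simulate_song(params, 2700.0, singer_id="F")
            pm = period_metrics(anns, "F", self._windows(), simulate.DEFAULT_REPERTOIRE)
            vals.append(pm.mean_switching_rate)
        assert np.mean(vals) == pytest.approx(0.15, abs=0.05)


def test_window_metrics_proportions_sum_to_one(simple_annotations):
    w = WindowSpec(0.0, 900.0, BEFORE, 0)
    m = window_metrics(simple_annotations, "F", w, "AB")
    assert sum(m.phrase_proportions.values()) == pytest.approx(1.0)
    assert m.n_phrases == 3 and m.n_transitions == 1
    assert m.n_transitions <= m.n_phrases - 1
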