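"""Track interpolation, separation distances, meander ratio, and the
pairwise solo-singer spatial null."""

import itertools
import math

import numpy as np
import pytest

from songdyad.errors import CoverageError, ValidationError
from songdyad.movement import (
    dyad_spatial,
    interpolate_track,
    meander_ratio,
    position_at,
    separation,
    solo_pairwise_null,
)
from songdyad.types import SingerTrack


def _track(sid, pts):
    t, x, y = zip(*pts)
    return SingerTrack(sid, np.array(t, float), np.array(x, float), np.array(y, float))


class TestInterpolateTrack:
    def test_midpoint_of_linear_motion(self):
        track = _track("F", [(0, 0, 0), (300, 300, 0)])
        out = interpolate_track(track, 150.0)
        assert list(out.times_s) == [0.0, 150.0, 300.0]
        assert out.x_m[1] == pytest.approx(150.0) and out.y_m[1] == 0.0

    def test_grid_equal_to_samples_is_identity(self):
        track = _track("F", [(0, 0, 0), (150, 10, 5), (300, -5, 20)])
        assert interpolate_track(track, 150.0) == track

    def test_idempotent_on_own_grid(self):
        track = _track("F", [(0, 0, 0), (100, 40, 10), (390, 80, -30)])
        once = interpolate_track(track, 150.0)
        assert interpolate_track(once, 150.0) == once

    def test_no_extrapolation(self):
        track = _track("F", [(0, 0, 0), (400, 100, 0)])
        out = interpolate_track(track, 150.0)
        assert out.times_s[-1] <= 400.0

    def test_points_lie_on_segments(self, rng):
        # Geometric oracle: every interpolated point has zero distance to
        # some original segment.
        t = np.cumsum(rng.uniform(30, 200, 20))
        track = SingerTrack(
            "F", t, rng.uniform(-1000, 1000, 20), rng.uniform(-1000, 1000, 20)
        )
        out = interpolate_track(track, 77.0)
        for ti, xi, yi in zip(out.times_s, out.x_m, out.y_m):
            d = min(
                _point_segment_distance(
                    (xi, yi),
                    (track.x_m[i], track.y_m[i]),
                    (track.x_m[i + 1], track.y_m[i + 1]),
                )
                for i in range(len(track) - 1)
                if track.times_s[i] - 1e-9 <= ti <= track.times_s[i + 1] + 1e-9
            )
            assert d == pytest.approx(0.0, abs=1e-6)

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            interpolate_track(_track("F", [(0, 0, 0)]))


def _point_segment_distance(p, a, b):
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    denom = float(ab @ ab)
    u = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0, 1))
    return float(np.linalg.norm(p - (a + u * ab)))


class TestSeparation:
    def test_three_four_five(self):
        a = _track("a", [(0, 0, 0), (100, 0, 0)])
        b = _track("b", [(0, 3, 4), (100, 3, 4)])
        assert separation(a, b, 50.0) == pytest.approx(5.0)

    def test_identical_positions(self):
        a = _track("a", [(0, 7, 7), (100, 7, 7)])
        assert separation(a, a, 30.0) == 0.0

    def test_outside_span_errors(self):
        a = _track("a", [(0, 0, 0), (100, 0, 0)])
        with pytest.raises(CoverageError):
            position_at(a, 500.0)

    def test_matches_brute_force_distance(self, rng):
        t = np.arange(0.0, 2000.0, 100.0)
        a = SingerTrack("a", t, rng.uniform(-500, 500, len(t)), rng.uniform(-500, 500, len(t)))
        b = SingerTrack("b", t, rng.uniform(-500, 500, len(t)), rng.uniform(-500, 500, len(t)))
        for ts in rng.uniform(0, 1900, 20):
            xa = np.interp(ts, a.times_s, a.x_m)
            ya = np.interp(ts, a.times_s, a.y_m)
            xb = np.interp(ts, b.times_s, b.x_m)
            yb = np.interp(ts, b.times_s, b.y_m)
            assert separation(a, b, ts) == pytest.approx(math.hypot(xa - xb, ya - yb))


class TestDyadSpatial:
    def test_stationary_pair_delta_zero(self):
        a = _track("a", [(0, 0, 0), (2700, 0, 0)])
        b = _track("b", [(0, 1000, 0), (2700, 1000, 0)])
        pair = dyad_spatial(a, b, 0.0, 2700.0)
        assert pair.delta_m == 0.0

    def test_approach_is_negative(self):
        a = _track("a", [(0, 0, 0), (2700, 0, 0)])
        b = _track("b", [(0, 2000, 0), (2700, 500, 0)])
        pair = dyad_spatial(a, b, 0.0, 2700.0)
        assert pair.start_sep_m == pytest.approx(2000.0)
        assert pair.end_sep_m == pytest.approx(500.0)
        assert pair.delta_m == pytest.approx(-1500.0)

    def test_symmetric_swap_gives_zero_delta(self):
        a = _track("a", [(0, 0, 0), (2700, 1000, 0)])
        b = _track("b", [(0, 1000, 0), (2700, 0, 0)])
        assert dyad_spatial(a, b, 0.0, 2700.0).delta_m == pytest.approx(0.0)

    def test_symmetry_in_arguments(self, rng):
        t = np.arange(0.0, 2701.0, 300.0)
        a = SingerTrack("a", t, rng.uniform(0, 5000, len(t)), rng.uniform(0, 3000, len(t)))
        b = SingerTrack("b", t, rng.uniform(0, 5000, len(t)), rng.uniform(0, 3000, len(t)))
        pab = dyad_spatial(a, b, 0.0, 2700.0)
        pba = dyad_spatial(b, a, 0.0, 2700.0)
        assert (pab.start_sep_m, pab.end_sep_m, pab.delta_m) == (
            pba.start_sep_m,
            pba.end_sep_m,
            pba.delta_m,
        )

    def test_endpoint_tolerance_snaps_to_nearest_cover(self):
        # Track starts 200 s into the window: within the 300-s tolerance.
        a = _track("a", [(200, 0, 0), (2700, 0, 0)])
        b = _track("b", [(0, 500, 0), (2700, 500, 0)])
        assert dyad_spatial(a, b, 0.0, 2700.0).start_sep_m == pytest.approx(500.0)

    def test_gap_beyond_tolerance_errors(self):
        a = _track("a", [(400, 0, 0), (2700, 0, 0)])
        b = _track("b", [(0, 500, 0), (2700, 500, 0)])
        with pytest.raises(CoverageError, match="'a'"):
            dyad_spatial(a, b, 0.0, 2700.0)


class TestMeanderRatio:
    def test_straight_line_is_one(self, straight_track):
        m = meander_ratio(straight_track, 0.0, 2700.0)
        assert m.ratio == pytest.approx(1.0)
        assert m.path_m == pytest.approx(m.chord_m)

    def test_l_shaped_path(self):
        track = _track("F", [(0, 0, 0), (300, 300, 0), (600, 300, 400)])
        m = meander_ratio(track, 0.0, 600.0)
        assert m.path_m == pytest.approx(700.0)
        assert m.chord_m == pytest.approx(500.0)
        assert m.ratio == pytest.approx(1.4)

    def test_return_to_start_undefined(self):
        track = _track("F", [(0, 0, 0), (300, 400, 0), (600, 0, 0)])
        m = meander_ratio(track, 0.0, 600.0)
        assert m.ratio is None and m.chord_m < 1.0

    def test_window_shorter_than_bin_errors(self, straight_track):
        with pytest.raises(ValidationError):
            meander_ratio(straight_track, 0.0, 200.0)

    def test_path_at_least_chord(self, rng):
        for _ in range(20):
            t = np.arange(0.0, 2701.0, 150.0)
            track = SingerTrack(
                "F", t, np.cumsum(rng.normal(0, 60, len(t))), np.cumsum(rng.normal(0, 60, len(t)))
            )
            m = meander_ratio(track, 0.0, 2700.0)
            assert m.path_m >= m.chord_m - 1e-9
            if m.ratio is not None:
                assert m.ratio >= 1.0 - 1e-12


class TestSoloPairwiseNull:
    def _endpoints(self, rng, n):
        return [
            (
                f"s{i}",
                (float(rng.uniform(0, 6000)), float(rng.uniform(0, 3000))),
                (float(rng.uniform(0, 6000)), float(rng.uniform(0, 3000))),
            )
            for i in range(n)
        ]

    def test_eighteen_singers_give_153_pairs(self, rng):
        null = solo_pairwise_null(self._endpoints(rng, 18))
        assert null.n_pairs == 153 and null.n_singers == 18

    def test_two_singers_one_pair(self, rng):
        assert solo_pairwise_null(self._endpoints(rng, 2)).n_pairs == 1

    def test_means_match_brute_force_loop(self, rng):
        endpoints = self._endpoints(rng, 5)
        null = solo_pairwise_null(endpoints)
        assert null.n_pairs == 10
        brute_start = [
            math.hypot(sa[0] - sb[0], sa[1] - sb[1])
            for (_, sa, _), (_, sb, _) in itertools.combinations(endpoints, 2)
        ]
        brute_end = [
            math.hypot(ea[0] - eb[0], ea[1] - eb[1])
            for (_, _, ea), (_, _, eb) in itertools.combinations(endpoints, 2)
        ]
        assert np.mean(null.start_seps) == pytest.approx(np.mean(brute_start))
        assert np.mean(null.end_seps) == pytest.approx(np.mean(brute_end))
        assert np.allclose(null.deltas, np.array(brute_end) - np.array(brute_start))

    def test_duplicate_singer_rejected(self, rng):
        eps = self._endpoints(rng, 3)
        eps[2] = ("s0", eps[2][1], eps[2][2])
        with pytest.raises(ValidationError):
            solo_pairwise_null(eps)

    def test_delta_negation_mirrors_distribution(self, rng):
        # Swapping every singer's start and end positions negates all deltas.
        eps = self._endpoints(rng, 6)
        flipped = [(sid, e, s) for sid, s, e in eps]
        assert np.allclose(
            solo_pairwise_null(flipped).deltas, -solo_pairwise_null(eps).deltas
        )
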