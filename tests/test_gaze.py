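"""Eye-tracking analysis: blink scrubbing, density maps, AFZ, bias vectors,
null-quadrant test."""

import numpy as np
import pandas as pd
import pytest

from prfkit.gaze import (BiasVector, DensityMap, adult_fixation_zone,
                         angular_distance_from_quadrant, bias_vector,
                         fixation_density, group_density, null_quadrant_test,
                         outside_afz_ratio, scrub_blinks)
from prfkit.synth import FixationSet, SyntheticGazeConfig, simulate_gaze

SCREEN = (768, 1024)


def _stream(ts, events=None):
    ts = np.asarray(ts, dtype=float)
    ev = ["sample"] * len(ts) if events is None else events
    return pd.DataFrame(dict(t_ms=ts, x_px=500.0, y_px=400.0, event=ev))


def _fix(points, durations, participant="p0", stimulus="s0"):
    pts = np.asarray(points, dtype=float)
    ev = pd.DataFrame(dict(t_ms=np.arange(len(pts), dtype=float) * 300,
                           x_px=pts[:, 0], y_px=pts[:, 1],
                           duration_ms=np.asarray(durations, dtype=float)))
    return FixationSet(participant=participant, stimulus=stimulus, events=ev)


class TestScrubBlinks:
    def test_no_blinks_is_noop(self):
        s = _stream(np.arange(100))
        out = scrub_blinks(s)
        pd.testing.assert_frame_equal(out, s)

    def test_halfopen_window_sample_count(self):
        # 1000 Hz samples at 0..999 ms; blink [500, 600), pad 100
        # -> samples in [400, 700) removed: exactly 300
        ts = np.arange(1000.0)
        df = _stream(ts)
        blink = pd.DataFrame(dict(t_ms=[500.0, 600.0], x_px=np.nan,
                                  y_px=np.nan,
                                  event=["blink_start", "blink_end"]))
        s = pd.concat([df, blink]).sort_values("t_ms", kind="stable")
        out = scrub_blinks(s, pad_ms=100.0)
        assert len(out) == 700
        assert not ((out["t_ms"] >= 400) & (out["t_ms"] < 700)).any()

    def test_overlapping_pads_merge(self):
        ts = np.arange(1000.0)
        rows = [_stream(ts)]
        for b0, b1 in [(300.0, 350.0), (420.0, 470.0)]:  # pads overlap
            rows.append(pd.DataFrame(dict(
                t_ms=[b0, b1], x_px=np.nan, y_px=np.nan,
                event=["blink_start", "blink_end"])))
        s = pd.concat(rows).sort_values("t_ms", kind="stable")
        out = scrub_blinks(s, pad_ms=100.0)
        # single merged gap [200, 570)
        assert len(out) == 1000 - 370
        assert not ((out["t_ms"] >= 200) & (out["t_ms"] < 570)).any()

    def test_unordered_rejected(self):
        s = _stream([0.0, 2.0, 1.0])
        with pytest.raises(ValueError):
            scrub_blinks(s)


class TestFixationDensity:
    def test_single_fixation_peak_one_decaying(self):
        fix = _fix([(500, 400)], [250])
        d = fixation_density(fix, sigma_px=10.0)
        assert d.values.max() == pytest.approx(1.0)
        assert d.values[400, 500] == pytest.approx(1.0)
        assert d.values[400, 550] < d.values[400, 520] < 1.0

    def test_two_distant_fixations_both_peak_near_one(self):
        fix = _fix([(200, 200), (800, 600)], [300, 300])
        d = fixation_density(fix, sigma_px=18.75)
        assert d.values[200, 200] == pytest.approx(1.0, abs=1e-6)
        assert d.values[600, 800] == pytest.approx(1.0, abs=1e-6)

    def test_duration_scale_invariance(self):
        pts = [(300, 300), (500, 400), (700, 500)]
        a = fixation_density(_fix(pts, [100, 200, 300]))
        b = fixation_density(_fix(pts, [200, 400, 600]))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_order_invariance(self):
        a = fixation_density(_fix([(300, 300), (600, 500)], [100, 400]))
        b = fixation_density(_fix([(600, 500), (300, 300)], [400, 100]))
        np.testing.assert_allclose(a.values, b.values)

    def test_empty_rejected(self):
        fix = FixationSet(participant="p", stimulus="s",
                          events=pd.DataFrame(columns=["t_ms", "x_px",
                                                       "y_px",
                                                       "duration_ms"]))
        with pytest.raises(ValueError):
            fixation_density(fix)


class TestGroupDensity:
    def test_identical_maps(self):
        d = fixation_density(_fix([(500, 400)], [100]))
        out = group_density([d, d])
        np.testing.assert_allclose(out.values, d.values)

    def test_map_plus_zero_halves(self):
        d = fixation_density(_fix([(500, 400)], [100]))
        zero = DensityMap(values=np.zeros_like(d.values), sigma_px=d.sigma_px)
        out = group_density([d, zero])
        np.testing.assert_allclose(out.values, d.values / 2)

    def test_three_map_pointwise_oracle(self, rng):
        maps = [DensityMap(values=rng.random((10, 12)), sigma_px=1.0)
                for _ in range(3)]
        out = group_density(maps)
        np.testing.assert_allclose(
            out.values, (maps[0].values + maps[1].values + maps[2].values) / 3)


class TestAFZ:
    def test_unanimous_adults(self):
        d = fixation_density(_fix([(500, 400)], [100]), sigma_px=10.0)
        afz = adult_fixation_zone([d, d, d], overlap=0.7, presence_eps=0.01)
        np.testing.assert_array_equal(afz, d.values > 0.01)

    def test_fraction_threshold_is_inclusive(self):
        maps = []
        for i in range(10):
            v = np.zeros((20, 20))
            if i < 7:
                v[5, 5] = 1.0  # pixel present in exactly 7/10 adults
            if i < 6:
                v[9, 9] = 1.0  # present in exactly 6/10
            maps.append(DensityMap(values=v, sigma_px=1.0))
        afz = adult_fixation_zone(maps, overlap=0.7, presence_eps=0.5)
        assert afz[5, 5]
        assert not afz[9, 9]

    def test_zero_overlap_gives_union(self):
        a = DensityMap(values=np.eye(4), sigma_px=1.0)
        b = DensityMap(values=np.fliplr(np.eye(4)), sigma_px=1.0)
        afz = adult_fixation_zone([a, b], overlap=0.0, presence_eps=0.5)
        np.testing.assert_array_equal(afz, (np.eye(4) > 0.5)
                                      | (np.fliplr(np.eye(4)) > 0.5))

    def test_afz_shrinks_with_overlap(self):
        rng = np.random.default_rng(3)
        maps = [DensityMap(values=rng.random((30, 30)), sigma_px=1.0)
                for _ in range(6)]
        sizes = [adult_fixation_zone(maps, overlap=o, presence_eps=0.5).sum()
                 for o in (0.2, 0.5, 0.8, 1.0)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_mean_density_variant(self):
        d = fixation_density(_fix([(500, 400)], [100]), sigma_px=10.0)
        afz = adult_fixation_zone([d], overlap=0.7, method="mean_density")
        assert afz[400, 500]
        assert afz.sum() < (d.values > 0.01).sum()


class TestOutsideAFZRatio:
    AFZ = np.zeros(SCREEN, dtype=bool)
    AFZ[300:500, 400:600] = True

    def test_all_inside(self):
        fix = _fix([(500, 400), (450, 350)], [100, 200])
        assert outside_afz_ratio(fix, self.AFZ) == 0.0

    def test_balanced(self):
        fix = _fix([(500, 400), (100, 100)], [300, 300])
        assert outside_afz_ratio(fix, self.AFZ) == pytest.approx(0.5)

    def test_duration_weighted(self):
        fix = _fix([(500, 400), (450, 420), (50, 50)], [100, 200, 700])
        assert outside_afz_ratio(fix, self.AFZ) == pytest.approx(0.7)

    def test_monotone_in_afz_growth(self):
        fix = _fix([(500, 400), (100, 100), (700, 600)], [100, 100, 100])
        bigger = self.AFZ.copy()
        bigger[550:650, 650:750] = True
        assert outside_afz_ratio(fix, bigger) <= \
            outside_afz_ratio(fix, self.AFZ)


class TestBiasVector:
    def test_identical_maps_zero_vector(self):
        d = fixation_density(_fix([(500, 400)], [100]), sigma_px=12.0)
        afz = adult_fixation_zone([d])
        v = bias_vector(d, d, afz)
        assert v.magnitude < 1e-9

    def test_up_right_displacement_angle_45(self):
        adult = fixation_density(_fix([(500, 400)], [100]), sigma_px=12.0)
        # child 30 px right, 30 px up on screen (up = smaller row index)
        child = fixation_density(_fix([(530, 370)], [100]), sigma_px=12.0)
        afz = adult_fixation_zone([adult])
        v = bias_vector(child, adult, afz)
        assert v.angle == pytest.approx(45.0, abs=1.0)
        assert v.magnitude == pytest.approx(np.hypot(30, 30), rel=0.05)

    def test_generator_round_trip(self):
        box = [(384, 256, 640, 512)]
        adults = simulate_gaze(SyntheticGazeConfig(
            n_participants=6, n_fixations=150, center_offset=(0, 0),
            spread=30.0, seed=21, group="adults"), box)
        children = simulate_gaze(SyntheticGazeConfig(
            n_participants=6, n_fixations=150, center_offset=(40.0, -40.0),
            spread=30.0, seed=22, group="children"), box)
        a_map = group_density([fixation_density(f) for f in adults])
        c_map = group_density([fixation_density(f) for f in children])
        afz = adult_fixation_zone([fixation_density(f) for f in adults])
        v = bias_vector(c_map, a_map, afz)
        assert abs(v.dx - 40.0) < 2.0
        assert abs(v.dy - 40.0) < 2.0  # screen -40 (up) -> +40 in y-up


class TestNullQuadrant:
    def test_wrapped_angle_oracle(self):
        # 45 deg vector vs lower-left quadrant [180, 270]: 135 deg away
        assert angular_distance_from_quadrant(45.0, (180.0, 270.0)) == \
            pytest.approx(135.0)

    def test_inside_quadrant_distance_zero(self):
        assert angular_distance_from_quadrant(200.0, (180.0, 270.0)) == 0.0
        assert angular_distance_from_quadrant(300.0, (270.0, 360.0)) == 0.0

    def test_uniform_angles_quadrant_occupancy(self):
        rng = np.random.default_rng(42)
        angles = rng.uniform(0, 360, 100_000)
        frac = np.mean([180.0 <= a <= 270.0 for a in angles])
        assert frac == pytest.approx(0.25, abs=0.005)

    def test_t_test_on_biased_vectors(self):
        vecs = [BiasVector(stimulus=f"s{i}", dx=1.0, dy=1.0 + 0.1 * i)
                for i in range(8)]
        out = null_quadrant_test(vecs, "lower-left")
        assert np.all(out["distances"] > 100)
        assert out["t"] > 10
        assert out["p"] < 1e-6

    def test_requires_two_vectors(self):
        with pytest.raises(ValueError):
            null_quadrant_test([BiasVector("s", 1, 1)], "lower-left")
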