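"""Dyssynchrony mapping, hotspot calling and proximity statistics."""

import numpy as np
import pytest

from stormquant import (
    CalciumMovie,
    DyssynchronyMap,
    compute_sd_map,
    detect_hotspots,
    gate_frames,
    measure_proximity,
    random_spot_null,
    segment_neutrophils,
    simulate_calcium_movie,
    summarize_association,
)
from stormquant.simulate import MovieSimSpec

from oracles import naive_sd_map


def movie_from(ca, px=2.0, phases=None):
    ca = np.asarray(ca, dtype=float)
    phases = np.zeros(ca.shape[0]) if phases is None else np.asarray(phases)
    return CalciumMovie(ca, np.zeros_like(ca), px, phases)


class TestGating:
    def test_alternating_phases_keep_every_other_frame(self):
        ca = np.arange(12, dtype=float).reshape(12, 1, 1)
        m = movie_from(ca, phases=np.tile([0.0, 0.5], 6))
        g = gate_frames(m, 0.0, 0.1)
        assert np.array_equal(g.ca[:, 0, 0], np.arange(0, 12, 2))

    def test_more_than_thirty_matches_truncated(self):
        ca = np.zeros((40, 2, 2))
        m = movie_from(ca, phases=np.zeros(40))
        assert gate_frames(m, 0.0, 0.1).n_frames == 30

    def test_fewer_than_five_matches_rejected(self):
        m = movie_from(np.zeros((10, 2, 2)), phases=np.linspace(0, 0.9, 10))
        with pytest.raises(ValueError, match="3 frames"):
            gate_frames(m, 0.0, 0.11)

    def test_circular_phase_distance(self):
        m = movie_from(np.zeros((10, 1, 1)), phases=np.array([0.98, 0.5] * 5))
        assert gate_frames(m, 0.0, 0.05).n_frames == 5


class TestSdMap:
    def test_constant_movie_gives_zero_map(self):
        m = movie_from(np.full((6, 4, 4), 3.7))
        assert np.all(compute_sd_map(m).sd_values == 0)

    def test_two_point_sample_sd(self):
        ca = np.stack([np.full((2, 2), 1.0), np.full((2, 2), 3.0)])
        sd = compute_sd_map(movie_from(ca)).sd_values
        assert sd == pytest.approx(np.sqrt(2.0))

    def test_matches_naive_two_pass_oracle(self, study_movie):
        movie, _ = study_movie
        gated = gate_frames(movie, 0.125, 0.01)
        sd = compute_sd_map(gated).sd_values
        assert np.max(np.abs(sd - naive_sd_map(gated.ca))) < 1e-10

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="two frames"):
            compute_sd_map(movie_from(np.zeros((1, 2, 2))))


class TestHotspots:
    def test_single_spiked_pixel_is_one_hotspot(self):
        vals = np.ones((32, 32))
        vals[10, 20] = 2.0  # far above mean + 10 x background SD (zero)
        dmap = DyssynchronyMap(vals, 10, 0.0, pixel_size_um=1.0)
        hs = detect_hotspots(dmap, k=4, min_area_um2=1.0)
        assert len(hs) == 1
        assert hs.hotspots[0].x_um == pytest.approx(20.5)
        assert hs.hotspots[0].y_um == pytest.approx(10.5)

    def test_zero_variance_map_has_no_hotspots(self):
        dmap = DyssynchronyMap(np.zeros((16, 16)), 10, 0.0, 1.0)
        assert len(detect_hotspots(dmap)) == 0

    def test_three_planted_cells_recovered(self, study_movie):
        movie, gt = study_movie
        dmap = compute_sd_map(gate_frames(movie, 0.125, 0.01))
        hs = detect_hotspots(dmap)
        assert len(hs) == 3
        px = movie.pixel_size_um
        for h in hs.hotspots:
            assert any(
                c0 * px <= h.x_um <= c1 * px and r0 * px <= h.y_um <= r1 * px
                for r0, r1, c0, c1 in gt.cell_bounds_px
            )

    def test_hotspot_area_non_increasing_in_k(self, study_movie):
        movie, _ = study_movie
        dmap = compute_sd_map(gate_frames(movie, 0.125, 0.01))
        areas = [
            sum(h.area_um2 for h in detect_hotspots(dmap, k=k, min_area_um2=0).hotspots)
            for k in (2.0, 4.0, 6.0, 10.0)
        ]
        assert all(a >= b for a, b in zip(areas, areas[1:]))

    def test_physical_unit_round_trip(self, study_movie):
        """Doubling the pixel size doubles distances and quadruples areas
        while the pixel-level detections stay identical."""
        movie, _ = study_movie
        dmap1 = compute_sd_map(gate_frames(movie, 0.125, 0.01))
        dmap2 = DyssynchronyMap(dmap1.sd_values, dmap1.n_frames_used,
                                dmap1.gating_phase, 2 * dmap1.pixel_size_um)
        h1 = detect_hotspots(dmap1, min_area_um2=0)
        h2 = detect_hotspots(dmap2, min_area_um2=0)
        assert len(h1) == len(h2)
        assert np.allclose(2 * h1.xy_um, h2.xy_um)
        assert np.allclose(
            4 * np.array([h.area_um2 for h in h1.hotspots]),
            np.array([h.area_um2 for h in h2.hotspots]),
        )


class TestNeutrophilSegmentation:
    def test_two_disjoint_blobs_recovered_within_one_pixel(self):
        spec = MovieSimSpec(grid=(10, 10), n_neutrophils=2, seed=8)
        movie, gt = simulate_calcium_movie(spec)
        cents = segment_neutrophils(movie)
        assert cents.shape[0] == 2
        for xy in gt.neutrophil_xy_um:
            d = np.linalg.norm(cents - xy, axis=1)
            assert d.min() <= movie.pixel_size_um

    def test_empty_channel_gives_empty_list(self):
        m = movie_from(np.zeros((6, 8, 8)))
        assert segment_neutrophils(m).shape == (0, 2)

    def test_blob_below_min_area_dropped(self):
        ca = np.zeros((5, 20, 20))
        neut = np.zeros((5, 20, 20))
        neut[:, 10, 10] = 100.0  # single bright pixel: 4 um^2 at 2 um/px
        m = CalciumMovie(ca, neut, 2.0, np.zeros(5))
        assert segment_neutrophils(m, min_area_um2=20.0).shape == (0, 2)


class TestProximity:
    def test_coincident_neutrophil_distance_zero(self):
        r = measure_proximity(np.array([[10.0, 10.0]]), np.array([[10.0, 10.0]]))
        assert r.nearest_um[0] == 0.0
        assert r.n_within_radius[0] == 1

    def test_neutrophil_beyond_radius_not_counted(self):
        r = measure_proximity(np.array([[0.0, 0.0]]), np.array([[60.0, 0.0]]),
                              radius_um=50.0)
        assert r.nearest_um[0] == pytest.approx(60.0)
        assert r.n_within_radius[0] == 0

    def test_no_neutrophils_flagged(self):
        r = measure_proximity(np.array([[0.0, 0.0]]), np.empty((0, 2)))
        assert r.no_neutrophils
        assert np.isnan(r.nearest_um[0]) and r.n_within_radius[0] == 0

    def test_uniform_density_count_matches_poisson_expectation(self):
        """With neutrophils uniform at density rho, the mean count within
        radius r approaches rho * pi * r^2."""
        rng = np.random.default_rng(3)
        side, n, radius = 1000.0, 400, 50.0
        rho = n / side**2
        counts = []
        for _ in range(150):
            neut = rng.uniform(0, side, (n, 2))
            spot = rng.uniform(200, 800, (1, 2))  # away from borders
            counts.append(measure_proximity(spot, neut, radius).n_within_radius[0])
        assert np.mean(counts) == pytest.approx(rho * np.pi * radius**2, rel=0.1)

    def test_random_spots_deterministic_under_seed(self):
        neut = np.array([[5.0, 5.0], [20.0, 30.0]])
        a = random_spot_null(neut, (64, 64), 2.0, seed=7)
        b = random_spot_null(neut, (64, 64), 2.0, seed=7)
        assert np.array_equal(a.points_xy_um, b.points_xy_um)


class TestAssociation:
    @staticmethod
    def _result(kind, fov, distances):
        return measure_proximity(
            np.zeros((len(distances), 2)),
            np.empty((0, 2)), kind=kind, fov_id=fov,
        ).__class__(
            kind=kind,
            points_xy_um=np.zeros((len(distances), 2)),
            nearest_um=np.asarray(distances, dtype=float),
            n_within_radius=np.zeros(len(distances), dtype=int),
            radius_um=50.0,
            fov_id=fov,
        )

    def test_exchangeable_distances_give_p_near_one(self):
        res = []
        for f in range(4):
            res.append(self._result("hotspot", f"f{f}", [10.0, 10.0]))
            res.append(self._result("random", f"f{f}", [10.0, 10.0]))
        s = summarize_association(res, n_permutations=500, seed=0)
        assert s.p_permutation > 0.9

    def test_strong_separation_is_significant(self):
        res = []
        for f in range(11):
            res.append(self._result("hotspot", f"f{f}", [5.0, 5.5, 4.5]))
            res.append(self._result("random", f"f{f}", [40.0, 41.0, 39.0]))
        s = summarize_association(res, n_permutations=2000, seed=0)
        assert s.p_permutation < 0.01
        assert s.p_ttest < 0.01
        assert s.diff_um < 0

    def test_single_fov_rejected(self):
        res = [self._result("hotspot", "f0", [5.0]),
               self._result("random", "f0", [9.0])]
        with pytest.raises(ValueError, match="2 FOVs"):
            summarize_association(res)
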