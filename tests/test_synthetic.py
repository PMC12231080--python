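import numpy as np
import pytest

from fireprogress import (GridSpec, SpreadParams, generate_covariate_grid,
                          generate_landscape, sample_detections, simulate_fire)
from fireprogress.landcover import CODE


class TestGenerateLandscape:
    def test_degenerate_weights_fill_grid(self):
        lc = generate_landscape(GridSpec(100, 100), {"warm_conifer": 1.0}, 90.0, 0)
        assert (lc.classes == CODE["warm_conifer"]).all()

    def test_marginal_frequencies_match_weights(self):
        # binomial SE at n = 40,000 is ~0.002; +/-0.02 is a generous bound
        lc = generate_landscape(GridSpec(200, 200),
                                {"aspen": 0.25, "warm_conifer": 0.75}, 0.0, 1)
        aspen_freq = (lc.classes == CODE["aspen"]).mean()
        assert abs(aspen_freq - 0.25) <= 0.02

    def test_deterministic_given_seed(self):
        kw = dict(spec=GridSpec(50, 50),
                  class_weights={"aspen": 0.3, "shrub": 0.7}, patchiness=120.0)
        a = generate_landscape(seed=7, **kw)
        b = generate_landscape(seed=7, **kw)
        assert np.array_equal(a.classes, b.classes)

    def test_unknown_class_name_is_error(self):
        with pytest.raises(ValueError, match="lodgepole"):
            generate_landscape(GridSpec(10, 10), {"lodgepole": 1.0}, 0.0, 0)

    def test_patchiness_increases_spatial_clustering(self):
        smooth = generate_landscape(GridSpec(80, 80), {"aspen": 0.5, "shrub": 0.5}, 240.0, 3)
        rough = generate_landscape(GridSpec(80, 80), {"aspen": 0.5, "shrub": 0.5}, 0.0, 3)

        def same_neighbor_frac(lc):
            c = lc.classes
            return (c[:, 1:] == c[:, :-1]).mean()

        assert same_neighbor_frac(smooth) > same_neighbor_frac(rough) + 0.2


class TestSimulateFire:
    def _uniform_landcover(self, n=15, group="warm_conifer"):
        from fireprogress.landcover import LandcoverGrid
        return LandcoverGrid(GridSpec(n, n),
                             np.full((n, n), CODE[group], dtype=np.int16))

    def test_deterministic_limit_is_chebyshev_ball(self):
        """With spread probability 1 everywhere, each cell's burn day is
        1 + its Chebyshev distance from the ignition."""
        lc = self._uniform_landcover(15)
        params = SpreadParams(base_spread_prob=1.0, max_days=8, rng_seed=0)
        fire = simulate_fire(lc, (7, 7), params)
        ii, jj = np.meshgrid(np.arange(15), np.arange(15), indexing="ij")
        cheb = np.maximum(np.abs(ii - 7), np.abs(jj - 7))
        expected = np.where(cheb <= 7, cheb + 1, cheb + 1)  # full grid reachable
        assert np.array_equal(fire.true_dob.day, expected)

    def test_nonflammable_strip_is_absorbing_barrier(self):
        from fireprogress.landcover import LandcoverGrid
        classes = np.full((20, 20), CODE["warm_conifer"], dtype=np.int16)
        classes[:, 8:13] = CODE["nonflammable"]
        lc = LandcoverGrid(GridSpec(20, 20), classes)
        params = SpreadParams(base_spread_prob=1.0, max_days=40, rng_seed=1)
        fire = simulate_fire(lc, (10, 2), params)
        assert not fire.true_dob.burned_mask[:, 13:].any()

    def test_aspen_penalty_reduces_mean_final_area(self):
        areas = {}
        for mult in (0.3, 1.0):
            tot = []
            for rep in range(20):
                lc = generate_landscape(GridSpec(40, 40),
                                        {"aspen": 0.5, "warm_conifer": 0.5},
                                        60.0, 100 + rep)
                params = SpreadParams(base_spread_prob=0.5,
                                      per_type_multiplier={"aspen": mult},
                                      max_days=15, rng_seed=100 + rep)
                fire = simulate_fire(lc, (20, 20), params, fire_id=f"r{rep}")
                tot.append(fire.true_dob.burned_mask.sum())
            areas[mult] = np.mean(tot)
        assert areas[0.3] < areas[1.0]

    def test_mean_area_monotone_in_aspen_multiplier(self):
        means = []
        for mult in (0.1, 0.5, 1.0):
            tot = []
            for rep in range(20):
                lc = generate_landscape(GridSpec(40, 40),
                                        {"aspen": 0.5, "warm_conifer": 0.5},
                                        60.0, 200 + rep)
                params = SpreadParams(base_spread_prob=0.5,
                                      per_type_multiplier={"aspen": mult},
                                      max_days=15, rng_seed=200 + rep)
                tot.append(simulate_fire(lc, (20, 20), params,
                                         fire_id=f"r{rep}").true_dob.burned_mask.sum())
            means.append(np.mean(tot))
        assert means[0] <= means[1] <= means[2]

    def test_ignition_lineage_days_non_decreasing(self):
        """With one sweep per day, every cell burned after day 1 touches a
        cell burned on an earlier day (its igniting neighbor)."""
        lc = self._uniform_landcover(40)
        params = SpreadParams(base_spread_prob=0.4, max_days=25, rng_seed=9)
        fire = simulate_fire(lc, (20, 20), params)
        day = fire.true_dob.day
        from scipy import ndimage
        for d in fire.true_dob.days_present():
            if d == 1:
                continue
            earlier = (day != -1) & (day < d)
            near = ndimage.binary_dilation(earlier, np.ones((3, 3), bool))
            assert near[day == d].all()

    def test_burn_grows_as_connected_front(self):
        """With intra-day substeps the cumulative burn through any day is a
        single 8-connected component containing the ignition."""
        from skimage import measure
        lc = self._uniform_landcover(40)
        params = SpreadParams(base_spread_prob=0.4, max_days=12, rng_seed=9,
                              substeps_per_day=3)
        fire = simulate_fire(lc, (20, 20), params)
        day = fire.true_dob.day
        for d in fire.true_dob.days_present():
            cum = (day != -1) & (day <= d)
            labels = measure.label(cum, connectivity=2)
            assert labels.max() == 1
            assert labels[20, 20] == 1

    def test_nonflammable_ignition_is_error(self):
        lc = self._uniform_landcover(10, "nonflammable")
        with pytest.raises(ValueError, match="flammable"):
            simulate_fire(lc, (5, 5), SpreadParams())

    def test_all_nodata_landscape_is_error(self):
        from fireprogress.landcover import LandcoverGrid
        lc = LandcoverGrid(GridSpec(5, 5), np.full((5, 5), -1, dtype=np.int16))
        with pytest.raises(ValueError, match="empty"):
            simulate_fire(lc, (2, 2), SpreadParams())

    def test_bit_reproducible(self):
        lc = self._uniform_landcover(25)
        params = SpreadParams(base_spread_prob=0.4, max_days=12, rng_seed=5)
        a = simulate_fire(lc, (12, 12), params, fire_id="x")
        b = simulate_fire(lc, (12, 12), params, fire_id="x")
        assert np.array_equal(a.true_dob.day, b.true_dob.day)


class TestSampleDetections:
    def _one_day_dob(self, n):
        from fireprogress.dob import DOBGrid
        return DOBGrid(GridSpec(n, n), np.ones((n, n), dtype=np.int32))

    def test_no_thinning_limit_hits_every_cell_center(self, dense_fire):
        fire = dense_fire["fire"]
        truth = fire.true_dob
        assert len(fire.detections) == int(truth.burned_mask.sum())
        spec = truth.spec
        for det in fire.detections[:200]:
            r, c = spec.index_of(np.array([det.x]), np.array([det.y]))
            assert truth.day[r[0], c[0]] == det.day
            x, y = spec.center_of(r, c)
            assert x[0] == det.x and y[0] == det.y

    def test_thinning_count_within_poisson_bound(self):
        # 10,000-cell burn day at 0.5 detections per 100 cells: expect 50
        dob = self._one_day_dob(100)
        dets = sample_detections(dob, rate=0.5, jitter_sigma=0.0, seed=4,
                                 min_per_day=0)
        assert abs(len(dets) - 50) <= 3 * np.sqrt(50)

    def test_jitter_displacement_matches_rayleigh_mean(self):
        """Isotropic Gaussian jitter of scale sigma displaces detections by
        sigma * sqrt(pi/2) on average (the Rayleigh mean)."""
        from fireprogress.dob import DOBGrid
        # burn widely spaced single cells so each detection's source center
        # is unambiguous (spacing 150 m >> any plausible 15-m jitter draw)
        day = np.full((250, 250), -1, dtype=np.int32)
        day[::5, ::5] = 1  # 2500 sources
        dob = DOBGrid(GridSpec(250, 250), day)
        dets = sample_detections(dob, rate=100.0, jitter_sigma=15.0, seed=6)
        xs = np.array([d.x for d in dets])
        ys = np.array([d.y for d in dets])
        sx = np.round((xs - 15.0) / 150.0) * 150.0 + 15.0
        sy = np.round((ys + 15.0) / 150.0) * 150.0 - 15.0
        disp = np.hypot(xs - sx, ys - sy)
        expected = 15.0 * np.sqrt(np.pi / 2)  # ~18.8 m
        se = disp.std(ddof=1) / np.sqrt(disp.size)
        assert abs(disp.mean() - expected) < 4 * se + 0.5

    def test_overpass_floor_guarantees_daily_detection(self):
        from fireprogress.dob import DOBGrid
        day = np.full((10, 10), -1, dtype=np.int32)
        day[0, :] = 1
        day[1, 0] = 2  # a single-cell day that thinning would usually miss
        dob = DOBGrid(GridSpec(10, 10), day)
        dets = sample_detections(dob, rate=0.1, jitter_sigma=0.0, seed=0,
                                 min_per_day=1)
        assert {d.day for d in dets} == {1, 2}

    def test_empty_dob_yields_empty_list(self):
        from fireprogress.dob import DOBGrid
        dob = DOBGrid(GridSpec(5, 5), np.full((5, 5), -1, dtype=np.int32))
        assert sample_detections(dob, rate=5.0, jitter_sigma=0.0, seed=0) == []

    def test_deterministic_given_seed(self):
        dob = self._one_day_dob(30)
        a = sample_detections(dob, 5.0, 10.0, seed=3, fire_id="f")
        b = sample_detections(dob, 5.0, 10.0, seed=3, fire_id="f")
        assert [(d.x, d.y, d.day) for d in a] == [(d.x, d.y, d.day) for d in b]


class TestCovariateGrids:
    def test_zero_trend_keeps_daily_means_flat(self):
        grids = generate_covariate_grid(GridSpec(60, 60), "FWI", 300.0, 0.0, 30, 2)
        means = np.array([g.values.mean() for g in grids])
        assert abs(np.diff(means).mean()) < 0.05

    def test_daily_trend_recovered_by_regression(self):
        grids = generate_covariate_grid(GridSpec(200, 200), "FWI", 300.0, 0.1, 30, 2)
        means = np.array([g.values.mean() for g in grids])
        days = np.arange(1, 31)
        slope = np.polyfit(days, means, 1)[0]
        # day-level mean noise (sd 0.3) gives a slope SE of ~0.006
        assert abs(slope - 0.1) < 0.03

    def test_name_folded_into_stream(self):
        a = generate_covariate_grid(GridSpec(20, 20), "FWI", 150.0, 0.0, 1, 5)[0]
        b = generate_covariate_grid(GridSpec(20, 20), "Tmax", 150.0, 0.0, 1, 5)[0]
        assert not np.allclose(a.values, b.values)

    def test_nonpositive_scale_is_error(self):
        with pytest.raises(ValueError):
            generate_covariate_grid(GridSpec(5, 5), "FWI", 0.0, 0.0, 1, 0)
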