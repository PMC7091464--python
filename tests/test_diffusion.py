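"""Jump-distance sets, cumulative fits, spatial maps, retention."""

import numpy as np
import pandas as pd
import pytest

from conftest import keep_long, make_track
from nanogap.diffusion import (
    JDSet,
    fit_jd_cumulative,
    jd_map,
    jump_distances,
    retention_fraction,
    zone_diffusion,
)
from nanogap.masking import ContactMask
from nanogap.synthetic_data import SimulationParams, simulate_tracks


def rayleigh_jumps(r0_sq: float, n: int, seed: int) -> np.ndarray:
    """Exact draws from the free-diffusion jump-distance law."""
    rng = np.random.default_rng(seed)
    return np.sqrt(-r0_sq * np.log(rng.uniform(size=n)))


class TestJumpDistances:
    def test_three_four_five(self):
        tracks = pd.DataFrame(
            {"track_id": [0, 0], "frame": [0, 1], "x_um": [0.0, 3.0], "y_um": [0.0, 4.0]}
        )
        jd = jump_distances(tracks, dt=0.03)
        assert jd.r == pytest.approx([5.0])

    def test_stationary_track_zero_jumps(self):
        tracks = make_track(0, [2.0] * 6)
        jd = jump_distances(tracks, dt=0.03)
        assert np.allclose(jd.r, 0.0)

    def test_gap_spanning_pairs_excluded(self):
        tracks = pd.DataFrame(
            {"track_id": 0, "frame": [0, 1, 3], "x_um": [0.0, 1.0, 2.0], "y_um": 0.0}
        )
        jd = jump_distances(tracks, dt=0.03)
        assert len(jd) == 1

    def test_region_partition_is_exact(self, square_mask):
        tracks = make_track(0, [3.0, 4.0, 6.0, 8.0, 10.0, 3.0])
        jd_in = jump_distances(tracks, 0.03, "inside", square_mask)
        jd_out = jump_distances(tracks, 0.03, "outside", square_mask)
        jd_all = jump_distances(tracks, 0.03)
        assert len(jd_in) + len(jd_out) == len(jd_all)


class TestCumulativeFit:
    def test_recovers_d_from_exact_rayleigh(self):
        # r0^2 = 4 D dt with D = 0.6, dt = 0.03, sigma = 0
        r = rayleigh_jumps(0.072, 10_000, seed=1)
        fit = fit_jd_cumulative(JDSet(r, 0.03), sigma=0.0, n_bootstrap=100)
        assert abs(fit.d - 0.6) / 0.6 < 0.05
        assert fit.r0_sq == pytest.approx(4 * fit.d * 0.03 + 4 * fit.sigma**2)

    def test_sample_median_matches_fitted_law(self):
        r = rayleigh_jumps(0.072, 50_000, seed=2)
        fit = fit_jd_cumulative(JDSet(r, 0.03), sigma=0.0, n_bootstrap=10)
        assert np.median(r**2) == pytest.approx(fit.r0_sq * np.log(2), rel=0.03)

    def test_static_emitters_yield_pure_noise_floor(self):
        # true D = 0: observed jumps are noise differences, r0^2 ~ 4 sigma^2
        sigma = 0.03
        rng = np.random.default_rng(3)
        pos = rng.normal(0.0, sigma, size=(5000, 2, 2))
        r = np.hypot(*(pos[:, 1] - pos[:, 0]).T)
        fit = fit_jd_cumulative(JDSet(r, 0.03), sigma=sigma, n_bootstrap=50)
        assert fit.r0_sq == pytest.approx(4 * sigma**2, rel=0.1)
        assert fit.d < 0.01

    def test_scale_consistency(self):
        r = rayleigh_jumps(0.072, 5000, seed=4)
        f1 = fit_jd_cumulative(JDSet(r, 0.03), sigma=0.0, n_bootstrap=10)
        f2 = fit_jd_cumulative(JDSet(3.0 * r, 0.03), sigma=0.0, n_bootstrap=10)
        assert f2.r0_sq == pytest.approx(9.0 * f1.r0_sq, rel=1e-6)

    def test_bootstrap_ci_shrinks_with_sample_size(self):
        w = []
        for n in (1000, 10_000):
            r = rayleigh_jumps(0.072, n, seed=5)
            fit = fit_jd_cumulative(JDSet(r, 0.03), sigma=0.0, n_bootstrap=200)
            w.append(fit.ci[1] - fit.ci[0])
        ratio = w[0] / w[1]  # expect ~ sqrt(10) ~ 3.2
        assert 2.0 < ratio < 5.0

    def test_too_few_jumps_rejected(self):
        with pytest.raises(ValueError):
            fit_jd_cumulative(JDSet(np.ones(10), 0.03))

    def test_two_region_contrast_resolved_with_disjoint_cis(
        self, default_image_mask
    ):
        _, mask, _ = default_image_mask
        params = SimulationParams(seed=53, d_in=0.3, d_out=0.6)
        locs, _ = simulate_tracks(params, mask)
        fits = {}
        for region in ("inside", "outside"):
            jd = jump_distances(locs, params.frame_interval, region, mask)
            assert len(jd) >= 1000
            fits[region] = fit_jd_cumulative(
                jd, sigma=params.sigma_loc, n_bootstrap=100
            )
        assert fits["inside"].d < fits["outside"].d
        assert fits["inside"].ci[1] < fits["outside"].ci[0]


class TestJDMap:
    def test_single_jump_assigned_to_start_pixel(self):
        tracks = pd.DataFrame(
            {
                "track_id": [0, 0],
                "frame": [0, 1],
                "x_um": [5.0 * 0.16 + 0.08, 5.0 * 0.16 + 0.28],
                "y_um": [5.0 * 0.16 + 0.08, 5.0 * 0.16 + 0.08],
            }
        )
        jmap = jd_map(tracks, (32, 32), 0.16)
        assert jmap.count[5, 5] == 1
        assert jmap.mean_jd[5, 5] == pytest.approx(0.2)

    def test_unvisited_pixels_are_nan_not_zero(self):
        tracks = make_track(0, [1.0, 1.2])
        jmap = jd_map(tracks, (32, 32), 0.16)
        assert np.isnan(jmap.mean_jd[jmap.count == 0]).all()
        assert (jmap.count == 0).any()

    def test_uniform_diffusion_spatial_mean_matches_rayleigh(self):
        params = SimulationParams(seed=55, sigma_loc=0.0, n_frames=150)
        locs, _ = simulate_tracks(params, mask=None)
        h, w = params.field_size[1], params.field_size[0]
        jmap = jd_map(locs, (h, w), params.pixel_size)
        expected = np.sqrt(np.pi * params.d_out * params.frame_interval)
        weighted = np.nansum(jmap.mean_jd * jmap.count) / jmap.count.sum()
        assert abs(weighted - expected) / expected < 0.03


class TestZoneDiffusion:
    def test_decreasing_d_with_intensity_rank_recovered(self, default_image_mask):
        image, mask, _ = default_image_mask
        lo, hi = image[mask.mask].min(), image[mask.mask].max()
        rel = np.clip((image - lo) / (hi - lo), 0, 1)
        d_map = np.where(mask.mask, 0.6 - 0.45 * rel, 0.6)
        params = SimulationParams(seed=52, d_map=d_map)
        locs, _ = simulate_tracks(params, mask)
        table = zone_diffusion(
            locs, image, mask, dt=params.frame_interval, n_zones=4,
            sigma=params.sigma_loc, n_bootstrap=20,
        )
        assert table["intensity_mean"].is_monotonic_increasing
        assert table["d"].is_monotonic_decreasing

    def test_single_zone_equals_inside_fit(self, barrier_free_run, default_image_mask):
        image, _, _ = default_image_mask
        locs, _, mask, params = barrier_free_run
        table = zone_diffusion(
            locs, image, mask, dt=params.frame_interval, n_zones=1,
            sigma=params.sigma_loc, n_bootstrap=10,
        )
        jd = jump_distances(locs, params.frame_interval, "inside", mask)
        fit = fit_jd_cumulative(jd, sigma=params.sigma_loc, n_bootstrap=10)
        assert table.loc[0, "d"] == pytest.approx(fit.d, rel=1e-9)

    def test_constant_intensity_cannot_be_binned(self, barrier_free_run):
        locs, _, mask, params = barrier_free_run
        with pytest.raises(ValueError):
            zone_diffusion(
                locs, np.ones(mask.shape), mask, dt=params.frame_interval
            )


class TestRetention:
    def test_all_inside_is_one(self, square_mask):
        tracks = make_track(0, [10.0, 10.5, 11.0])
        assert retention_fraction(tracks, square_mask) == (1.0, 1)

    def test_half_retained(self, square_mask):
        tracks = pd.concat(
            [make_track(0, [10.0, 10.5, 11.0]), make_track(1, [10.0, 8.0, 3.0])]
        )
        frac, n = retention_fraction(tracks, square_mask)
        assert frac == 0.5 and n == 2

    def test_no_inside_starting_tracks_flagged(self, square_mask):
        tracks = make_track(0, [2.0, 2.5, 3.0])
        frac, n = retention_fraction(tracks, square_mask)
        assert np.isnan(frac) and n == 0
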