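"""Track categories, crossing tallies, Boltzmann penalties, breach zones."""

import numpy as np
import pandas as pd
import pytest

from conftest import keep_long, make_track
from nanogap.energetics import (
    baseline_corrected,
    breach_zones,
    categorize_tracks,
    crossing_events,
    energy_penalty,
    tally_crossings,
    CrossingTally,
)
from nanogap.masking import ContactMask
from nanogap.synthetic_data import SimulationParams, simulate_tracks

# square mask edges at x, y = 5.12 and 15.36 um (see conftest square_mask)


class TestCategorize:
    def test_four_primary_categories(self, square_mask):
        tracks = pd.concat(
            [
                make_track(0, [2.0, 2.1, 2.2]),  # outside_stay
                make_track(1, [3.0, 6.0, 10.0]),  # enter
                make_track(2, [10.0, 10.1, 10.2]),  # inside_stay
                make_track(3, [10.0, 6.0, 3.0]),  # exit
            ]
        )
        cats = categorize_tracks(tracks, square_mask)
        assert cats.loc[0, "category"] == "outside_stay"
        assert cats.loc[1, "category"] == "enter"
        assert cats.loc[2, "category"] == "inside_stay"
        assert cats.loc[3, "category"] == "exit"
        assert not cats.loc[0, "deflected"]

    def test_deflected_refines_outside_stay(self, square_mask):
        # touches the border band (x = 5.02, 0.10 um from the edge at 5.12)
        tracks = make_track(0, [3.0, 5.02, 3.0])
        cats = categorize_tracks(tracks, square_mask, touch_band=0.16)
        assert cats.loc[0, "category"] == "outside_stay"
        assert cats.loc[0, "deflected"]

    def test_all_band_track_flagged_ambiguous(self, square_mask):
        tracks = make_track(0, [5.02, 5.05, 5.03])
        cats = categorize_tracks(tracks, square_mask, touch_band=0.16)
        assert cats.loc[0, "category"] == "outside_stay"
        assert cats.loc[0, "ambiguous"]

    def test_categories_partition_tracks(self, barrier_run):
        locs, _, mask, _ = barrier_run
        kept = keep_long(locs)
        cats = categorize_tracks(kept, mask)
        assert len(cats) == kept["track_id"].nunique()
        assert set(cats["category"]).issubset(
            {"outside_stay", "enter", "inside_stay", "exit"}
        )


class TestEpisodeCounting:
    def test_clean_crossing_is_one_successful_attempt(self, square_mask):
        tracks = make_track(0, [3.0, 5.0, 5.3, 6.0, 7.0, 8.0, 9.0])
        tally = tally_crossings(tracks, square_mask, mode="episode")
        assert tally.n_attempts_enter == 1
        assert tally.n_success_enter == 1
        assert tally.n_attempts_exit == 0

    def test_two_touch_retreats_are_two_failed_attempts(self, square_mask):
        tracks = make_track(0, [3.0, 5.0, 4.0, 4.5, 5.05, 3.5, 3.0, 2.5])
        tally = tally_crossings(tracks, square_mask, mode="episode")
        assert tally.n_attempts_enter == 2
        assert tally.n_success_enter == 0

    def test_track_too_short_after_touch_excluded(self, square_mask):
        tracks = make_track(0, [3.0, 5.0, 4.0, 4.0])
        tally = tally_crossings(tracks, square_mask, mode="episode")
        assert tally.n_attempts_enter == 0

    def test_jump_across_band_counts_as_success(self, square_mask):
        tracks = make_track(0, [2.0, 4.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0])
        tally = tally_crossings(tracks, square_mask, mode="episode")
        assert tally.n_attempts_enter == 1
        assert tally.n_success_enter == 1


class TestStepCounting:
    def test_crossing_and_near_miss_steps(self, square_mask):
        # steps: 3.0->5.0 near-miss fail; 5.0->5.3 flip success;
        # later steps far from boundary -> not attempts
        tracks = make_track(0, [3.0, 5.0, 5.3, 6.0, 7.0, 8.0, 9.0])
        tally = tally_crossings(tracks, square_mask, mode="step")
        assert tally.n_attempts_enter == 2
        assert tally.n_success_enter == 1

    def test_ambiguous_steps_discarded(self, square_mask):
        # endpoint at 5.10 is 0.02 um from the edge: below the noise margin
        tracks = make_track(0, [3.0, 5.10, 3.0, 3.0, 3.0, 3.0, 3.0])
        ev = crossing_events(tracks, square_mask, mode="step")
        assert len(ev) == 0


class TestEnergyPenalty:
    def test_all_successes_zero_penalty(self):
        tally = CrossingTally(100, 100, 50, 50)
        enter, exit_ = energy_penalty(tally)
        assert enter.eps == 0.0
        assert exit_.eps == 0.0

    def test_quarter_success_is_ln4(self):
        tally = CrossingTally(100, 25, 0, 0)
        enter, exit_ = energy_penalty(tally)
        assert enter.eps == pytest.approx(np.log(4.0))
        assert enter.ci_low < enter.eps < enter.ci_high
        assert exit_.flag == "no attempts"

    def test_zero_successes_censored(self):
        tally = CrossingTally(40, 0, 0, 0)
        enter, _ = energy_penalty(tally)
        assert enter.censored
        assert np.isinf(enter.eps)
        assert enter.ci_low == pytest.approx(np.log(40))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            CrossingTally(10, 11, 0, 0)

    def test_ci_narrows_with_attempts(self):
        narrow = energy_penalty(CrossingTally(1000, 250, 0, 0))[0]
        wide = energy_penalty(CrossingTally(40, 10, 0, 0))[0]
        assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)

    def test_baseline_corrected_combines_variances(self):
        est = energy_penalty(CrossingTally(400, 50, 0, 0))[0]
        base = energy_penalty(CrossingTally(400, 200, 0, 0))[0]
        corr, lo, hi = baseline_corrected(est, base)
        assert corr == pytest.approx(est.eps - base.eps)
        assert lo < corr < hi
        # wider than the raw estimate interval alone
        assert (hi - lo) > (est.ci_high - est.ci_low) * 0.9


class TestDilatedMaskControl:
    def test_annulus_boundary_penalty_matches_free_bilayer(
        self, barrier_free_run, default_image_mask
    ):
        """No entry restriction at a control annulus in the free bilayer."""
        from nanogap.masking import dilate_mask

        locs, _, mask, _ = barrier_free_run
        kept = keep_long(locs)
        annulus = dilate_mask(mask, 12)
        t_ann = tally_crossings(kept, annulus)
        t_contact = tally_crossings(kept, mask)
        e_ann = energy_penalty(t_ann)[0]
        e_contact = energy_penalty(t_contact)[0]
        # barrier-free data: both are sampling baselines of similar size
        corr, lo, hi = baseline_corrected(e_ann, e_contact)
        assert lo < 0.35 and hi > -0.35


class TestBreachZones:
    def test_insufficient_segments_rejected(self, square_mask, barrier_free_run):
        locs, _, _, _ = barrier_free_run
        with pytest.raises(ValueError):
            breach_zones(
                keep_long(locs), square_mask, np.ones(square_mask.shape),
                segment_length=50.0,
            )

    def test_uniform_barrier_no_correlation(self, barrier_free_run, default_image_mask):
        image, _, _ = default_image_mask
        locs, _, mask, _ = barrier_free_run
        table, rho, _ = breach_zones(keep_long(locs), mask, image, segment_length=2.0)
        n_used = (table["n_attempts"] > 0).sum()
        null_bound = 1.96 / np.sqrt(n_used - 1)
        assert abs(rho) < null_bound

    def test_intensity_coupled_barrier_gives_negative_correlation(
        self, default_image_mask
    ):
        _, mask, _ = default_image_mask
        h, w = mask.shape
        ps = mask.pixel_size
        ramp = np.tile(np.linspace(0.0, 1.0, w), (h, 1))
        image = 100.0 + np.where(mask.mask, 100.0 + 200.0 * ramp, 0.0)
        params = SimulationParams(seed=51, eps_enter=3.0 * ramp, eps_exit=0.0)
        locs, _ = simulate_tracks(params, mask)
        _, rho, _ = breach_zones(keep_long(locs), mask, image, segment_length=2.0)
        assert rho < 0
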