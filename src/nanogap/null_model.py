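"""Barrier-free control simulation over a measured contact mask.

The null model releases particles (inside or outside the contact) at a
density and diffusion coefficient matched to the data and lets them
diffuse freely over the mask -- no boundary barriers, uniform D.  The
resulting tracks are pushed through exactly the same estimators as the
experimental data (energy penalties, retention), so that estimator bias
cancels in the comparison.  Repeats with independent seeds provide an
empirical 95% envelope; experimental values outside it are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diffusion import retention_fraction
from .energetics import (
    DEFAULT_NOISE_MARGIN,
    DEFAULT_TOUCH_BAND,
    MIN_FRAMES_AFTER_TOUCH,
    energy_penalty,
    tally_crossings,
)
from .masking import ContactMask
from .synthetic_data import SimulationParams, simulate_tracks
from .tracking import MIN_TRACK_LENGTH

__all__ = [
    "NullRunConfig",
    "EstimatorSettings",
    "run_null",
    "contact_stats",
    "null_stats",
    "compare_to_null",
]


@dataclass(frozen=True)
class EstimatorSettings:
    """Estimator parameters that must match between experiment and null."""

    touch_band: float = DEFAULT_TOUCH_BAND
    min_frames_after: int = MIN_FRAMES_AFTER_TOUCH
    min_track_length: int = MIN_TRACK_LENGTH
    mode: str = "step"
    noise_margin: float = DEFAULT_NOISE_MARGIN


@dataclass
class NullRunConfig:
    """Configuration of the barrier-free control simulation."""

    mask: ContactMask
    d: float = 0.6  # um^2/s, uniform
    density: float = 0.5  # particles/um^2 in start_region
    n_frames: int = 1000
    dt: float = 0.03
    start_region: str = "inside"
    n_repeats: int = 20
    seeds: Optional[Sequence[int]] = None
    sigma_loc: float = 0.03
    survival_prob: float = 0.93

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.seeds is None:
            self.seeds = list(range(self.n_repeats))
        if len(self.seeds) != self.n_repeats:
            raise ValueError("need one seed per repeat")

    def simulation_params(self) -> SimulationParams:
        h, w = self.mask.shape
        return SimulationParams(
            field_size=(w, h),
            pixel_size=self.mask.pixel_size,
            frame_interval=self.dt,
            n_frames=self.n_frames,
            d_out=self.d,
            d_in=self.d,
            eps_enter=0.0,
            eps_exit=0.0,
            sigma_loc=self.sigma_loc,
            particle_density_out=self.density,
            survival_prob=self.survival_prob,
        )


def run_null(config: NullRunConfig) -> list[pd.DataFrame]:
    """Simulate the barrier-free control; one track table per repeat."""
    params = config.simulation_params()
    out = []
    for seed in config.seeds:
        locs, _ = simulate_tracks(
            params, config.mask, seed=int(seed), init_region=config.start_region
        )
        out.append(locs)
    return out


def contact_stats(
    tracks: pd.DataFrame,
    mask: ContactMask,
    settings: EstimatorSettings = EstimatorSettings(),
) -> dict:
    """Energy penalties and retention of one track set over a mask.

    Applies the track-length filter and the shared estimator settings; the
    returned dict carries the settings so that experiment/null comparisons
    can verify they match.
    """
    lengths = tracks.groupby("track_id")["frame"].transform("size")
    kept = tracks[lengths >= settings.min_track_length]
    tally = tally_crossings(
        kept,
        mask,
        settings.touch_band,
        settings.min_frames_after,
        settings.mode,
        settings.noise_margin,
    )
    est_enter, est_exit = energy_penalty(tally)
    retention, n_inside = retention_fraction(kept, mask)
    return {
        "eps_enter": est_enter.eps,
        "eps_exit": est_exit.eps,
        "n_attempts_enter": tally.n_attempts_enter,
        "n_attempts_exit": tally.n_attempts_exit,
        "retention": retention,
        "n_inside_tracks": n_inside,
        "settings": settings,
    }


def null_stats(
    config: NullRunConfig,
    settings: EstimatorSettings = EstimatorSettings(),
) -> list[dict]:
    """Per-repeat estimator statistics of the null simulation."""
    return [
        contact_stats(tracks, config.mask, settings)
        for tracks in run_null(config)
    ]


def compare_to_null(
    experiment_stats: dict,
    null_repeat_stats: list[dict],
    quantities: Sequence[str] = ("eps_enter", "eps_exit", "retention"),
) -> pd.DataFrame:
    """Tabulate experiment-vs-null differences with repeat envelopes.

    For each quantity the null repeats provide a (2.5%, 97.5%) empirical
    envelope; the experimental value is flagged when it falls outside.
    Estimator settings must match on both sides (hard error otherwise).
    """
    exp_settings = experiment_stats.get("settings")
    for stats in null_repeat_stats:
        if stats.get("settings") != exp_settings:
            raise ValueError(
                "estimator settings differ between experiment and null; "
                "refusing an apples-to-oranges comparison"
            )
    rows = []
    for q in quantities:
        null_vals = np.array([s[q] for s in null_repeat_stats], dtype=float)
        finite = null_vals[np.isfinite(null_vals)]
        if len(finite) == 0:
            rows.append(
                {
                    "quantity": q,
                    "experiment": experiment_stats[q],
                    "null_mean": np.nan,
                    "null_sd": np.nan,
                    "null_lo": np.nan,
                    "null_hi": np.nan,
                    "difference": np.nan,
                    "flagged": False,
                }
            )
            continue
        lo, hi = np.percentile(finite, [2.5, 97.5])
        exp_val = float(experiment_stats[q])
        rows.append(
            {
                "quantity": q,
                "experiment": exp_val,
                "null_mean": float(finite.mean()),
                "null_sd": float(finite.std(ddof=1)) if len(finite) > 1 else 0.0,
                "null_lo": float(lo),
                "null_hi": float(hi),
                "difference": exp_val - float(finite.mean()),
                "flagged": bool(exp_val < lo or exp_val > hi),
            }
        )
    return pd.DataFrame(rows)
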