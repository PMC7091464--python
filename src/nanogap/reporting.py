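"""Cross-condition statistics, pipeline configuration and orchestration.

Per-cell scalar measurements (relative density, energy penalty, D) grouped
by condition are compared with one-way ANOVA followed by Tukey-Kramer post
hoc tests (studentized-range pairwise comparisons with the unequal-n
correction).  `run_pipeline` drives the full simulate -> mask -> track ->
exclusion -> energetics -> diffusion -> null-comparison chain and writes a
structured results directory with provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from . import __version__
from .diffusion import fit_jd_cumulative, jd_map, jump_distances, retention_fraction
from .exclusion import relative_density
from .energetics import energy_penalty, tally_crossings
from .masking import MaskParams, contact_mask
from .null_model import (
    EstimatorSettings,
    NullRunConfig,
    compare_to_null,
    contact_stats,
    null_stats,
)
from .synthetic_data import (
    DiskContact,
    SimulationParams,
    generate_spacer_image,
    simulate_tracks,
)
from .tracking import MIN_TRACK_LENGTH, link_tracks, track_qc

logger = logging.getLogger("nanogap")

__all__ = ["AnovaResult", "anova_tukey", "PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA with Tukey-Kramer pairwise comparisons."""

    f_statistic: float
    p_value: float
    pairwise: Optional[pd.DataFrame]
    valid: bool = True
    flag: Optional[str] = None


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """Compare condition groups by one-way ANOVA + Tukey-Kramer post hoc.

    ``groups`` maps condition label to an array of per-cell measurements;
    at least two groups with at least two observations each are required.
    Zero within-group variance makes F undefined and yields a flagged
    result instead of an exception.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} has < 2 observations")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {k!r} contains non-finite values")
    within_ss = sum(((v - v.mean()) ** 2).sum() for v in arrays.values())
    if within_ss == 0:
        return AnovaResult(
            np.nan, np.nan, None, valid=False, flag="zero within-group variance"
        )
    f_stat, p_val = stats.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return AnovaResult(float(f_stat), float(p_val), table)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All pipeline parameters; serializes losslessly to/from YAML."""

    seed: int = 0
    simulate: bool = True
    input_localizations: Optional[str] = None
    input_spacer_image: Optional[str] = None
    # synthetic acquisition
    field_size: tuple[int, int] = (128, 128)
    pixel_size: float = 0.16
    frame_interval: float = 0.03
    n_frames: int = 1000
    d_out: float = 0.6
    d_in: float = 0.6
    eps_enter: float = 0.0
    eps_exit: float = 0.0
    sigma_loc: float = 0.03
    particle_density_out: float = 0.5
    survival_prob: float = 0.93
    contact_radius_um: float = 6.0
    # masking
    gradient_threshold_fraction: float = 0.2
    min_object_area: float = 0.5
    smoothing_sigma: float = 1.0
    # tracking
    max_jump: float = 0.8
    max_gap: int = 0
    # estimators
    touch_band: float = 0.16
    min_frames_after: int = 5
    n_bootstrap: int = 200
    # null model
    null_repeats: int = 20

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["field_size"] = list(self.field_size)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "field_size" in data:
            data = {**data, "field_size": tuple(data["field_size"])}
        return cls(**data)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["field_size"] = list(self.field_size)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]

    def simulation_params(self) -> SimulationParams:
        return SimulationParams(
            field_size=self.field_size,
            pixel_size=self.pixel_size,
            frame_interval=self.frame_interval,
            n_frames=self.n_frames,
            d_out=self.d_out,
            d_in=self.d_in,
            eps_enter=self.eps_enter,
            eps_exit=self.eps_exit,
            sigma_loc=self.sigma_loc,
            particle_density_out=self.particle_density_out,
            survival_prob=self.survival_prob,
            seed=self.seed,
        )


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis chain and write a results directory.

    Stages: spacer image + mask -> tracks (simulated localization table,
    relinked with the standard linker) -> first-frame exclusion -> crossing
    energetics -> diffusion fits and JD map -> barrier-free null
    comparison.  A stage failure preserves the results of the stages
    already completed and records the error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {
        "provenance": {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "version": __version__,
        }
    }
    config.to_yaml(out / "config.yaml")
    errors: dict[str, str] = {}

    import tifffile

    if not config.simulate:
        missing = [
            p
            for p in (config.input_localizations, config.input_spacer_image)
            if p is None or not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(
                f"missing inputs (simulate=False): {missing}"
            )

    params = config.simulation_params()
    mask_params = MaskParams(
        gradient_threshold_fraction=config.gradient_threshold_fraction,
        min_object_area=config.min_object_area,
        smoothing_sigma=config.smoothing_sigma,
    )
    settings = EstimatorSettings(
        touch_band=config.touch_band,
        min_frames_after=config.min_frames_after,
        min_track_length=MIN_TRACK_LENGTH,
    )

    # --- stage: spacer image + mask -----------------------------------
    mask = None
    spacer = None
    try:
        if config.simulate:
            spacer, _ = generate_spacer_image(
                params, DiskContact(radius_um=config.contact_radius_um)
            )
        else:
            spacer = tifffile.imread(config.input_spacer_image).astype(float)
            if spacer.ndim == 3:  # temporal mean of the spacer channel
                spacer = spacer.mean(axis=0)
        tifffile.imwrite(out / "spacer.tif", spacer.astype(np.float32))
        mask = contact_mask(spacer, mask_params, pixel_size=config.pixel_size)
        if mask is None:
            errors["masking"] = "no contact found"
        else:
            tifffile.imwrite(
                out / "mask.tif", (mask.mask * np.uint8(255)).astype(np.uint8)
            )
    except Exception as err:  # noqa: BLE001 - stage isolation
        logger.exception("masking stage failed")
        errors["masking"] = str(err)

    # --- stage: tracks -------------------------------------------------
    tracks = None
    try:
        if config.simulate:
            locs, _ = simulate_tracks(params, mask)
        else:
            locs = pd.read_csv(config.input_localizations)
        tracks = link_tracks(
            locs[["frame", "x_um", "y_um"]].assign(
                intensity=locs.get("intensity", 1.0)
            ),
            max_jump=config.max_jump,
            max_gap=config.max_gap,
        )
        tracks.to_csv(out / "tracks.csv", index=False)
        results["track_qc"] = track_qc(tracks).as_dict()
        first_frame = locs[locs["frame"] == locs["frame"].min()]
    except Exception as err:  # noqa: BLE001
        logger.exception("tracking stage failed")
        errors["tracking"] = str(err)
        first_frame = None

    # --- stage: exclusion ----------------------------------------------
    if mask is not None and first_frame is not None:
        try:
            dens = relative_density(first_frame, mask)
            results["exclusion"] = dataclasses.asdict(dens)
        except Exception as err:  # noqa: BLE001
            logger.exception("exclusion stage failed")
            errors["exclusion"] = str(err)

    # --- stage: energetics ---------------------------------------------
    if mask is not None and tracks is not None:
        try:
            tally = tally_crossings(
                tracks, mask, config.touch_band, config.min_frames_after
            )
            est_enter, est_exit = energy_penalty(tally)
            results["energetics"] = {
                "tally": dataclasses.asdict(tally),
                "enter": dataclasses.asdict(est_enter),
                "exit": dataclasses.asdict(est_exit),
            }
        except Exception as err:  # noqa: BLE001
            logger.exception("energetics stage failed")
            errors["energetics"] = str(err)

    # --- stage: diffusion ----------------------------------------------
    if tracks is not None:
        try:
            diff: dict = {}
            for region in (("inside", "outside") if mask is not None else ("all",)):
                jd = jump_distances(
                    tracks,
                    config.frame_interval,
                    None if region == "all" else region,
                    mask,
                )
                if len(jd) >= 50:
                    fit = fit_jd_cumulative(
                        jd,
                        sigma=config.sigma_loc,
                        n_bootstrap=config.n_bootstrap,
                        seed=config.seed,
                    )
                    diff[region] = dataclasses.asdict(fit)
            h, w = config.field_size[1], config.field_size[0]
            jmap = jd_map(tracks, (h, w), config.pixel_size)
            tifffile.imwrite(
                out / "jd_mean.tif", jmap.mean_jd.astype(np.float32)
            )
            tifffile.imwrite(
                out / "jd_count.tif", jmap.count.astype(np.int32)
            )
            if mask is not None:
                retention, n_inside = retention_fraction(tracks, mask)
                diff["retention"] = {
                    "fraction": retention,
                    "n_inside_tracks": n_inside,
                }
            results["diffusion"] = diff
        except Exception as err:  # noqa: BLE001
            logger.exception("diffusion stage failed")
            errors["diffusion"] = str(err)

    # --- stage: null comparison ----------------------------------------
    if mask is not None and tracks is not None and "energetics" in results:
        try:
            exp_stats = contact_stats(tracks, mask, settings)
            cfg = NullRunConfig(
                mask=mask,
                d=config.d_out,
                density=config.particle_density_out,
                n_frames=config.n_frames,
                dt=config.frame_interval,
                start_region="inside",
                n_repeats=config.null_repeats,
                seeds=[config.seed * 1000 + k for k in range(config.null_repeats)],
                sigma_loc=config.sigma_loc,
                survival_prob=config.survival_prob,
            )
            nstats = null_stats(cfg, settings)
            comparison = compare_to_null(exp_stats, nstats)
            comparison.to_csv(out / "null_comparison.csv", index=False)
            results["null_comparison"] = comparison.to_dict(orient="records")
        except Exception as err:  # noqa: BLE001
            logger.exception("null stage failed")
            errors["null"] = str(err)

    if errors:
        results["errors"] = errors
    (out / "results.json").write_text(
        json.dumps(results, indent=2, default=_json_default, sort_keys=True)
    )
    return results
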