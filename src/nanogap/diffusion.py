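"""Jump-distance diffusion analysis.

For free 2D Brownian motion observed at lag Dt with localization precision
sigma, the squared frame-to-frame jump distance r^2 follows the cumulative
distribution P(r^2) = 1 - exp(-r^2 / r0^2) with r0^2 = 4*D*Dt + 4*sigma^2.
Fitting the empirical CDF of the observed jumps yields r0^2 and hence D;
bootstrap resampling of the jumps gives confidence intervals.  sigma is
supplied rather than co-fitted: with single-lag data D and sigma are not
jointly identifiable.

Spatial variants: per-pixel mean-JD maps, spacer-intensity-zone fits
inside the contact, and the retention fraction of inside-starting tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .masking import ContactMask

__all__ = [
    "JDSet",
    "DiffusionFit",
    "JDMap",
    "jump_distances",
    "fit_jd_cumulative",
    "jd_map",
    "zone_diffusion",
    "retention_fraction",
]


@dataclass
class JDSet:
    """Jump distances (um) at a single lag with provenance."""

    r: np.ndarray
    dt: float
    region: str = "all"
    track_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if np.any(self.r < 0):
            raise ValueError("jump distances must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.r)


@dataclass(frozen=True)
class DiffusionFit:
    """Result of the cumulative jump-distance fit.

    ``r0_sq = 4 * D * dt + 4 * sigma**2`` holds exactly at the fitted
    point (D floored at zero); ``ci`` is the bootstrap (2.5%, 97.5%)
    interval on D.
    """

    r0_sq: float  # um^2
    d: float  # um^2/s
    sigma: float  # um
    dt: float  # s
    ci: tuple[float, float]
    n_jumps: int
    converged: bool = True
    flag: Optional[str] = None


@dataclass
class JDMap:
    """Per-pixel mean jump distance and jump count.

    Pixels never visited carry NaN in ``mean_jd``, never 0.0.
    """

    mean_jd: np.ndarray  # um, NaN where count == 0
    count: np.ndarray
    pixel_size: float

    @property
    def mean_speed(self) -> float:
        """Spatial mean of per-pixel mean JD divided by dt is left to the
        caller; this is the plain spatial mean JD over visited pixels."""
        return float(np.nanmean(self.mean_jd))


def _jumps(tracks: pd.DataFrame) -> pd.DataFrame:
    """Frame-to-frame jumps; pairs spanning a frame gap > 1 are excluded."""
    g = tracks.sort_values(["track_id", "frame"], kind="stable")
    same = g["track_id"].to_numpy()[1:] == g["track_id"].to_numpy()[:-1]
    consec = np.diff(g["frame"].to_numpy()) == 1
    ok = same & consec
    x = g["x_um"].to_numpy()
    y = g["y_um"].to_numpy()
    return pd.DataFrame(
        {
            "track_id": g["track_id"].to_numpy()[:-1][ok],
            "frame": g["frame"].to_numpy()[:-1][ok],
            "x_um": x[:-1][ok],  # starting localization
            "y_um": y[:-1][ok],
            "r": np.hypot(np.diff(x), np.diff(y))[ok],
        }
    )


def jump_distances(
    tracks: pd.DataFrame,
    dt: float,
    region_filter: Optional[str] = None,
    mask: Optional[ContactMask] = None,
) -> JDSet:
    """Euclidean frame-to-frame jump distances of a track set.

    A jump's region is the region of its *starting* localization;
    ``region_filter`` may be 'inside' or 'outside' (requires ``mask``).
    """
    jumps = _jumps(tracks)
    region = "all"
    if region_filter is not None:
        if mask is None:
            raise ValueError("region_filter requires a mask")
        if region_filter not in ("inside", "outside"):
            raise ValueError("region_filter must be 'inside' or 'outside'")
        inside = mask.contains(jumps["x_um"].to_numpy(), jumps["y_um"].to_numpy())
        jumps = jumps[inside if region_filter == "inside" else ~inside]
        region = region_filter
    return JDSet(
        r=jumps["r"].to_numpy(),
        dt=dt,
        region=region,
        track_ids=jumps["track_id"].to_numpy(),
    )


def _fit_r0_sq(r_sq: np.ndarray) -> float:
    """Nonlinear least squares of the empirical CDF of r^2."""
    r_sq = np.sort(r_sq)
    ecdf = (np.arange(1, len(r_sq) + 1) - 0.5) / len(r_sq)
    popt, _ = curve_fit(
        lambda rsq, r0sq: 1.0 - np.exp(-rsq / r0sq),
        r_sq,
        ecdf,
        p0=[max(r_sq.mean(), 1e-12)],
    )
    return float(popt[0])


def fit_jd_cumulative(
    jdset: JDSet,
    sigma: float = 0.03,
    n_bootstrap: int = 1000,
    min_jumps: int = 50,
    seed: int = 0,
) -> DiffusionFit:
    """Fit the cumulative jump-distance distribution for D.

    The empirical CDF of r^2 is fitted to 1 - exp(-r^2/r0^2) by nonlinear
    least squares; D = (r0^2 - 4*sigma^2) / (4*dt), floored at zero.
    Bootstrap resampling of the jumps (with replacement) yields the
    (2.5%, 97.5%) interval on D.
    """
    n = len(jdset)
    if n < min_jumps:
        raise ValueError(f"need >= {min_jumps} jumps, got {n}")
    r_sq = jdset.r**2

    def to_d(r0sq: float) -> float:
        return max((r0sq - 4.0 * sigma**2) / (4.0 * jdset.dt), 0.0)

    try:
        r0_sq = _fit_r0_sq(r_sq)
    except RuntimeError as err:  # non-convergence
        return DiffusionFit(
            np.nan, np.nan, sigma, jdset.dt, (np.nan, np.nan), n,
            converged=False, flag=str(err),
        )
    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sample = r_sq[rng.integers(0, n, n)]
        try:
            boot[b] = to_d(_fit_r0_sq(sample))
        except RuntimeError:
            boot[b] = np.nan
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    return DiffusionFit(
        r0_sq=r0_sq,
        d=to_d(r0_sq),
        sigma=sigma,
        dt=jdset.dt,
        ci=(float(lo), float(hi)),
        n_jumps=n,
    )


def jd_map(
    tracks: pd.DataFrame,
    shape: tuple[int, int],
    pixel_size: float,
) -> JDMap:
    """Per-pixel mean jump distance over the original pixel grid.

    Each jump is assigned to the pixel containing its starting
    localization; ``shape`` is (height, width).
    """
    jumps = _jumps(tracks)
    h, w = shape
    col = np.clip((jumps["x_um"].to_numpy() / pixel_size).astype(int), 0, w - 1)
    row = np.clip((jumps["y_um"].to_numpy() / pixel_size).astype(int), 0, h - 1)
    count = np.zeros((h, w), dtype=int)
    total = np.zeros((h, w), dtype=float)
    np.add.at(count, (row, col), 1)
    np.add.at(total, (row, col), jumps["r"].to_numpy())
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return JDMap(mean_jd=mean, count=count, pixel_size=pixel_size)


def zone_diffusion(
    tracks: pd.DataFrame,
    spacer_image: np.ndarray,
    mask: ContactMask,
    dt: float,
    n_zones: int = 4,
    sigma: float = 0.03,
    n_bootstrap: int = 1000,
    min_jumps: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Diffusion fits per spacer-intensity zone inside the contact.

    Contact pixels are binned into ``n_zones`` equal-count intensity
    quantile bins; jumps are assigned by their starting pixel's zone and
    fitted separately.  Zones with fewer than ``min_jumps`` jumps are
    flagged and carry NaN fits.

    Returns a DataFrame with one row per zone: zone, intensity_mean,
    n_jumps, d, ci_low, ci_high, r0_sq, flagged.
    """
    img = np.asarray(spacer_image, dtype=float)
    vals = img[mask.mask]
    edges = np.quantile(vals, np.linspace(0, 1, n_zones + 1))
    if len(np.unique(edges)) < n_zones + 1:
        raise ValueError(
            f"contact intensities do not support {n_zones} distinct quantile bins"
        )
    zone_img = np.full(img.shape, -1, dtype=int)
    zone_img[mask.mask] = np.clip(
        np.searchsorted(edges, vals, side="right") - 1, 0, n_zones - 1
    )
    jumps = _jumps(tracks)
    h, w = img.shape
    col = np.clip((jumps["x_um"].to_numpy() / mask.pixel_size).astype(int), 0, w - 1)
    row = np.clip((jumps["y_um"].to_numpy() / mask.pixel_size).astype(int), 0, h - 1)
    jump_zone = zone_img[row, col]
    rows = []
    for z in range(n_zones):
        sel = jump_zone == z
        r = jumps["r"].to_numpy()[sel]
        intensity_mean = float(vals[(zone_img[mask.mask] == z)].mean())
        if len(r) < min_jumps:
            rows.append(
                {
                    "zone": z,
                    "intensity_mean": intensity_mean,
                    "n_jumps": int(len(r)),
                    "d": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "r0_sq": np.nan,
                    "flagged": True,
                }
            )
            continue
        fit = fit_jd_cumulative(
            JDSet(r, dt, region=f"zone {z}"),
            sigma=sigma,
            n_bootstrap=n_bootstrap,
            min_jumps=min_jumps,
            seed=seed + z,
        )
        rows.append(
            {
                "zone": z,
                "intensity_mean": intensity_mean,
                "n_jumps": fit.n_jumps,
                "d": fit.d,
                "ci_low": fit.ci[0],
                "ci_high": fit.ci[1],
                "r0_sq": fit.r0_sq,
                "flagged": not fit.converged,
            }
        )
    return pd.DataFrame(rows)


def retention_fraction(
    tracks: pd.DataFrame, mask: ContactMask
) -> tuple[float, int]:
    """Fraction of inside-starting tracks that never leave the contact.

    Returns ``(fraction, n_inside_starting)``; the fraction is NaN when no
    track starts inside.
    """
    n_start = 0
    n_retained = 0
    for _, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        inside = mask.contains(g["x_um"].to_numpy(), g["y_um"].to_numpy())
        if inside[0]:
            n_start += 1
            n_retained += int(inside.all())
    if n_start == 0:
        return np.nan, 0
    return n_retained / n_start, n_start
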