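"""Synthetic ground-truth data: spacer images, Brownian tracks, movies.

Emulates a TIRF single-particle acquisition of probes diffusing in a
supported lipid bilayer under a cell contact: a spacer-protein channel
(elevated heterogeneous intensity over the contact) and probe tracks that
perform 2D Brownian motion with region-dependent diffusion, Boltzmann
energy barriers at the contact boundary, Gaussian localization noise,
geometric track lifetimes and stationary particle density.

The generative barrier mechanism: a step whose continuous segment crosses
the mask boundary inward is accepted with probability exp(-eps_enter),
outward with exp(-eps_exit); rejected steps are specularly reflected at
the boundary, which preserves the step-length distribution.  Only the
first boundary encounter within one frame interval is treated as a
proposal.  Every accepted/rejected proposal is recorded in the ground
truth so that downstream estimators can be validated against the exact
crossing statistics that generated the data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .masking import ContactMask

__all__ = [
    "SimulationParams",
    "DiskContact",
    "GroundTruth",
    "InvalidGeometryError",
    "generate_spacer_image",
    "simulate_tracks",
    "render_movie",
]


class InvalidGeometryError(ValueError):
    """Contact geometry does not fit the simulated field."""


@dataclass
class SimulationParams:
    """Physical and sampling parameters of one synthetic acquisition.

    Defaults reproduce the study conditions: 1000 frames at 30 ms exposure,
    probes diffusing at ~0.6 um^2/s in the free bilayer, per-frame survival
    0.93 giving mean track length ~14 frames, localization noise 0.03 um,
    and 0.16 um pixels (typical 100x EMCCD).
    """

    field_size: tuple[int, int] = (128, 128)  # (width, height) px
    pixel_size: float = 0.16  # um / px
    frame_interval: float = 0.03  # s
    n_frames: int = 1000
    d_out: float = 0.6  # um^2/s outside the contact
    d_in: float = 0.6  # um^2/s inside the contact
    d_map: Optional[np.ndarray] = None  # per-pixel D overriding d_in/d_out
    eps_enter: Union[float, np.ndarray] = 0.0  # kT
    eps_exit: Union[float, np.ndarray] = 0.0  # kT
    sigma_loc: float = 0.03  # um, per-axis localization noise
    particle_density_out: float = 0.5  # particles / um^2
    survival_prob: float = 0.93  # per-frame track continuation probability
    seed: int = 0

    def __post_init__(self) -> None:
        w, h = self.field_size
        if w < 32 or h < 32:
            raise ValueError("field dimensions must be >= 32 px")
        for name in ("pixel_size", "frame_interval"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be finite and positive")
        for name in ("d_out", "d_in", "sigma_loc", "particle_density_out"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        for name in ("eps_enter", "eps_exit"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{name} must be finite and >= 0")
        if not 0.0 < self.survival_prob <= 1.0:
            raise ValueError("survival_prob must be in (0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.d_map is not None:
            d_map = np.asarray(self.d_map, dtype=float)
            if d_map.shape != (h, w):
                raise ValueError("d_map shape must be (height, width)")
            if not np.all(np.isfinite(d_map)) or np.any(d_map < 0):
                raise ValueError("d_map must be finite and >= 0")
            self.d_map = d_map

    @property
    def field_um(self) -> tuple[float, float]:
        """(width, height) of the field in um."""
        w, h = self.field_size
        return w * self.pixel_size, h * self.pixel_size


@dataclass(frozen=True)
class DiskContact:
    """Disk-shaped contact descriptor; default radius 6 um, centred."""

    radius_um: float = 6.0
    center_um: Optional[tuple[float, float]] = None  # (x, y); None = centre


@dataclass
class GroundTruth:
    """Exact state of one simulation run.

    positions
        True (noise-free) particle positions: columns track_id, frame,
        x_um, y_um, inside.
    proposals
        One row per boundary proposal: frame, track_id, direction
        ('enter'/'exit'), accepted, x_um, y_um (crossing point).
    params
        Copy of the generating :class:`SimulationParams`.
    """

    positions: pd.DataFrame
    proposals: pd.DataFrame
    params: SimulationParams


# ---------------------------------------------------------------------------
# Spacer-channel image
# ---------------------------------------------------------------------------

def generate_spacer_image(
    params: SimulationParams,
    contact_shape: DiskContact | None = None,
    background: float = 100.0,
    contact_amplitude: float = 150.0,
    heterogeneity_amplitude: float = 0.3,
    heterogeneity_scale_px: float = 4.0,
    noise_sd: float = 5.0,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, ContactMask]:
    """Synthesize a spacer-channel image and its exact contact mask.

    The image is a uniform bilayer background plus a contact region whose
    mean intensity is elevated by ``contact_amplitude`` and modulated by a
    smoothed Gaussian random field (relative sd ``heterogeneity_amplitude``,
    correlation length ``heterogeneity_scale_px``), plus white camera noise.
    Intensities are clipped at zero.

    Returns ``(image, true_mask)``.
    """
    contact_shape = contact_shape or DiskContact()
    w, h = params.field_size
    ps = params.pixel_size
    cx, cy = contact_shape.center_um or (w * ps / 2.0, h * ps / 2.0)
    r = contact_shape.radius_um
    if r <= 0:
        raise InvalidGeometryError("contact radius must be positive")
    if cx - r < 0 or cy - r < 0 or cx + r > w * ps or cy + r > h * ps:
        raise InvalidGeometryError("contact region does not fit within the field")

    yy, xx = np.mgrid[0:h, 0:w]
    # pixel-centre coordinates in um
    px_x = (xx + 0.5) * ps
    px_y = (yy + 0.5) * ps
    mask = (px_x - cx) ** 2 + (px_y - cy) ** 2 <= r**2

    rng = np.random.default_rng(params.seed if seed is None else seed)
    image = np.full((h, w), background, dtype=float)
    if heterogeneity_amplitude > 0:
        het = ndimage.gaussian_filter(
            rng.standard_normal((h, w)), heterogeneity_scale_px
        )
        sd = het.std()
        het = het / sd if sd > 0 else het
    else:
        het = np.zeros((h, w))
    image[mask] += contact_amplitude * (
        1.0 + heterogeneity_amplitude * het[mask]
    )
    if noise_sd > 0:
        image += rng.normal(0.0, noise_sd, size=(h, w))
    np.clip(image, 0.0, None, out=image)

    true_mask = ContactMask(
        mask=mask,
        pixel_size=ps,
        provenance={"synthetic": True, "shape": dataclasses.asdict(contact_shape)},
    )
    return image, true_mask


# ---------------------------------------------------------------------------
# Brownian dynamics with boundary barriers
# ---------------------------------------------------------------------------

def _sample_region(
    rng: np.random.Generator,
    n: int,
    field_um: tuple[float, float],
    mask: Optional[ContactMask],
    region: str,
) -> np.ndarray:
    """Uniform positions in the field restricted to a region."""
    lx, ly = field_um
    pos = np.column_stack([rng.uniform(0, lx, n), rng.uniform(0, ly, n)])
    if region == "uniform" or mask is None:
        return pos
    want_inside = region == "inside"
    for _ in range(1000):
        inside = mask.contains(pos[:, 0], pos[:, 1])
        bad = np.flatnonzero(inside != want_inside)
        if bad.size == 0:
            return pos
        pos[bad, 0] = rng.uniform(0, lx, bad.size)
        pos[bad, 1] = rng.uniform(0, ly, bad.size)
    raise RuntimeError(f"could not sample positions in region {region!r}")


def _reflect_into_field(xy: np.ndarray, field_um: tuple[float, float]) -> np.ndarray:
    """Mirror coordinates at the field edges (applied twice for safety)."""
    out = xy.copy()
    for axis, lim in enumerate(field_um):
        for _ in range(2):
            out[:, axis] = np.where(out[:, axis] < 0, -out[:, axis], out[:, axis])
            out[:, axis] = np.where(
                out[:, axis] > lim, 2 * lim - out[:, axis], out[:, axis]
            )
        out[:, axis] = np.clip(out[:, axis], 0.0, np.nextafter(lim, 0.0))
    return out


def simulate_tracks(
    params: SimulationParams,
    mask: Optional[ContactMask] = None,
    seed: Optional[int] = None,
    init_region: str = "uniform",
    n_particles: Optional[int] = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate probe tracks over a contact mask.

    Per frame each particle takes an isotropic Gaussian step with per-axis
    sd sqrt(2 * D_local * frame_interval).  Steps whose segment crosses the
    mask boundary are accepted with the Boltzmann factor for the crossing
    direction, otherwise specularly reflected.  Reported positions carry
    independent Gaussian localization noise; tracks end with per-frame
    probability 1 - survival_prob and are replaced by fresh particles in
    ``init_region`` to keep the density stationary.

    Parameters
    ----------
    mask
        Contact mask on the same pixel grid as ``params.field_size``; pass
        ``None`` for a barrier-free homogeneous field (all "outside").
    init_region
        'uniform' (whole field), 'outside' or 'inside' -- initial placement
        and respawn region.
    n_particles
        Override the particle count; default derives it from
        ``particle_density_out`` times the area of ``init_region``.

    Returns
    -------
    (localizations, ground_truth)
        ``localizations`` has columns track_id, frame, x_um, y_um,
        intensity (reported, noisy positions).
    """
    if init_region not in ("uniform", "outside", "inside"):
        raise ValueError("init_region must be 'uniform', 'outside' or 'inside'")
    w, h = params.field_size
    ps = params.pixel_size
    if mask is not None:
        if mask.shape != (h, w):
            raise ValueError("mask grid does not match field geometry")
        if abs(mask.pixel_size - ps) > 1e-12:
            raise ValueError("mask pixel size does not match params")
    field_um = params.field_um
    dt = params.frame_interval
    rng = np.random.default_rng(params.seed if seed is None else seed)

    mask_arr = mask.mask if mask is not None else np.zeros((h, w), dtype=bool)

    def inside_of(xy: np.ndarray) -> np.ndarray:
        col = np.clip((xy[:, 0] / ps).astype(int), 0, w - 1)
        row = np.clip((xy[:, 1] / ps).astype(int), 0, h - 1)
        return mask_arr[row, col]

    # local diffusion coefficient at positions
    if params.d_map is not None:
        d_map = params.d_map

        def local_d(xy: np.ndarray) -> np.ndarray:
            col = np.clip((xy[:, 0] / ps).astype(int), 0, w - 1)
            row = np.clip((xy[:, 1] / ps).astype(int), 0, h - 1)
            return d_map[row, col]

        d_max = float(d_map.max(initial=0.0))
    else:

        def local_d(xy: np.ndarray) -> np.ndarray:
            return np.where(inside_of(xy), params.d_in, params.d_out)

        d_max = max(params.d_in, params.d_out)

    def eps_at(direction_enter: np.ndarray, xy: np.ndarray) -> np.ndarray:
        out = np.empty(len(xy))
        for val, sel in (
            (params.eps_enter, direction_enter),
            (params.eps_exit, ~direction_enter),
        ):
            arr = np.asarray(val, dtype=float)
            if arr.ndim == 0:
                out[sel] = float(arr)
            else:
                col = np.clip((xy[sel, 0] / ps).astype(int), 0, w - 1)
                row = np.clip((xy[sel, 1] / ps).astype(int), 0, h - 1)
                out[sel] = arr[row, col]
        return out

    # boundary-normal field from the smoothed mask gradient
    smooth = ndimage.gaussian_filter(mask_arr.astype(float), 1.5)
    gy, gx = np.gradient(smooth)
    norm = np.hypot(gx, gy)
    norm[norm == 0] = 1.0
    nx, ny = gx / norm, gy / norm

    # number of sample points along each step segment (crossing detection on
    # the continuous segment, not endpoint pixels, to avoid tunnelling)
    step_sd = np.sqrt(2.0 * max(d_max, 1e-12) * dt)
    n_seg = int(np.clip(np.ceil(4.0 * step_sd / (0.3 * ps)) + 1, 3, 40))
    seg_t = np.linspace(0.0, 1.0, n_seg)

    if n_particles is None:
        if init_region == "uniform" or mask is None:
            area = field_um[0] * field_um[1]
        elif init_region == "inside":
            area = mask.area_um2
        else:
            area = mask.field_area_um2 - mask.area_um2
        n_particles = max(1, int(round(params.particle_density_out * area)))

    pos = _sample_region(rng, n_particles, field_um, mask, init_region)
    track_id = np.arange(n_particles, dtype=np.int64)
    next_id = n_particles

    rec_frame, rec_id, rec_xy, rec_inside = [], [], [], []
    prop_rows: list[tuple[int, int, str, bool, float, float]] = []

    for frame in range(params.n_frames):
        rec_frame.append(np.full(n_particles, frame, dtype=np.int32))
        rec_id.append(track_id.copy())
        rec_xy.append(pos.copy())
        rec_inside.append(inside_of(pos))

        if frame == params.n_frames - 1:
            break

        # --- propose steps ------------------------------------------------
        d_local = local_d(pos)
        steps = rng.standard_normal((n_particles, 2)) * np.sqrt(
            2.0 * d_local * dt
        )[:, None]
        prop = _reflect_into_field(pos + steps, field_um)

        # --- boundary crossings on the continuous segment ----------------
        seg = pos[:, None, :] * (1 - seg_t)[None, :, None] + prop[
            :, None, :
        ] * seg_t[None, :, None]
        col = np.clip((seg[:, :, 0] / ps).astype(int), 0, w - 1)
        row = np.clip((seg[:, :, 1] / ps).astype(int), 0, h - 1)
        lab = mask_arr[row, col]
        diff = lab != lab[:, :1]
        crossing = diff.any(axis=1)
        final = prop
        if crossing.any():
            idx = np.flatnonzero(crossing)
            j = diff[idx].argmax(axis=1)
            entering = ~lab[idx, 0]
            c_prev = seg[idx, j - 1, :]
            c_mid = 0.5 * (c_prev + seg[idx, j, :])
            eps = eps_at(entering, c_mid)
            accepted = rng.random(idx.size) < np.exp(-eps)
            for k in range(idx.size):
                prop_rows.append(
                    (
                        frame,
                        int(track_id[idx[k]]),
                        "enter" if entering[k] else "exit",
                        bool(accepted[k]),
                        float(c_mid[k, 0]),
                        float(c_mid[k, 1]),
                    )
                )
            rej = idx[~accepted]
            if rej.size:
                c_prev_r = c_prev[~accepted]
                c_mid_r = c_mid[~accepted]
                pc = np.clip((c_mid_r[:, 0] / ps).astype(int), 0, w - 1)
                pr = np.clip((c_mid_r[:, 1] / ps).astype(int), 0, h - 1)
                n_vec = np.column_stack([nx[pr, pc], ny[pr, pc]])
                v = prop[rej] - c_mid_r
                v_ref = v - 2.0 * (v * n_vec).sum(axis=1, keepdims=True) * n_vec
                cand = _reflect_into_field(c_prev_r + v_ref, field_um)
                ok = inside_of(cand) == lab[rej, 0]
                cand[~ok] = c_prev_r[~ok]
                final = final.copy() if final is prop else final
                final[rej] = cand
        pos = final

        # --- deaths and births -------------------------------------------
        dead = rng.random(n_particles) >= params.survival_prob
        n_dead = int(dead.sum())
        if n_dead:
            pos[dead] = _sample_region(rng, n_dead, field_um, mask, init_region)
            track_id[dead] = np.arange(next_id, next_id + n_dead)
            next_id += n_dead

    frames = np.concatenate(rec_frame)
    ids = np.concatenate(rec_id)
    xy = np.concatenate(rec_xy, axis=0)
    inside = np.concatenate(rec_inside)

    noisy = xy + rng.normal(0.0, params.sigma_loc, size=xy.shape)
    intensity = rng.normal(1000.0, 50.0, size=len(ids))

    order = np.lexsort((frames, ids))
    locs = pd.DataFrame(
        {
            "track_id": ids[order],
            "frame": frames[order],
            "x_um": noisy[order, 0],
            "y_um": noisy[order, 1],
            "intensity": intensity[order],
        }
    )
    truth_positions = pd.DataFrame(
        {
            "track_id": ids[order],
            "frame": frames[order],
            "x_um": xy[order, 0],
            "y_um": xy[order, 1],
            "inside": inside[order],
        }
    )
    proposals = pd.DataFrame(
        prop_rows,
        columns=["frame", "track_id", "direction", "accepted", "x_um", "y_um"],
    )
    return locs, GroundTruth(
        positions=truth_positions, proposals=proposals, params=params
    )


# ---------------------------------------------------------------------------
# Movie rendering
# ---------------------------------------------------------------------------

def render_movie(
    tracks: pd.DataFrame,
    params: SimulationParams,
    psf_sigma: float = 0.16,
    photon_count: float = 500.0,
    background: float = 10.0,
    noise_seed: int = 0,
) -> np.ndarray:
    """Render localizations as Gaussian spots into a noisy image stack.

    Each localization becomes a 2D Gaussian of integrated intensity
    ``photon_count`` and width ``psf_sigma`` (um); Poisson noise is applied
    to spot + background.  Returns a float stack of shape
    (n_frames, height, width).
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    w, h = params.field_size
    ps = params.pixel_size
    lx, ly = params.field_um
    if len(tracks) and (
        (tracks["x_um"] < 0).any()
        or (tracks["y_um"] < 0).any()
        or (tracks["x_um"] >= lx).any()
        or (tracks["y_um"] >= ly).any()
    ):
        raise ValueError("tracks contain localizations outside the field")
    stack = np.full((params.n_frames, h, w), background, dtype=float)
    sigma_px = psf_sigma / ps
    half = max(2, int(np.ceil(4 * sigma_px)))
    for frame, x, y in zip(tracks["frame"], tracks["x_um"], tracks["y_um"]):
        if frame >= params.n_frames:
            continue
        cx, cy = x / ps, y / ps
        x0, x1 = int(cx) - half, int(cx) + half + 1
        y0, y1 = int(cy) - half, int(cy) + half + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        xs = np.arange(x0c, x1c) + 0.5
        ys = np.arange(y0c, y1c) + 0.5
        gx = np.exp(-((xs - cx) ** 2) / (2 * sigma_px**2))
        gy = np.exp(-((ys - cy) ** 2) / (2 * sigma_px**2))
        spot = photon_count / (2 * np.pi * sigma_px**2) * np.outer(gy, gx)
        stack[int(frame), y0c:y1c, x0c:x1c] += spot
    rng = np.random.default_rng(noise_seed)
    return rng.poisson(stack).astype(float)
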