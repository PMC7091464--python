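"""Spot detection and track linking for the probe channel.

Detection: local maxima above a robust threshold (frame median + k * MAD),
refined to sub-pixel position by the intensity centroid of a 5x5 window.
Linking: greedy mutual-nearest-neighbour frame-to-frame assignment within a
maximum jump, appropriate at the low particle densities used.  Tracks with
more than five localizations are retained, matching the track-length filter
applied to the experimental recordings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

__all__ = [
    "MIN_TRACK_LENGTH",
    "detect_peaks",
    "detect_stack",
    "link_tracks",
    "track_qc",
    "TrackSummary",
]

#: retained tracks must be longer than five frames, i.e. >= 6 localizations
MIN_TRACK_LENGTH = 6


def detect_peaks(
    frame_image: np.ndarray,
    min_separation: int = 4,
    threshold_k: float = 5.0,
    pixel_size: float = 0.16,
    frame: int = 0,
) -> pd.DataFrame:
    """Detect spots in a single frame.

    Local maxima at least ``min_separation`` px apart whose intensity
    exceeds ``median + threshold_k * sigma`` -- with sigma the robust
    noise scale 1.4826 * MAD -- are kept and refined by the
    background-subtracted centroid of the surrounding 5x5 window.

    Returns a DataFrame with columns frame, x_um, y_um, intensity, score
    (possibly empty).
    """
    img = np.asarray(frame_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D frame image")
    med = np.median(img)
    sigma = 1.4826 * np.median(np.abs(img - med))  # robust noise scale
    thr = med + threshold_k * sigma
    coords = peak_local_max(
        img, min_distance=min_separation, threshold_abs=thr, exclude_border=False
    )
    rows = []
    h, w = img.shape
    for r, c in coords:
        y0, y1 = max(r - 2, 0), min(r + 3, h)
        x0, x1 = max(c - 2, 0), min(c + 3, w)
        win = img[y0:y1, x0:x1] - med
        win = np.clip(win, 0, None)
        total = win.sum()
        if total <= 0:
            cy, cx = float(r), float(c)
        else:
            ys, xs = np.mgrid[y0:y1, x0:x1]
            cy = float((ys * win).sum() / total)
            cx = float((xs * win).sum() / total)
        rows.append(
            {
                "frame": frame,
                "x_um": (cx + 0.5) * pixel_size,
                "y_um": (cy + 0.5) * pixel_size,
                "intensity": float(img[r, c]),
                "score": float((img[r, c] - med) / sigma) if sigma > 0 else np.inf,
            }
        )
    return pd.DataFrame(
        rows, columns=["frame", "x_um", "y_um", "intensity", "score"]
    )


def detect_stack(
    stack: np.ndarray,
    min_separation: int = 4,
    threshold_k: float = 5.0,
    pixel_size: float = 0.16,
) -> pd.DataFrame:
    """Run :func:`detect_peaks` on every frame of a stack."""
    parts = [
        detect_peaks(stack[f], min_separation, threshold_k, pixel_size, frame=f)
        for f in range(stack.shape[0])
    ]
    return pd.concat(parts, ignore_index=True)


def link_tracks(
    localizations: pd.DataFrame,
    max_jump: float = 0.8,
    max_gap: int = 0,
    min_length: int = MIN_TRACK_LENGTH,
) -> pd.DataFrame:
    """Link localizations into tracks by mutual nearest neighbours.

    Frame-to-frame assignment pairs detections that are each other's
    nearest neighbour within ``max_jump`` (um).  Track ends stay eligible
    for ``max_gap`` further frames; unmatched detections seed new tracks.
    Tracks shorter than ``min_length`` localizations are discarded.

    Returns a DataFrame with columns track_id, frame, x_um, y_um plus any
    extra input columns, sorted by (track_id, frame).
    """
    if len(localizations) == 0:
        return localizations.assign(track_id=np.array([], dtype=np.int64))
    locs = localizations.sort_values("frame", kind="stable").reset_index(drop=True)
    dup = locs.duplicated(subset=["frame", "x_um", "y_um"])
    if dup.any():
        warnings.warn(
            f"removed {int(dup.sum())} duplicate (frame, position) entries",
            stacklevel=2,
        )
        locs = locs[~dup].reset_index(drop=True)

    track_of = np.full(len(locs), -1, dtype=np.int64)
    next_track = 0
    # open track ends: track id -> (row index of last loc, frame of last loc)
    open_ends: dict[int, tuple[int, int]] = {}
    for frame, group in locs.groupby("frame", sort=True):
        gi = group.index.to_numpy()
        pts = group[["x_um", "y_um"]].to_numpy()
        # drop ends that have been silent for longer than max_gap
        open_ends = {
            t: (i, f) for t, (i, f) in open_ends.items() if frame - f <= max_gap + 1
        }
        assigned = np.zeros(len(gi), dtype=bool)
        if open_ends and len(gi):
            end_items = list(open_ends.items())
            end_pts = locs.loc[[i for _, (i, _) in end_items], ["x_um", "y_um"]].to_numpy()
            tree_prev = cKDTree(end_pts)
            tree_new = cKDTree(pts)
            d_new, nn_prev = tree_prev.query(pts, distance_upper_bound=max_jump)
            d_prev, nn_new = tree_new.query(end_pts, distance_upper_bound=max_jump)
            for k in range(len(gi)):
                p = nn_prev[k]
                if np.isinf(d_new[k]) or p >= len(end_items):
                    continue
                if nn_new[p] == k:  # mutual nearest neighbours
                    t = end_items[p][0]
                    track_of[gi[k]] = t
                    open_ends[t] = (int(gi[k]), int(frame))
                    assigned[k] = True
        for k in np.flatnonzero(~assigned):
            track_of[gi[k]] = next_track
            open_ends[next_track] = (int(gi[k]), int(frame))
            next_track += 1

    out = locs.assign(track_id=track_of)
    lengths = out.groupby("track_id")["frame"].transform("size")
    out = out[lengths >= min_length]
    cols = ["track_id"] + [c for c in out.columns if c != "track_id"]
    return (
        out[cols]
        .sort_values(["track_id", "frame"], kind="stable")
        .reset_index(drop=True)
    )


@dataclass(frozen=True)
class TrackSummary:
    """Quality-control summary of a track set."""

    n_tracks: int
    mean_length: float
    sd_length: float
    mean_step_um: float

    def as_dict(self) -> dict:
        return {
            "n_tracks": self.n_tracks,
            "mean_length": self.mean_length,
            "sd_length": self.sd_length,
            "mean_step_um": self.mean_step_um,
        }


def track_qc(tracks: pd.DataFrame) -> TrackSummary:
    """Track count, mean +/- sd track length and mean per-track step."""
    if len(tracks) == 0:
        return TrackSummary(0, np.nan, np.nan, np.nan)
    lengths = tracks.groupby("track_id").size().to_numpy()
    steps = []
    for _, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        dx = np.diff(g["x_um"].to_numpy())
        dy = np.diff(g["y_um"].to_numpy())
        consec = np.diff(g["frame"].to_numpy()) == 1
        if consec.any():
            steps.append(np.hypot(dx[consec], dy[consec]).mean())
    return TrackSummary(
        n_tracks=int(len(lengths)),
        mean_length=float(lengths.mean()),
        sd_length=float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0,
        mean_step_um=float(np.mean(steps)) if steps else np.nan,
    )
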