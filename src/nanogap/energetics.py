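"""Boltzmann energy penalties for contact entry and exit.

Tracks are categorized relative to the contact mask (staying outside,
entering, staying inside, exiting; "deflected" refines outside-staying
tracks that touched the border).  Success fractions p = n_success /
n_attempts of boundary-crossing attempts convert to energy penalties
eps = -ln(p) in kT via the Boltzmann distribution, with Clopper-Pearson
confidence intervals propagated through the log.

Two attempt-counting schemes are provided:

``step`` (default)
    Each frame-to-frame step from one side is an attempt when it either
    flips side (success) or stays on its side while passing within the
    touch band of the boundary (failure).  Steps with an endpoint closer
    to the boundary than ``noise_margin`` are discarded as ambiguous:
    localization noise can flip the apparent side of such points, and the
    spurious flips would otherwise contaminate the success counts.  With
    this scheme the attempt denominator is outcome-independent, so the
    estimate is the true penalty plus an additive sampling baseline that
    cancels when the barrier-free null baseline is subtracted.

``episode``
    A maximal contiguous run of localizations within the touch band is
    one attempt from the side the track approached on; it succeeds when
    the first localization after the run lies on the opposite side, and a
    jump straight across the band is one successful attempt.  This
    matches intuitive per-approach counting, but a particle reflected at
    the boundary can retry within the same episode, and rejected fast
    attempts leave no in-band localization at all, so its bias does not
    cancel against the null baseline.  It is kept for descriptive use.

Estimated penalties should always be interpreted relative to a matched
barrier-free null simulation (the baseline is reported alongside, never
silently subtracted).  Attempts by a single track are treated as
independent Bernoulli trials for the confidence intervals (a stated
limitation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .masking import ContactMask

__all__ = [
    "TRACK_CATEGORIES",
    "CrossingTally",
    "EnergyEstimate",
    "DEFAULT_TOUCH_BAND",
    "MIN_FRAMES_AFTER_TOUCH",
    "categorize_tracks",
    "crossing_events",
    "tally_crossings",
    "energy_penalty",
    "breach_zones",
]

TRACK_CATEGORIES = ("outside_stay", "enter", "inside_stay", "exit")

#: default touch band, one pixel at the default pixel size (um)
DEFAULT_TOUCH_BAND = 0.16
#: tracks need at least this many localizations after first touching the
#: border to enter the tallies (avoids bias toward unresolved attempts)
MIN_FRAMES_AFTER_TOUCH = 5
#: half-width (um) of the ambiguity zone around the boundary within which
#: localization noise can flip the apparent side (~3x typical precision)
DEFAULT_NOISE_MARGIN = 0.09


@dataclass(frozen=True)
class CrossingTally:
    """Attempt/success counts for boundary crossings in both directions."""

    n_attempts_enter: int
    n_success_enter: int
    n_attempts_exit: int
    n_success_exit: int

    def __post_init__(self) -> None:
        for d in ("enter", "exit"):
            na = getattr(self, f"n_attempts_{d}")
            ns = getattr(self, f"n_success_{d}")
            if not 0 <= ns <= na:
                raise ValueError("success counts must satisfy 0 <= ns <= na")

    @property
    def p_enter(self) -> float:
        return (
            self.n_success_enter / self.n_attempts_enter
            if self.n_attempts_enter
            else np.nan
        )

    @property
    def p_exit(self) -> float:
        return (
            self.n_success_exit / self.n_attempts_exit
            if self.n_attempts_exit
            else np.nan
        )


@dataclass(frozen=True)
class EnergyEstimate:
    """Energy penalty (kT) for one crossing direction with 95% CI.

    ``censored`` marks the zero-success case, where only the lower bound
    ln(n_attempts) is informative.
    """

    direction: str
    n_attempts: int
    n_success: int
    eps: float
    ci_low: float
    ci_high: float
    censored: bool = False
    flag: Optional[str] = None


def _sides_and_band(
    track: pd.DataFrame, mask: ContactMask, touch_band: float
) -> tuple[np.ndarray, np.ndarray]:
    x = track["x_um"].to_numpy()
    y = track["y_um"].to_numpy()
    side = mask.contains(x, y)  # True = inside
    band = mask.distance_to_boundary(x, y) <= touch_band
    return side, band


def categorize_tracks(
    tracks: pd.DataFrame,
    mask: ContactMask,
    touch_band: float = DEFAULT_TOUCH_BAND,
) -> pd.DataFrame:
    """Assign each track one of the four primary categories.

    The category follows from the sides of the first and last localization:
    outside/outside -> outside_stay, outside/inside -> enter,
    inside/inside -> inside_stay, inside/outside -> exit.  A ``deflected``
    flag refines outside_stay tracks that had >= 1 localization within the
    touch band of the boundary.  Tracks whose localizations all lie within
    the band are categorized by their first localization's side and flagged
    ``ambiguous``.

    Returns a DataFrame indexed by track_id with columns category,
    deflected, ambiguous.
    """
    rows = []
    for tid, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        side, band = _sides_and_band(g, mask, touch_band)
        first, last = bool(side[0]), bool(side[-1])
        if not first and not last:
            cat = "outside_stay"
        elif not first and last:
            cat = "enter"
        elif first and last:
            cat = "inside_stay"
        else:
            cat = "exit"
        rows.append(
            {
                "track_id": tid,
                "category": cat,
                "deflected": cat == "outside_stay" and bool(band.any()),
                "ambiguous": bool(band.all()),
            }
        )
    return pd.DataFrame(rows).set_index("track_id")


def _events_step(
    side: np.ndarray,
    dist: np.ndarray,
    frames: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    touch_band: float,
    noise_margin: float,
    tid,
    rows: list,
) -> None:
    for i in range(len(side) - 1):
        if frames[i + 1] - frames[i] != 1:
            continue
        if dist[i] <= noise_margin or dist[i + 1] <= noise_margin:
            continue  # apparent side unreliable under localization noise
        if side[i + 1] != side[i]:
            success = True
        elif min(dist[i], dist[i + 1]) <= touch_band:
            success = False
        else:
            continue
        rows.append(
            {
                "track_id": tid,
                "direction": "exit" if side[i] else "enter",
                "success": success,
                "x_um": float(0.5 * (x[i] + x[i + 1])),
                "y_um": float(0.5 * (y[i] + y[i + 1])),
            }
        )


def _events_episode(
    side: np.ndarray,
    band: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    tid,
    rows: list,
) -> None:
    n = len(side)
    i = 0
    while i < n:
        if band[i]:
            j = i
            while j < n and band[j]:
                j += 1
            s_before = side[i - 1] if i > 0 else side[i]
            if j < n:  # resolved episode
                rows.append(
                    {
                        "track_id": tid,
                        "direction": "exit" if s_before else "enter",
                        "success": bool(side[j] != s_before),
                        "x_um": float(x[i]),
                        "y_um": float(y[i]),
                    }
                )
            i = j
        else:
            if i > 0 and not band[i - 1] and side[i] != side[i - 1]:
                # jump fully across the band: one successful attempt
                rows.append(
                    {
                        "track_id": tid,
                        "direction": "exit" if side[i - 1] else "enter",
                        "success": True,
                        "x_um": float(0.5 * (x[i - 1] + x[i])),
                        "y_um": float(0.5 * (y[i - 1] + y[i])),
                    }
                )
            i += 1


def crossing_events(
    tracks: pd.DataFrame,
    mask: ContactMask,
    touch_band: float = DEFAULT_TOUCH_BAND,
    min_frames_after: int = MIN_FRAMES_AFTER_TOUCH,
    mode: str = "step",
    noise_margin: float = DEFAULT_NOISE_MARGIN,
) -> pd.DataFrame:
    """Enumerate boundary-crossing attempts and their outcomes.

    Tracks with fewer than ``min_frames_after`` localizations recorded
    after first touching the border are excluded entirely.  ``mode``
    selects the attempt-counting scheme ('step' or 'episode', see module
    docstring); unresolved episodes at track end contribute no attempt.

    Returns a DataFrame with one row per attempt: track_id, direction
    ('enter'/'exit'), success, x_um, y_um (representative boundary
    position).
    """
    if touch_band < 0:
        raise ValueError("touch_band must be >= 0")
    if mode not in ("step", "episode"):
        raise ValueError("mode must be 'step' or 'episode'")
    rows: list[dict] = []
    for tid, g in tracks.groupby("track_id"):
        g = g.sort_values("frame")
        side, band = _sides_and_band(g, mask, touch_band)
        n = len(g)
        x = g["x_um"].to_numpy()
        y = g["y_um"].to_numpy()
        frames = g["frame"].to_numpy()
        # first contact with the border: in-band localization or side flip
        touch_idx = None
        for i in range(n):
            if band[i] or (i > 0 and side[i] != side[i - 1]):
                touch_idx = i
                break
        if touch_idx is None:
            continue
        if n - 1 - touch_idx < min_frames_after:
            continue
        if mode == "step":
            dist = mask.distance_to_boundary(x, y)
            _events_step(
                side, dist, frames, x, y, touch_band, noise_margin, tid, rows
            )
        else:
            _events_episode(side, band, x, y, tid, rows)
    return pd.DataFrame(
        rows, columns=["track_id", "direction", "success", "x_um", "y_um"]
    )


def tally_crossings(
    tracks: pd.DataFrame,
    mask: ContactMask,
    touch_band: float = DEFAULT_TOUCH_BAND,
    min_frames_after: int = MIN_FRAMES_AFTER_TOUCH,
    mode: str = "step",
    noise_margin: float = DEFAULT_NOISE_MARGIN,
) -> CrossingTally:
    """Accumulate entry/exit attempt and success counts over all tracks."""
    ev = crossing_events(tracks, mask, touch_band, min_frames_after, mode, noise_margin)
    ent = ev[ev["direction"] == "enter"]
    ext = ev[ev["direction"] == "exit"]
    return CrossingTally(
        n_attempts_enter=len(ent),
        n_success_enter=int(ent["success"].sum()),
        n_attempts_exit=len(ext),
        n_success_exit=int(ext["success"].sum()),
    )


def _one_direction(
    direction: str, n_attempts: int, n_success: int, confidence: float
) -> EnergyEstimate:
    if n_attempts < 1:
        return EnergyEstimate(
            direction, 0, 0, np.nan, np.nan, np.nan, flag="no attempts"
        )
    alpha = 1.0 - confidence
    p = n_success / n_attempts
    # Clopper-Pearson interval on p
    p_lo = (
        0.0
        if n_success == 0
        else stats.beta.ppf(alpha / 2, n_success, n_attempts - n_success + 1)
    )
    p_hi = (
        1.0
        if n_success == n_attempts
        else stats.beta.ppf(1 - alpha / 2, n_success + 1, n_attempts - n_success)
    )
    if n_success == 0:
        # censored: only the lower bound -ln(1/n) is informative
        return EnergyEstimate(
            direction,
            n_attempts,
            0,
            np.inf,
            np.log(n_attempts),
            np.inf,
            censored=True,
            flag="zero successes",
        )
    return EnergyEstimate(
        direction,
        n_attempts,
        n_success,
        -np.log(p),
        -np.log(p_hi),
        np.inf if p_lo == 0 else -np.log(p_lo),
    )


def energy_penalty(
    tally: CrossingTally, confidence: float = 0.95
) -> tuple[EnergyEstimate, EnergyEstimate]:
    """Convert a crossing tally to (enter, exit) energy penalties in kT."""
    return (
        _one_direction(
            "enter", tally.n_attempts_enter, tally.n_success_enter, confidence
        ),
        _one_direction(
            "exit", tally.n_attempts_exit, tally.n_success_exit, confidence
        ),
    )


def baseline_corrected(
    estimate: EnergyEstimate, baseline: EnergyEstimate
) -> tuple[float, float, float]:
    """Energy penalty relative to a barrier-free null baseline.

    Returns ``(corrected, ci_low, ci_high)`` where corrected =
    estimate.eps - baseline.eps and the 95% interval combines both
    binomial sampling variances by the delta method on -ln(p).
    """
    for e in (estimate, baseline):
        if e.n_attempts < 1 or e.n_success < 1:
            raise ValueError("baseline correction needs successes on both sides")
    var = 0.0
    for e in (estimate, baseline):
        p = e.n_success / e.n_attempts
        var += (1.0 - p) / (p * e.n_attempts)
    half = 1.96 * np.sqrt(var)
    corrected = estimate.eps - baseline.eps
    return corrected, corrected - half, corrected + half


def breach_zones(
    tracks: pd.DataFrame,
    mask: ContactMask,
    spacer_image: np.ndarray,
    segment_length: float = 1.0,
    touch_band: float = DEFAULT_TOUCH_BAND,
    min_frames_after: int = MIN_FRAMES_AFTER_TOUCH,
    mode: str = "step",
    noise_margin: float = DEFAULT_NOISE_MARGIN,
) -> tuple[pd.DataFrame, float, float]:
    """Per-boundary-segment entry success rate vs local spacer intensity.

    The boundary polyline is split into segments of about
    ``segment_length`` um; each entry attempt is assigned to the nearest
    segment.  Segments with zero attempts are excluded from the Spearman
    rank correlation between success rate and mean local spacer intensity.

    Returns ``(table, rho, pvalue)`` where the table has one row per
    segment: segment, n_attempts, n_success, success_rate, mean_intensity.
    """
    contours = measure.find_contours(mask.mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary contour")
    contour = max(contours, key=len)  # (row, col) vertices
    ps = mask.pixel_size
    verts = np.column_stack([(contour[:, 1] + 0.5) * ps, (contour[:, 0] + 0.5) * ps])
    seg_len = np.hypot(*(np.diff(verts, axis=0).T))
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arc[-1]
    n_segments = int(np.floor(total / segment_length))
    if n_segments < 3:
        raise ValueError(
            f"boundary of length {total:.2f} um yields {n_segments} segments; "
            "need >= 3"
        )
    vert_segment = np.minimum(
        (arc / total * n_segments).astype(int), n_segments - 1
    )

    ev = crossing_events(tracks, mask, touch_band, min_frames_after, mode, noise_margin)
    ev = ev[ev["direction"] == "enter"]
    n_att = np.zeros(n_segments, dtype=int)
    n_suc = np.zeros(n_segments, dtype=int)
    if len(ev):
        d2 = (
            (ev["x_um"].to_numpy()[:, None] - verts[None, :, 0]) ** 2
            + (ev["y_um"].to_numpy()[:, None] - verts[None, :, 1]) ** 2
        )
        seg_of = vert_segment[np.argmin(d2, axis=1)]
        for s, ok in zip(seg_of, ev["success"]):
            n_att[s] += 1
            n_suc[s] += int(ok)

    img = np.asarray(spacer_image, dtype=float)
    rr = np.clip(np.round(contour[:, 0]).astype(int), 0, img.shape[0] - 1)
    cc = np.clip(np.round(contour[:, 1]).astype(int), 0, img.shape[1] - 1)
    mean_int = np.array(
        [img[rr[vert_segment == s], cc[vert_segment == s]].mean()
         for s in range(n_segments)]
    )
    table = pd.DataFrame(
        {
            "segment": np.arange(n_segments),
            "n_attempts": n_att,
            "n_success": n_suc,
            "success_rate": np.where(n_att > 0, n_suc / np.maximum(n_att, 1), np.nan),
            "mean_intensity": mean_int,
        }
    )
    used = table[table["n_attempts"] > 0]
    if len(used) < 3:
        return table, np.nan, np.nan
    rho, pval = stats.spearmanr(used["success_rate"], used["mean_intensity"])
    return table, float(rho), float(pval)
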