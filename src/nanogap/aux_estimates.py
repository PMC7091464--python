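"""Back-of-envelope diffusion-to-surface estimates.

How many probe particles from a dilute solution collide with a surface
during an acquisition, and what bounds that places on the nonspecific
binding rate.  The collision count uses the classical one-sided diffusive
uptake of an absorbing wall: integrating the flux J(t) = 0.5 * c0 *
sqrt(D / (pi * t)) over the acquisition gives N(t) = A * c0 *
sqrt(D * t / pi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CollisionEstimate", "collision_count", "nonspecific_rate_bounds"]


@dataclass(frozen=True)
class CollisionEstimate:
    """Diffusive collision count with provenance of the formula used."""

    surface_area: float  # um^2
    concentration: float  # particles / um^3
    diffusion: float  # um^2/s
    duration: float  # s
    n_collisions: float
    formula: str = "N(t) = A * c0 * sqrt(D * t / pi) (absorbing-wall uptake)"


def collision_count(
    surface_area: float,
    concentration: float,
    diffusion: float,
    duration: float,
) -> CollisionEstimate:
    """Number of diffusive collisions with a surface during ``duration``.

    One-sided absorbing-wall result N(t) = A * c0 * sqrt(D * t / pi);
    linear in area and concentration, square-root in D and t.
    """
    for name, v in (
        ("surface_area", surface_area),
        ("concentration", concentration),
        ("diffusion", diffusion),
        ("duration", duration),
    ):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and positive")
    n = surface_area * concentration * np.sqrt(diffusion * duration / np.pi)
    return CollisionEstimate(
        surface_area, concentration, diffusion, duration, float(n)
    )


def nonspecific_rate_bounds(
    n_tracked_binding: int,
    n_collisions: float,
    n_tracked_total: int,
    volume_ratio: float | None = None,
) -> dict:
    """Lower and upper bounds on the nonspecific binding rate.

    Lower bound: observed binding events over the theoretical collision
    count (every collision was an opportunity).  Upper bound: binding
    fraction among tracked particles (slow enough to be tracked); the
    explored-to-imaged volume ratio is reported as context for why this
    overestimates.

    Returns a dict with lower_bound, upper_bound (fractions, NaN when
    undefined) and inputs.
    """
    if n_tracked_binding < 0 or n_tracked_total < 0:
        raise ValueError("counts must be >= 0")
    if n_collisions <= 0:
        raise ValueError("n_collisions must be positive")
    lower = n_tracked_binding / n_collisions
    upper = (
        n_tracked_binding / n_tracked_total if n_tracked_total > 0 else np.nan
    )
    return {
        "lower_bound": lower,
        "upper_bound": upper,
        "n_tracked_binding": n_tracked_binding,
        "n_collisions": n_collisions,
        "n_tracked_total": n_tracked_total,
        "volume_ratio": volume_ratio,
    }
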