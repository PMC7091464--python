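"""Gap geometry and size-dependent probe exclusion.

The membrane-membrane gap P set by a spacer/ligand complex is compared to
the probe's hydrodynamic diameter Q through Delta(P, Q) = P - Q; probes
larger than the gap (negative Delta) are expected to be excluded from the
contact.  Exclusion is quantified from the first acquisition frame as
1 - relative density, with relative density the ratio of probe density
inside the contact mask to the density outside it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .masking import ContactMask

__all__ = [
    "GapGeometry",
    "DensityResult",
    "gap_delta",
    "relative_density",
    "exclusion_fraction",
]


@dataclass(frozen=True)
class GapGeometry:
    """Spacer/ligand/probe sizes (nm) and the derived gap difference."""

    spacer_length: float
    ligand_length: float
    probe_diameter: float

    @property
    def gap(self) -> float:
        """Gap P created by the spacer complex: spacer + ligand (nm)."""
        return self.spacer_length + self.ligand_length

    @property
    def delta(self) -> float:
        """Delta(P, Q) = P - Q (nm); negative = probe larger than gap."""
        return self.gap - self.probe_diameter


def gap_delta(
    spacer_length: float, ligand_length: float, probe_diameter: float
) -> GapGeometry:
    """Build the gap geometry from component sizes in nm.

    P = spacer + ligand, Delta = P - probe diameter.
    """
    for name, v in (
        ("spacer_length", spacer_length),
        ("ligand_length", ligand_length),
        ("probe_diameter", probe_diameter),
    ):
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{name} must be finite and positive")
    return GapGeometry(spacer_length, ligand_length, probe_diameter)


@dataclass(frozen=True)
class DensityResult:
    """Probe counts and densities inside vs outside a contact mask."""

    n_in: int
    n_out: int
    area_in: float  # um^2
    area_out: float  # um^2
    relative_density: float
    exclusion: float
    valid: bool = True
    flag: str | None = None


def relative_density(
    localizations: pd.DataFrame, mask: ContactMask
) -> DensityResult:
    """Density of localizations inside the mask relative to outside.

    Intended for the detections of the first acquisition frame; any
    localization table in the mask's coordinate frame is accepted.
    Localizations on boundary pixels count as inside; the outside area is
    the full field minus the mask.  Degenerate geometry (empty mask or no
    outside area) yields a flagged, invalid result instead of an exception.
    """
    area_in = mask.area_um2
    area_out = mask.field_area_um2 - area_in
    inside = mask.contains(
        localizations["x_um"].to_numpy(), localizations["y_um"].to_numpy()
    )
    n_in = int(inside.sum())
    n_out = int(len(localizations) - n_in)
    if area_in <= 0:
        return DensityResult(
            n_in, n_out, area_in, area_out, np.nan, np.nan, False, "empty mask"
        )
    if area_out <= 0 or n_out == 0:
        return DensityResult(
            n_in,
            n_out,
            area_in,
            area_out,
            np.nan,
            np.nan,
            False,
            "zero outside density; ratio undefined",
        )
    rel = (n_in / area_in) / (n_out / area_out)
    return DensityResult(n_in, n_out, area_in, area_out, rel, 1.0 - rel)


def exclusion_fraction(relative_density_value: float) -> float:
    """Exclusion = 1 - relative density (negative values mean enrichment)."""
    if relative_density_value < 0:
        raise ValueError("relative density must be >= 0")
    return 1.0 - relative_density_value
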