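"""Biovolume and carbon conversions for Lugol-fixed ciliate cells.

Cells are treated as spheres or prolate spheroids (length along the
rotation axis, width the two equal equatorial axes — the standard
convention for fixed-ciliate biometry).  Biovolume converts to cellular
carbon with a linear factor (default 0.19 pg C µm⁻³), and prey density
converts to a carbon-equivalent concentration assuming a fixed per-cell
prey carbon content (default 10 pg C for the cryptophyte prey).
"""

from __future__ import annotations

import math

from .io_formats import CellDimension, Treatment, ValidationError

__all__ = ["biovolume", "ciliate_carbon", "prey_carbon_density"]


def biovolume(dim: CellDimension, volume_correction: float = 1.0) -> float:
    """Biovolume of one cell in µm³.

    Spheres use the mean of length and width as diameter (robust to which
    axis got labelled "length"); ellipsoids are prolate spheroids,
    V = (π/6)·L·W².  ``volume_correction`` is a multiplicative hook for a
    fixation-shrinkage correction; the default applies none.
    """
    if not dim.length > 0 or not dim.width > 0:
        raise ValidationError("dimensions must be positive")
    if dim.shape == "sphere":
        d = 0.5 * (dim.length + dim.width)
        v = math.pi / 6.0 * d ** 3
    else:
        v = math.pi / 6.0 * dim.length * dim.width ** 2
    return v * volume_correction


def ciliate_carbon(bv: float, treatment: Treatment) -> float:
    """Cellular carbon C_y (pg C cell⁻¹) from biovolume (µm³)."""
    if bv < 0:
        raise ValidationError("biovolume must be >= 0")
    return treatment.carbon_per_volume * bv


def prey_carbon_density(density: float, treatment: Treatment) -> float:
    """Carbon-equivalent prey concentration (ng C mL⁻¹) from cells mL⁻¹."""
    if density < 0:
        raise ValidationError("density must be >= 0")
    return density * treatment.prey_carbon / 1000.0  # pg -> ng
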