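"""Volume and maximum-3D-diameter morphometry of binary masks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .errors import DegenerateMaskError
from .imaging_io import BinaryMask
from .margin_analysis import extract_surface


@dataclass(frozen=True)
class Morphometrics:
    volume_ml: float
    max_diameter_mm: float


def volume_ml(mask: BinaryMask) -> float:
    """Mask volume in milliliters: foreground count x voxel volume / 1000."""
    return mask.foreground_count * mask.geometry.voxel_volume_mm3 / 1000.0


def max_diameter_mm(mask: BinaryMask) -> float:
    """Maximum 3D diameter: largest pairwise distance between surface voxel centers.

    Computed over the convex hull vertices of the surface point set (the
    diameter of a finite point set is attained at hull vertices); falls back
    to the full pairwise scan for small or degenerate (flat/collinear)
    configurations.
    """
    if mask.is_empty:
        raise DegenerateMaskError("cannot measure the diameter of an empty mask")
    pts = mask.geometry.voxel_to_world(extract_surface(mask))
    if len(pts) == 1:
        return 0.0
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # coplanar/collinear point sets: brute force below
    return float(pdist(pts).max())


def measure(mask: BinaryMask) -> Morphometrics:
    return Morphometrics(volume_ml(mask), max_diameter_mm(mask))
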