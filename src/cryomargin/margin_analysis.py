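"""Signed 3D treatment-margin analysis on co-registered tumor / ice-ball masks.

The minimal treatment margin (MTM) is the smallest signed 3D distance from
the tumor surface to the ice-ball surface: positive where the ice ball
extends beyond the tumor, negative where part of the tumor lies outside the
ice ball (incomplete coverage).  The computation is voxel-based: the tumor
surface is the set of foreground voxels with a face-adjacent background
neighbor, and distances are anisotropic-spacing-aware Euclidean distances
between voxel centers.  Reported margins therefore carry a resolution band
of half a voxel body diagonal; no sub-voxel surface mesh is interpolated.

The smallest margin is localized by dividing the tumor into octants along
the patient left-right, anterior-posterior and cranio-caudal axes through
the tumor center of mass, and tumor voxels are classified into three
coverage classes relative to a user-defined intended margin (default 5 mm):
covered with margin, covered but insufficient margin, and uncovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateMaskError, ParameterError
from .imaging_io import BinaryMask, ImageGeometry, assert_same_grid

#: Octant labels: patient Right/Left x Anterior/Posterior x Superior/Inferior.
OCTANT_LABELS = (
    "RAS", "RAI", "RPS", "RPI", "LAS", "LAI", "LPS", "LPI",
)

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class SignedDistanceField:
    """Per-voxel signed Euclidean distance to a mask's boundary, in mm.

    Positive inside the mask, negative outside; the magnitude is the
    distance from the voxel center to the nearest voxel center of opposite
    membership (the voxel-center boundary convention).
    """

    geometry: ImageGeometry
    values: np.ndarray

    def sample_at_indices(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices))
        return self.values[idx[:, 0], idx[:, 1], idx[:, 2]]


@dataclass
class MarginMap:
    """Signed margin at every tumor-surface voxel.

    ``signed_margin[i]`` is the signed distance from surface voxel center
    ``surface_points[i]`` to the ice-ball boundary: positive means that
    point lies inside the ice ball.
    """

    surface_points: np.ndarray          # (N, 3) voxel indices, lexicographic
    world_points: np.ndarray            # (N, 3) world mm
    signed_margin: np.ndarray           # (N,) mm
    geometry: ImageGeometry

    def __len__(self) -> int:
        return len(self.signed_margin)


@dataclass
class MarginSummary:
    """Scalar margin metrics for one treated tumor."""

    mtm_raw_mm: float
    mtm_mm: int
    argmin_point_mm: tuple[float, float, float]
    argmin_octant: str
    octant_min_mm: dict[str, float | None]
    coverage_fractions: dict[str, float]
    threshold_mm: float
    voxel_diagonal_mm: float

    @property
    def incomplete_coverage(self) -> bool:
        return self.mtm_raw_mm < 0

    @property
    def margin_achieved(self) -> bool:
        """Intended-margin flag, evaluated on the raw (unrounded) MTM."""
        return self.mtm_raw_mm >= self.threshold_mm


def round_half_away_from_zero(x: float) -> int:
    """Round to nearest integer, ties away from zero (so -6.5 -> -7, 4.5 -> 5)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def signed_distance_field(mask: BinaryMask) -> SignedDistanceField:
    """Anisotropic signed Euclidean distance transform of a binary mask.

    Raises :class:`DegenerateMaskError` if the mask is all-foreground or
    all-background (the boundary, and hence the sign, would be undefined).
    """
    vox = mask.voxels.astype(bool)
    n_fg = mask.foreground_count
    if n_fg == 0 or n_fg == vox.size:
        raise DegenerateMaskError(
            "signed distance needs both foreground and background voxels"
        )
    spacing = mask.geometry.spacing
    dist_to_bg = ndimage.distance_transform_edt(vox, sampling=spacing)
    dist_to_fg = ndimage.distance_transform_edt(~vox, sampling=spacing)
    values = np.where(vox, dist_to_bg, -dist_to_fg)
    return SignedDistanceField(mask.geometry, values)


def extract_surface(mask: BinaryMask) -> np.ndarray:
    """Surface voxels: foreground with >= 1 of 6 face-neighbors background.

    Out-of-volume counts as background.  Returns (N, 3) voxel indices in
    lexicographic order.
    """
    if mask.is_empty:
        raise DegenerateMaskError("cannot extract the surface of an empty mask")
    vox = mask.voxels.astype(bool)
    interior = ndimage.binary_erosion(vox, structure=_FACE_STRUCTURE, border_value=0)
    return np.argwhere(vox & ~interior)


def compute_margin_map(tumor: BinaryMask, ice: BinaryMask) -> MarginMap:
    """Signed margin at every tumor-surface voxel center.

    Both masks must share one voxel lattice (co-registration and resampling
    happen upstream).  The margin at a surface point is the ice ball's
    signed distance field sampled at that voxel center.
    """
    assert_same_grid(tumor, ice)
    if tumor.is_empty:
        raise DegenerateMaskError("tumor mask is empty")
    if ice.is_empty:
        raise DegenerateMaskError("ice-ball mask is empty")
    surface = extract_surface(tumor)
    ice_sdf = signed_distance_field(ice)
    margins = ice_sdf.sample_at_indices(surface)
    world = tumor.geometry.voxel_to_world(surface)
    return MarginMap(surface, world, margins.astype(float), tumor.geometry)


def octant_partition(tumor: BinaryMask) -> tuple[np.ndarray, np.ndarray]:
    """Assign each tumor voxel to an anatomical octant.

    Octants are delimited by the patient R/L, A/P and S/I axes through the
    tumor center of mass (computed over foreground voxel centers in world
    mm).  Exact-zero offsets go to the positive (R, A, S) side.

    Returns ``(indices, labels)``: (N, 3) foreground voxel indices and the
    octant label of each.
    """
    if tumor.is_empty:
        raise DegenerateMaskError("cannot partition an empty mask into octants")
    idx = tumor.foreground_indices()
    world = tumor.geometry.voxel_to_world(idx)
    center = world.mean(axis=0)
    return idx, octant_labels_for_points(world, center)


def octant_labels_for_points(world_points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Octant label of each world-mm point relative to ``center`` (ties positive)."""
    offset = np.atleast_2d(world_points) - center
    pos = offset >= 0
    letters = np.where(
        pos,
        np.array(["R", "A", "S"]),
        np.array(["L", "P", "I"]),
    )
    return np.array(["".join(row) for row in letters])


def octant_minima(margin_map: MarginMap, tumor: BinaryMask) -> dict[str, float | None]:
    """Per-octant minimum signed margin over the tumor-surface points.

    Octants containing no surface point map to ``None``.  The octant origin
    is the tumor center of mass, matching :func:`octant_partition`.
    """
    idx = tumor.foreground_indices()
    center = tumor.geometry.voxel_to_world(idx).mean(axis=0)
    labels = octant_labels_for_points(margin_map.world_points, center)
    minima: dict[str, float | None] = {}
    for lab in OCTANT_LABELS:
        sel = labels == lab
        minima[lab] = float(margin_map.signed_margin[sel].min()) if sel.any() else None
    return minima


def summarize_margin(
    margin_map: MarginMap,
    tumor: BinaryMask,
    ice: BinaryMask,
    threshold_mm: float = 5.0,
) -> MarginSummary:
    """Reduce a margin map to the scalar MTM, octant minima and coverage classes.

    The MTM is the minimum signed margin, reported raw and rounded to the
    nearest millimeter (half away from zero); a negative MTM means
    incomplete coverage.  Coverage classes are volume fractions over tumor
    voxels: *uncovered* if the voxel lies outside the ice ball,
    *covered_insufficient* if inside but with ice signed distance below
    ``threshold_mm``, and *covered_with_margin* otherwise.
    """
    if threshold_mm < 0:
        raise ParameterError(f"threshold_mm must be >= 0, got {threshold_mm}")
    if len(margin_map) == 0:
        raise DegenerateMaskError("margin map is empty")

    margins = margin_map.signed_margin
    k = int(np.argmin(margins))  # ties -> first in lexicographic voxel order
    mtm_raw = float(margins[k])
    argmin_world = margin_map.world_points[k]

    minima = octant_minima(margin_map, tumor)
    idx = tumor.foreground_indices()
    center = tumor.geometry.voxel_to_world(idx).mean(axis=0)
    argmin_octant = str(octant_labels_for_points(argmin_world[None, :], center)[0])

    ice_sdf = signed_distance_field(ice)
    tumor_vals = ice_sdf.values[tumor.voxels.astype(bool)]
    inside_ice = ice.voxels.astype(bool)[tumor.voxels.astype(bool)]
    n = tumor_vals.size
    uncovered = int(np.count_nonzero(~inside_ice))
    insufficient = int(np.count_nonzero(inside_ice & (tumor_vals < threshold_mm)))
    with_margin = n - uncovered - insufficient
    fractions = {
        "covered_with_margin": with_margin / n,
        "covered_insufficient": insufficient / n,
        "uncovered": uncovered / n,
    }

    return MarginSummary(
        mtm_raw_mm=mtm_raw,
        mtm_mm=round_half_away_from_zero(mtm_raw),
        argmin_point_mm=tuple(float(v) for v in argmin_world),
        argmin_octant=argmin_octant,
        octant_min_mm=minima,
        coverage_fractions=fractions,
        threshold_mm=float(threshold_mm),
        voxel_diagonal_mm=tumor.geometry.voxel_diagonal_mm,
    )


def margin_map_volume(margin_map: MarginMap) -> np.ndarray:
    """Scalar volume with the signed margin on tumor-surface voxels, NaN elsewhere."""
    vol = np.full(margin_map.geometry.shape, np.nan, dtype=float)
    s = margin_map.surface_points
    vol[s[:, 0], s[:, 1], s[:, 2]] = margin_map.signed_margin
    return vol
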