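"""Reading, writing and geometric validation of 3D binary mask volumes.

All volumes are carried as :class:`BinaryMask` objects on an explicit
:class:`ImageGeometry`: a voxel lattice together with a 4x4 affine mapping
0-based voxel indices (voxel *centers*) to world millimeters in the RAS
frame (+x toward patient Right, +y Anterior, +z Superior).  NIfTI files in
any orientation are reoriented to RAS on load so that anatomical octant
labels downstream are unambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import (
    DimensionalityError,
    GeometryError,
    GridIncompatibilityError,
)


@dataclass(frozen=True)
class ImageGeometry:
    """Physical geometry of a 3D voxel lattice.

    Parameters
    ----------
    shape
        Number of voxels along each of the three axes.
    affine
        4x4 matrix mapping homogeneous voxel indices ``(i, j, k, 1)`` to
        world RAS coordinates ``(x, y, z, 1)`` in millimeters.  The affine
        addresses voxel centers.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {affine.shape}")
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise DimensionalityError(f"shape must be a positive integer triple, got {self.shape}")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise GeometryError("affine is singular")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm along each axis (column norms of the 3x3 block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def voxel_diagonal_mm(self) -> float:
        """Length of the voxel body diagonal in mm; the resolution bound on distances."""
        return float(np.linalg.norm(self.spacing))

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (N, 3) voxel indices to (N, 3) world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def close_to(self, other: "ImageGeometry", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=tol)

    @classmethod
    def from_spacing(
        cls,
        shape: tuple[int, int, int],
        spacing: tuple[float, float, float],
        origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    ) -> "ImageGeometry":
        """Axis-aligned RAS geometry from spacing and world origin."""
        spacing = np.asarray(spacing, dtype=float)
        if np.any(spacing <= 0):
            raise GeometryError(f"spacing must be positive, got {spacing}")
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing)
        affine[:3, 3] = origin
        return cls(tuple(shape), affine)


@dataclass
class BinaryMask:
    """A binary segmentation on a physical voxel lattice.

    ``voxels`` is a 3D uint8 array of {0, 1}; ``geometry`` supplies the
    world-mm context for every distance and volume computed from it.
    """

    geometry: ImageGeometry
    voxels: np.ndarray
    _foreground_count: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise DimensionalityError(f"mask must be 3D, got {vox.ndim}D")
        if tuple(vox.shape) != self.geometry.shape:
            raise GridIncompatibilityError(
                f"voxel array shape {vox.shape} != geometry shape {self.geometry.shape}"
            )
        uniq = np.unique(vox)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, got {uniq}")
        self.voxels = vox.astype(np.uint8)
        self._foreground_count = int(self.voxels.sum())

    @property
    def foreground_count(self) -> int:
        return self._foreground_count

    @property
    def is_empty(self) -> bool:
        return self._foreground_count == 0

    def foreground_indices(self) -> np.ndarray:
        """(N, 3) integer voxel indices of foreground voxels, lexicographic order."""
        return np.argwhere(self.voxels > 0)

    def touches_boundary(self) -> bool:
        v = self.voxels
        return bool(
            v[0].any() or v[-1].any()
            or v[:, 0].any() or v[:, -1].any()
            or v[:, :, 0].any() or v[:, :, -1].any()
        )


def read_mask(path: str | Path) -> BinaryMask:
    """Load a NIfTI volume as a binary mask, reoriented to RAS.

    Any nonzero voxel maps to 1.  Raises ``FileNotFoundError`` for a missing
    file, :class:`DimensionalityError` for a non-3D volume and
    :class:`GeometryError` for a degenerate affine.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data_shape = img.shape
    if len(data_shape) == 4 and data_shape[3] == 1:
        img = img.slicer[..., 0]
    elif len(data_shape) != 3:
        raise DimensionalityError(f"expected a 3D volume, got shape {data_shape} in {path}")
    img = nib.as_closest_canonical(img)  # reorient to RAS
    affine = np.asarray(img.affine, dtype=float)
    if abs(np.linalg.det(affine)) < 1e-12:
        raise GeometryError(f"degenerate affine in {path}")
    data = np.asanyarray(img.dataobj)
    mask = BinaryMask(ImageGeometry(tuple(data.shape), affine), (data != 0).astype(np.uint8))
    if mask.touches_boundary():
        warnings.warn(
            f"mask {path.name} has foreground touching the volume boundary; "
            "distances beyond the field of view are unknowable",
            stacklevel=2,
        )
    return mask


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask to NIfTI; re-reading reproduces voxels exactly and the affine within 1e-6."""
    path = Path(path)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.geometry.affine)
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


def assert_same_grid(a: BinaryMask, b: BinaryMask, tol: float = 1e-6) -> None:
    """Require two masks to share one voxel lattice, else raise naming the offending field."""
    if a.geometry.shape != b.geometry.shape:
        raise GridIncompatibilityError(
            f"shape mismatch: {a.geometry.shape} vs {b.geometry.shape}"
        )
    if not np.allclose(a.geometry.affine, b.geometry.affine, atol=tol):
        diff = np.abs(a.geometry.affine - b.geometry.affine).max()
        raise GridIncompatibilityError(
            f"affine mismatch: max element difference {diff:.3g} exceeds tol {tol:g}"
        )


def resample_mask(mask: BinaryMask, reference: ImageGeometry, transform) -> BinaryMask:
    """Resample ``mask`` onto ``reference`` after applying a rigid world transform.

    ``transform`` maps the mask's world frame into the reference world frame.
    Nearest-neighbor interpolation keeps the output binary; voxels that fall
    outside the source field of view become background.
    """
    from .registration import RigidTransform  # local import to avoid a cycle

    if not isinstance(transform, RigidTransform):
        transform = RigidTransform.from_matrix(np.asarray(transform, dtype=float))
    transform.validate()

    # output index -> reference world -> source world -> source index
    M = (
        np.linalg.inv(mask.geometry.affine)
        @ np.linalg.inv(transform.matrix)
        @ reference.affine
    )
    out = ndimage.affine_transform(
        mask.voxels,
        matrix=M[:3, :3],
        offset=M[:3, 3],
        output_shape=reference.shape,
        order=0,
        mode="constant",
        cval=0,
        prefilter=False,
    )
    return BinaryMask(reference, out.astype(np.uint8))
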