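"""Rigid pre/post-ablation co-registration from paired anatomical landmarks.

The pre- and post-ablation scans are brought into one frame by a rigid
(rotation + translation, no scaling) transform.  The fit is the closed-form
weighted least-squares solution (Kabsch/Umeyama orthogonal Procrustes with
the scale fixed at 1) over corresponding landmark pairs such as cysts,
renal cortex or local vasculature near the treated tumor.  A user-supplied
transform file can stand in for the fit when registration was done
externally; manual adjustment is modeled as composing a correction
transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    CorrespondenceError,
    DegenerateConfigurationError,
    TransformValidityError,
)

_RIGID_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform in world millimeters: ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float).reshape(3, 3))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float).reshape(3))

    def validate(self, tol: float = 1e-6) -> None:
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=tol):
            raise TransformValidityError("rotation is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > tol:
            raise TransformValidityError(f"det(rotation) = {np.linalg.det(R):.9f}, expected +1")

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 form."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise TransformValidityError(f"expected a 4x4 matrix, got {matrix.shape}")
        t = cls(matrix[:3, :3], matrix[:3, 3])
        t.validate()
        return t

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    # -- persistence ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {"matrix": [float(v) for v in self.matrix.flatten()], "frame": "RAS"}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        payload = json.loads(Path(path).read_text())
        if payload.get("frame", "RAS") != "RAS":
            raise TransformValidityError(f"unsupported frame {payload.get('frame')!r}; expected RAS")
        matrix = np.asarray(payload["matrix"], dtype=float).reshape(4, 4)
        return cls.from_matrix(matrix)


@dataclass
class LandmarkSet:
    """World-mm anatomical landmark coordinates with optional labels."""

    points: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise CorrespondenceError(f"landmarks must be (N, 3), got {self.points.shape}")
        if self.labels is not None and len(self.labels) != len(self.points):
            raise CorrespondenceError("label count does not match point count")

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LandmarkSet":
        """Load from CSV with columns label,x_mm,y_mm,z_mm (RAS)."""
        import pandas as pd

        df = pd.read_csv(path)
        required = {"x_mm", "y_mm", "z_mm"}
        if not required.issubset(df.columns):
            raise CorrespondenceError(f"landmark CSV needs columns {sorted(required)}")
        labels = df["label"].astype(str).tolist() if "label" in df.columns else None
        return cls(df[["x_mm", "y_mm", "z_mm"]].to_numpy(float), labels)


def _check_not_collinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DegenerateConfigurationError(
            "landmarks are collinear (or coincident); a unique rigid fit needs 3 "
            "non-collinear points"
        )


def fit_rigid(
    source: LandmarkSet,
    target: LandmarkSet,
    weights: np.ndarray | None = None,
) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit mapping source landmarks onto target landmarks.

    Corresponding points are matched by index.  Optional nonnegative
    ``weights`` let the fit emphasize landmarks close to the area of
    interest (default uniform).  Returns the transform and the post-fit
    root-mean-square distance in mm.
    """
    src, tgt = source.points, target.points
    if len(src) != len(tgt):
        raise CorrespondenceError(f"point count mismatch: {len(src)} vs {len(tgt)}")
    if len(src) < 3:
        raise DegenerateConfigurationError(f"need >= 3 landmark pairs, got {len(src)}")
    _check_not_collinear(src)

    if weights is None:
        w = np.full(len(src), 1.0 / len(src))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(src),) or np.any(w < 0) or w.sum() <= 0:
            raise CorrespondenceError("weights must be nonnegative, one per landmark pair")
        w = w / w.sum()

    mu_s = w @ src
    mu_t = w @ tgt
    H = (src - mu_s).T @ ((tgt - mu_t) * w[:, None])
    U, _, Vt = np.linalg.svd(H)
    # reflection guard: force a proper rotation by flipping the smallest singular direction
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s

    transform = RigidTransform(R, t)
    residual = transform.apply(src) - tgt
    rmsd = float(np.sqrt(w @ np.sum(residual**2, axis=1)))
    return transform, rmsd


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Transform applying ``inner`` first, then ``outer``."""
    R = outer.rotation @ inner.rotation
    t = outer.rotation @ inner.translation + outer.translation
    return RigidTransform(R, t)


def invert(t: RigidTransform) -> RigidTransform:
    Rt = t.rotation.T
    return RigidTransform(Rt, -Rt @ t.translation)
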