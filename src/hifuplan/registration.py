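"""Landmark-based affine registration of referral to treatment space.

A referral (supine diagnostic) dataset is brought into treatment
orientation by a 12-parameter affine fitted in the least-squares sense to
ten or more paired bony landmarks, then resampled onto the treatment
grid. Registration quality is the mean Euclidean distance between
corresponding points after transformation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import FitError, InputError
from .volume import LabelMask, VoxelVolume


@dataclass
class LandmarkSet:
    """Named 3D points in world mm."""

    names: list
    points: np.ndarray  # (N, 3)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.names = list(self.names)
        if len(self.names) != len(self.points):
            raise InputError("landmark names and points disagree in length")
        if len(self.points) < 1:
            raise InputError("a landmark set needs at least one point")
        if not np.all(np.isfinite(self.points)):
            raise InputError("landmark coordinates must be finite")

    def __len__(self):
        return len(self.points)

    @classmethod
    def read_csv(cls, path) -> "LandmarkSet":
        path = Path(path)
        if not path.exists():
            raise InputError(f"landmark file not found: {path}")
        df = pd.read_csv(path)
        required = {"name", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise InputError(f"{path}: landmark CSV needs columns name,x,y,z")
        return cls(df["name"].tolist(), df[["x", "y", "z"]].to_numpy(dtype=float))

    def write_csv(self, path) -> None:
        pd.DataFrame(
            {"name": self.names, "x": self.points[:, 0],
             "y": self.points[:, 1], "z": self.points[:, 2]}
        ).to_csv(path, index=False)


@dataclass
class AffineTransform:
    """3D affine ``y = A x + t`` in world mm."""

    matrix: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) <= 1e-12:
            raise FitError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def apply_landmarks(self, lms: LandmarkSet) -> LandmarkSet:
        return LandmarkSet(lms.names, self.apply(lms.points))

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Transform applying ``other`` first, then ``self``."""
        return AffineTransform(
            self.matrix @ other.matrix, self.matrix @ other.translation + self.translation
        )

    def to_json(self, path=None):
        obj = {
            "matrix": [float(v) for v in self.matrix.ravel()],
            "translation": [float(v) for v in self.translation],
            "convention": "y = A x + t, world mm",
        }
        if path is not None:
            Path(path).write_text(json.dumps(obj, indent=2))
        return obj

    @classmethod
    def from_json(cls, source) -> "AffineTransform":
        if isinstance(source, (str, Path)):
            source = json.loads(Path(source).read_text())
        return cls(np.asarray(source["matrix"]).reshape(3, 3), source["translation"])


def fit_landmark_affine(
    source: LandmarkSet, dest: LandmarkSet
) -> tuple[AffineTransform, np.ndarray]:
    """Least-squares affine mapping source landmarks onto destination ones.

    Minimises sum ||A s_i + t - d_i||^2. Needs at least four non-coplanar
    point pairs; returns the transform and per-point residual distances.
    """
    if len(source) != len(dest):
        raise InputError(
            f"paired landmark sets differ in size: {len(source)} vs {len(dest)}"
        )
    n = len(source)
    if n < 4:
        raise FitError(f"affine fit needs >= 4 landmark pairs, got {n}")
    s = source.points
    centred = s - s.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[-1] <= 1e-8 * max(sv[0], 1.0):
        raise FitError("landmarks are coplanar or otherwise degenerate")
    design = np.hstack([s, np.ones((n, 1))])
    params, *_ = np.linalg.lstsq(design, dest.points, rcond=None)
    transform = AffineTransform(params[:3].T, params[3])
    residuals = np.linalg.norm(transform.apply(s) - dest.points, axis=1)
    return transform, residuals


def fit_landmark_rigid(
    source: LandmarkSet, dest: LandmarkSet
) -> tuple[AffineTransform, np.ndarray]:
    """Least-squares rigid (rotation + translation) fit, Kabsch algorithm.

    Offered for sensitivity checks against the default affine fit.
    """
    if len(source) != len(dest):
        raise InputError(
            f"paired landmark sets differ in size: {len(source)} vs {len(dest)}"
        )
    if len(source) < 3:
        raise FitError("rigid fit needs >= 3 landmark pairs")
    s, d = source.points, dest.points
    sc, dc = s - s.mean(axis=0), d - d.mean(axis=0)
    h = sc.T @ dc
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, sign]) @ u.T
    t = d.mean(axis=0) - rot @ s.mean(axis=0)
    transform = AffineTransform(rot, t)
    residuals = np.linalg.norm(transform.apply(s) - d, axis=1)
    return transform, residuals


def registration_error(transformed_source: LandmarkSet, dest: LandmarkSet) -> float:
    """Mean Euclidean distance between corresponding landmark points (mm)."""
    if len(transformed_source) != len(dest):
        raise InputError(
            f"paired landmark sets differ in size: "
            f"{len(transformed_source)} vs {len(dest)}"
        )
    return float(
        np.linalg.norm(transformed_source.points - dest.points, axis=1).mean()
    )


def apply_transform(volume_or_mask, transform: AffineTransform, reference):
    """Resample a volume or mask through an affine onto a reference grid.

    The transform maps source world coordinates into reference world
    coordinates; resampling pulls each reference voxel back through the
    inverse. Intensity volumes use trilinear interpolation, masks
    nearest-neighbour (labels stay binary); voxels mapping outside the
    source field of view become background / False.
    """
    is_mask = isinstance(volume_or_mask, LabelMask)
    src = volume_or_mask
    inv = transform.inverse()
    # reference voxel j -> world y = o_ref + S_ref j -> source world
    # x = A^-1 (y - t) -> source voxel i = S_src^-1 (x - o_src)
    s_ref = np.diag(reference.spacing)
    m = np.diag(1.0 / src.spacing) @ inv.matrix @ s_ref
    offset = (inv.apply(reference.origin) - src.origin) / src.spacing
    data = src.data.astype(np.float64) if is_mask else np.asarray(src.data, dtype=np.float64)
    out = ndimage.affine_transform(
        data,
        m,
        offset=offset,
        output_shape=reference.shape,
        order=0 if is_mask else 1,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if is_mask:
        return LabelMask(out > 0.5, reference.spacing.copy(), reference.origin.copy())
    return VoxelVolume(out, reference.spacing.copy(), reference.origin.copy())
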