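"""Voxel volumes, label masks and the co-registered anatomy bundle.

Coordinate conventions used throughout the package:

* World frame: right-handed, millimetres. Axis 0 is LR (x), axis 1 is AP
  (y, positive toward anterior, i.e. *up* when the subject lies on the
  HIFU couch), axis 2 is IS (z, positive superior). The couch geometry is
  described vertically (the transducer home position sits a fixed
  distance below the magnetic isocentre), so AP is the vertical axis.
* Voxel-centre convention with 0-based indices: the world coordinate of
  voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing``.
* World-to-voxel mapping rounds to the nearest voxel centre (``np.rint``,
  so exact half-voxel ties round to even).

Volumes are stored axis-aligned; oblique direction-cosine matrices are
rejected on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .errors import GeometryError, InputError, ValidationError

AXIS_LABELS = ("LR", "AP", "IS")
#: index of the anterior-posterior (vertical-on-couch) axis
AP = 1

GRID_TOL_MM = 1e-3


def _as_triple(v) -> np.ndarray:
    a = np.asarray(v, dtype=float).reshape(3)
    return a


@dataclass
class VoxelVolume:
    """A 3D scalar image on a regular axis-aligned grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Image intensities (arbitrary units).
    spacing : (3,) float
        Per-axis voxel size in mm; strictly positive.
    origin : (3,) float
        World coordinate (mm) of the centre of voxel (0, 0, 0).
    axis_labels : tuple of str
        Anatomical meaning of the array axes, default ``("LR", "AP", "IS")``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axis_labels: tuple = AXIS_LABELS

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if not np.all(np.isfinite(self.spacing)) or np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.origin)):
            raise GeometryError(f"origin must be finite, got {self.origin}")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axis_coords(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one array axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    def voxel_to_world(self, index) -> np.ndarray:
        """World coordinates (mm) of voxel indices (..., 3)."""
        idx = np.asarray(index, dtype=float)
        return self.origin + idx * self.spacing

    def world_to_voxel(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-voxel indices for world points.

        Returns ``(indices, in_bounds)``: out-of-bounds points are flagged,
        never silently clamped.
        """
        pts = np.asarray(points, dtype=float)
        idx = np.rint((pts - self.origin) / self.spacing).astype(np.intp)
        shp = np.asarray(self.shape)
        in_bounds = np.all((idx >= 0) & (idx < shp), axis=-1)
        return idx, in_bounds

    def same_grid(self, other, tol: float = GRID_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class LabelMask:
    """A boolean mask sharing the geometry of a parent :class:`VoxelVolume`."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    axis_labels: tuple = AXIS_LABELS

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3D mask, got ndim={self.data.ndim}")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")

    @classmethod
    def like(cls, data, ref) -> "LabelMask":
        """Build a mask on the grid of ``ref`` (a VoxelVolume or LabelMask)."""
        return cls(np.asarray(data), ref.spacing.copy(), ref.origin.copy(), ref.axis_labels)

    @classmethod
    def empty_like(cls, ref) -> "LabelMask":
        return cls.like(np.zeros(ref.shape, dtype=bool), ref)

    shape = VoxelVolume.shape
    voxel_volume_mm3 = VoxelVolume.voxel_volume_mm3
    axis_coords = VoxelVolume.axis_coords
    voxel_to_world = VoxelVolume.voxel_to_world
    world_to_voxel = VoxelVolume.world_to_voxel
    same_grid = VoxelVolume.same_grid

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3


def world_to_voxel(point, volume) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-voxel index of a world point plus an in-bounds flag."""
    return volume.world_to_voxel(point)


def voxel_to_world(index, volume) -> np.ndarray:
    return volume.voxel_to_world(index)


# ---------------------------------------------------------------------------
# anatomy bundle
# ---------------------------------------------------------------------------

@dataclass
class LabelledAnatomy:
    """A co-registered image volume plus the masks the planner consumes.

    ``oar`` and ``extracorporeal_air`` may be empty; ``body``, ``bone`` and
    ``target`` are required. Invariants (checked by :meth:`validate`):
    target does not touch bone, target lies inside the body, and
    extracorporeal air lies outside the body.
    """

    image: VoxelVolume
    body: LabelMask
    bone: LabelMask
    target: LabelMask
    extracorporeal_air: LabelMask = None
    oar: LabelMask = None
    couch: object = None  # CouchGeometry; kept duck-typed to avoid a cycle

    def __post_init__(self):
        if self.extracorporeal_air is None:
            self.extracorporeal_air = LabelMask.empty_like(self.image)
        if self.oar is None:
            self.oar = LabelMask.empty_like(self.image)

    def masks(self) -> dict:
        return {
            "body": self.body,
            "bone": self.bone,
            "target": self.target,
            "extracorporeal_air": self.extracorporeal_air,
            "oar": self.oar,
        }

    def validate(self, tol: float = GRID_TOL_MM) -> None:
        for name, mask in self.masks().items():
            if not self.image.same_grid(mask, tol):
                raise GeometryError(
                    f"mask '{name}' does not share the image grid "
                    f"(shape {mask.shape} vs {self.image.shape}, "
                    f"spacing {mask.spacing} vs {self.image.spacing})"
                )
        overlap = int((self.target.data & self.bone.data).sum())
        if overlap:
            raise ValidationError(f"target overlaps bone in {overlap} voxel(s)")
        outside = int((self.target.data & ~self.body.data).sum())
        if outside:
            raise ValidationError(f"target extends outside the body in {outside} voxel(s)")
        air_in_body = int((self.extracorporeal_air.data & self.body.data).sum())
        if air_in_body:
            raise ValidationError(
                f"extracorporeal air overlaps the body in {air_in_body} voxel(s)"
            )

    def obstruction_mask(self) -> LabelMask:
        """Union of everything that blocks the beam: bone, air, OARs."""
        data = self.bone.data | self.extracorporeal_air.data | self.oar.data
        return LabelMask.like(data, self.image)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine_for(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _grid_from_affine(aff, path) -> tuple[np.ndarray, np.ndarray]:
    lin = aff[:3, :3]
    spacing = np.diag(lin).copy()
    off = lin - np.diag(spacing)
    if np.max(np.abs(off)) > 1e-6 * max(np.max(np.abs(spacing)), 1.0):
        raise GeometryError(f"{path}: oblique (non-axis-aligned) volumes are not supported")
    if np.any(spacing <= 0):
        raise GeometryError(f"{path}: non-positive voxel spacing in affine")
    return spacing, aff[:3, 3].copy()


def read_volume(path) -> VoxelVolume:
    path = Path(path)
    if not path.exists():
        raise InputError(f"volume not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing, origin = _grid_from_affine(img.affine, path)
    return VoxelVolume(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(volume: VoxelVolume, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(volume.data, dtype=np.float32), _affine_for(volume.spacing, volume.origin)
    )
    nib.save(img, str(path))


def read_mask(path) -> LabelMask:
    vol = read_volume(path)
    return LabelMask(vol.data > 0, vol.spacing, vol.origin)


def write_mask(mask: LabelMask, path) -> None:
    """Write a mask as uint8 NIfTI; re-reading gives a voxel-identical mask."""
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine_for(mask.spacing, mask.origin)
    )
    nib.save(img, str(path))


MASK_FILES = {
    "body": "body.nii.gz",
    "bone": "bone.nii.gz",
    "target": "target.nii.gz",
    "extracorporeal_air": "air.nii.gz",
    "oar": "oar.nii.gz",
}
REQUIRED_MASKS = ("body", "bone", "target")
IMAGE_FILE = "image.nii.gz"
COUCH_FILE = "couch.yaml"


def read_anatomy(source, couch_config=None, tol: float = GRID_TOL_MM) -> LabelledAnatomy:
    """Load a validated :class:`LabelledAnatomy` from files.

    ``source`` is either a directory following the standard layout
    (``image.nii.gz``, ``body.nii.gz``, ``bone.nii.gz``, ``target.nii.gz``,
    optional ``air.nii.gz``/``oar.nii.gz``/``couch.yaml``) or a mapping of
    names (``image``, ``body``, ...) to file paths. Masks are binarised at
    > 0; all grids must agree within ``tol`` mm.
    """
    from .transducer import CouchGeometry

    if isinstance(source, (str, Path)):
        d = Path(source)
        if not d.is_dir():
            raise InputError(f"anatomy directory not found: {d}")
        paths = {"image": d / IMAGE_FILE}
        for name, fname in MASK_FILES.items():
            p = d / fname
            if p.exists():
                paths[name] = p
        if couch_config is None and (d / COUCH_FILE).exists():
            couch_config = d / COUCH_FILE
    else:
        paths = {k: Path(v) for k, v in dict(source).items()}

    if "image" not in paths:
        raise InputError("anatomy input must include an 'image' volume")
    missing = [m for m in REQUIRED_MASKS if m not in paths]
    if missing:
        raise InputError(f"missing required mask(s): {', '.join(missing)}")

    image = read_volume(paths["image"])
    masks = {}
    for name in MASK_FILES:
        if name in paths:
            mask = read_mask(paths[name])
            if not image.same_grid(mask, tol):
                raise GeometryError(
                    f"{paths[name]}: grid mismatch with {paths['image']} "
                    f"(shape {mask.shape} vs {image.shape}, spacing "
                    f"{mask.spacing} vs {image.spacing})"
                )
            masks[name] = mask

    couch = CouchGeometry()
    if couch_config is not None:
        couch = CouchGeometry.from_yaml(couch_config)

    anatomy = LabelledAnatomy(
        image=image,
        body=masks["body"],
        bone=masks["bone"],
        target=masks["target"],
        extracorporeal_air=masks.get("extracorporeal_air"),
        oar=masks.get("oar"),
        couch=couch,
    )
    anatomy.validate(tol)
    return anatomy


def write_anatomy(anatomy: LabelledAnatomy, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_volume(anatomy.image, d / IMAGE_FILE)
    for name, fname in MASK_FILES.items():
        mask = anatomy.masks()[name]
        if name in REQUIRED_MASKS or mask.n_voxels:
            write_mask(mask, d / fname)
    if anatomy.couch is not None:
        anatomy.couch.to_yaml(d / COUCH_FILE)
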