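"""Target-volume-coverage prediction by exhaustive pose sweep.

The core algorithm: a regular grid of target points (one per target-mask
voxel) is tested against every admissible transducer pose. For each pose
the 256 element-to-focus rays, discretised at 0.2 mm, are checked for
intersection with acoustic obstructions (bone, extracorporeal air,
organs at risk) by nearest-voxel lookup; if *no* ray sample hits an
obstruction, an ellipsoidal treatment cell is drawn around the focus and
every grid point inside it is marked covered. Covered flags accumulate
monotonically over the sweep (a pure union, so the result is independent
of pose order). Coverage is summarised as

    TVC_pat = 100 * CV / TV          (covered / total target volume)
    TVC_vol = 100 * |A ∩ B| / |B|    (overlap of two covered-voxel sets,
                                      B being the treatment-dataset set)

Samples falling outside the volume bounds are treated as unobstructed:
they lie in the oil bath / couch region below the imaged field of view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .transducer import (
    CouchGeometry,
    PoseLimits,
    SearchBounds,
    TransducerModel,
    TransducerPose,
    TreatmentCell,
    enumerate_poses,
    pose_to_focus,
    tilt_rotation,
)
from .volume import LabelMask, LabelledAnatomy


@dataclass
class TargetGrid:
    """One world point per target-mask voxel, with a covered flag each."""

    points: np.ndarray  # (N, 3) world mm, voxel centres
    indices: np.ndarray  # (N, 3) voxel indices into the target grid
    covered: np.ndarray  # (N,) bool
    voxel_volume_mm3: float

    @classmethod
    def from_mask(cls, target: LabelMask) -> "TargetGrid":
        if target.n_voxels == 0:
            raise InputError("target mask is empty")
        idx = np.argwhere(target.data)
        pts = target.voxel_to_world(idx)
        return cls(
            points=pts,
            indices=idx,
            covered=np.zeros(len(idx), dtype=bool),
            voxel_volume_mm3=target.voxel_volume_mm3,
        )

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def covered_volume_mm3(self) -> float:
        return float(self.covered.sum()) * self.voxel_volume_mm3

    @property
    def total_volume_mm3(self) -> float:
        return self.n_points * self.voxel_volume_mm3


@dataclass
class CoverageResult:
    grid: TargetGrid
    covered_volume_mm3: float
    total_volume_mm3: float
    tvc_pat: float
    n_poses_tested: int
    n_poses_clear: int
    covered_mask: LabelMask
    settings: dict = field(default_factory=dict)

    def to_report(self) -> dict:
        return {
            "CV_mm3": self.covered_volume_mm3,
            "TV_mm3": self.total_volume_mm3,
            "tvc_pat": self.tvc_pat,
            "n_poses_tested": self.n_poses_tested,
            "n_poses_clear": self.n_poses_clear,
            "settings": self.settings,
        }


def tvc_pat(cv_mm3: float, tv_mm3: float) -> float:
    """Percentage of the target volume covered: 100 * CV / TV."""
    if tv_mm3 <= 0:
        raise InputError("total target volume must be positive")
    if not 0 <= cv_mm3 <= tv_mm3 + 1e-9:
        raise InputError(f"covered volume {cv_mm3} outside [0, {tv_mm3}]")
    return 100.0 * cv_mm3 / tv_mm3

def tvc_vol(covered_regref, covered_treat) -> float:
    """Overlap of the registered-referral covered set with the treatment one.

    Both arguments are boolean voxel sets on the shared treatment grid
    (:class:`LabelMask` or boolean arrays). The treatment covered set acts
    as the reference target: 100 * |regref ∩ treat| / |treat|.
    """
    a = covered_regref.data if isinstance(covered_regref, LabelMask) else np.asarray(covered_regref)
    b = covered_treat.data if isinstance(covered_treat, LabelMask) else np.asarray(covered_treat)
    if a.shape != b.shape:
        raise InputError(f"covered sets live on different grids: {a.shape} vs {b.shape}")
    n_treat = int(b.sum())
    if n_treat == 0:
        raise InputError("treatment covered set is empty")
    return 100.0 * int((a & b).sum()) / n_treat


def target_search_bounds(
    target: LabelMask, couch: CouchGeometry, margin: float = 0.0
) -> SearchBounds:
    """LR/IS sweep bounds from the target's bounding box (± margin).

    Returned as transducer translations from home, i.e. relative to the
    isocentre LR/IS; the AP axis is left unrestricted.
    """
    if target.n_voxels == 0:
        raise InputError("target mask is empty")
    idx = np.argwhere(target.data)
    lo = target.voxel_to_world(idx.min(axis=0))
    hi = target.voxel_to_world(idx.max(axis=0))
    iso = np.asarray(couch.isocentre, dtype=float)
    return SearchBounds(
        lr=(lo[0] - iso[0] - margin, hi[0] - iso[0] + margin),
        is_=(lo[2] - iso[2] - margin, hi[2] - iso[2] + margin),
    )


# ---------------------------------------------------------------------------
# beam obstruction testing
# ---------------------------------------------------------------------------

class _BeamTester:
    """Vectorised any-ray-blocked test against an obstruction mask.

    Per tilt angle the rotated ray cloud is cached in units of voxels, so
    each pose costs one add + round + gather over the ~180k ray samples.
    """

    def __init__(self, transducer, couch, obstruction: LabelMask, sample_spacing=0.2):
        self.transducer = transducer
        self.couch = couch
        self.obstruction = obstruction
        self.sample_spacing = sample_spacing
        self._per_tilt: dict = {}
        self._obst_any = bool(obstruction.data.any())
        shape = obstruction.shape
        self._hi = np.asarray(shape)  # clip bound; -1 and shape land on the border
        # obstruction padded with a one-voxel False border: clipped indices of
        # out-of-bounds samples land there, implementing "outside = unobstructed"
        padded = np.zeros((shape[0] + 2, shape[1] + 2, shape[2] + 2), dtype=bool)
        padded[1:-1, 1:-1, 1:-1] = obstruction.data
        self._pflat = padded.ravel()
        self._stride0 = padded.shape[1] * padded.shape[2]
        self._stride1 = padded.shape[2]

    def _base(self, tilt: float) -> np.ndarray:
        """Ray cloud at this tilt, home-relative, in voxel units, (3, K)."""
        if tilt not in self._per_tilt:
            local = self.transducer.ray_points_local(self.sample_spacing)
            cloud = local.reshape(-1, 3) @ tilt_rotation(tilt).T
            base = (cloud + (self.couch.home - self.obstruction.origin)) / self.obstruction.spacing
            self._per_tilt[tilt] = np.ascontiguousarray(base.T)
        return self._per_tilt[tilt]

    def _hits(self, pose: TransducerPose) -> np.ndarray:
        """Per-sample obstruction flags, flat over (n_elements * n_points)."""
        base = self._base(pose.tilt_lr)
        shift = np.asarray(pose.translation, dtype=float) / self.obstruction.spacing
        v = base + shift[:, None]
        np.rint(v, out=v)
        idx = v.astype(np.int64)
        np.clip(idx[0], -1, self._hi[0], out=idx[0])
        np.clip(idx[1], -1, self._hi[1], out=idx[1])
        np.clip(idx[2], -1, self._hi[2], out=idx[2])
        lin = (idx[0] + 1) * self._stride0 + (idx[1] + 1) * self._stride1 + (idx[2] + 1)
        return self._pflat.take(lin)

    def blocked_fraction(self, pose: TransducerPose) -> float:
        """Fraction of rays with at least one sample inside an obstruction."""
        if not self._obst_any:
            return 0.0
        hits = self._hits(pose)
        if not hits.any():
            return 0.0
        per_ray = hits.reshape(self.transducer.n_elements, -1).any(axis=1)
        return float(per_ray.sum()) / self.transducer.n_elements

    def is_clear(self, pose: TransducerPose, tolerated_blocked_fraction=0.0) -> bool:
        if not self._obst_any:
            return True
        if tolerated_blocked_fraction <= 0.0:
            return not bool(self._hits(pose).any())
        return self.blocked_fraction(pose) <= tolerated_blocked_fraction


def is_beam_clear(
    pose: TransducerPose,
    transducer: TransducerModel,
    anatomy: LabelledAnatomy,
    couch: CouchGeometry = None,
    sample_spacing: float = 0.2,
    tolerated_blocked_fraction: float = 0.0,
) -> bool:
    """True iff no sampled ray point maps to an obstruction voxel.

    Obstructions are the union of bone, extracorporeal air and OAR masks;
    samples outside the volume are treated as unobstructed.
    """
    couch = couch if couch is not None else (anatomy.couch or CouchGeometry())
    tester = _BeamTester(transducer, couch, anatomy.obstruction_mask(), sample_spacing)
    return tester.is_clear(pose, tolerated_blocked_fraction)


def accumulate_cell(
    pose: TransducerPose,
    grid: TargetGrid,
    transducer: TransducerModel,
    couch: CouchGeometry,
    cell: TreatmentCell = None,
) -> TargetGrid:
    """Mark grid points inside the treatment cell at this pose's focus.

    Flags are only ever set (monotone union), so repeated application is
    idempotent and pose order is irrelevant.
    """
    cell = cell if cell is not None else TreatmentCell()
    focus, axis = pose_to_focus(pose, transducer, couch)
    rel = grid.points - focus
    w = rel @ axis
    r2 = np.einsum("ij,ij->i", rel, rel) - w * w
    a = cell.diameter / 2.0
    c = cell.length / 2.0
    inside = r2 / (a * a) + (w * w) / (c * c) <= 1.0 + 1e-12
    grid.covered |= inside
    return grid


def compute_coverage(
    anatomy: LabelledAnatomy,
    transducer: TransducerModel,
    couch: CouchGeometry = None,
    limits: PoseLimits = None,
    search_bounds: SearchBounds = None,
    cell: TreatmentCell = None,
    step: float = None,
    sample_spacing: float = 0.2,
    margin: float = 0.0,
    tolerated_blocked_fraction: float = 0.0,
) -> CoverageResult:
    """Exhaustive pose sweep over the target: the end-to-end coverage run.

    Enumerates the pose grid (LR/IS restricted to the target extents
    unless explicit bounds are given, AP over the full device range, all
    tilts), tests each pose's beam for obstruction, accumulates treatment
    cells for clear poses, and returns covered volume and TVC_pat.
    """
    couch = couch if couch is not None else (anatomy.couch or CouchGeometry())
    limits = limits if limits is not None else PoseLimits()
    cell = cell if cell is not None else TreatmentCell()
    if search_bounds is None:
        search_bounds = target_search_bounds(anatomy.target, couch, margin)

    grid = TargetGrid.from_mask(anatomy.target)
    poses = enumerate_poses(limits, search_bounds, step)
    tester = _BeamTester(transducer, couch, anatomy.obstruction_mask(), sample_spacing)

    n_clear = 0
    for pose in poses:
        if tester.is_clear(pose, tolerated_blocked_fraction):
            n_clear += 1
            accumulate_cell(pose, grid, transducer, couch, cell)

    covered = np.zeros(anatomy.target.shape, dtype=bool)
    ci = grid.indices[grid.covered]
    covered[ci[:, 0], ci[:, 1], ci[:, 2]] = True
    cv = grid.covered_volume_mm3
    tv = grid.total_volume_mm3
    return CoverageResult(
        grid=grid,
        covered_volume_mm3=cv,
        total_volume_mm3=tv,
        tvc_pat=tvc_pat(cv, tv),
        n_poses_tested=len(poses),
        n_poses_clear=n_clear,
        covered_mask=LabelMask.like(covered, anatomy.target),
        settings={
            "step_mm": step if step is not None else limits.translation_step,
            "sample_spacing_mm": sample_spacing,
            "cell_diameter_mm": cell.diameter,
            "cell_length_mm": cell.length,
            "tilt_max_deg": limits.tilt_max,
            "tilt_step_deg": limits.tilt_step,
            "tolerated_blocked_fraction": tolerated_blocked_fraction,
            "isocentre_mm": [float(v) for v in couch.isocentre],
        },
    )
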