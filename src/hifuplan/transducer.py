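"""Geometric model of a Sonalleve-V2-class HIFU transducer and couch.

The device is a 256-element phased array (130 mm aperture, 140 mm focal
length, 1.22 MHz) mounted under the couch in an oil bath. Its home
position lies 140 mm below the magnetic isocentre; the undeformed
oil-bath membrane lies 72.5 mm below the isocentre, hence 67.5 mm above
the home position. From home it can translate 72.5 mm left/right and
inferior/superior, 34 mm toward the patient (anterior) and 33 mm away,
and tilt up to 10 degrees in 2.5-degree steps about the IS axis
(left-right tilt only).

The acoustic beam is represented as 256 straight rays, one per element
centre, converging on the focus; each sonication ablates an idealised
ellipsoidal treatment cell (8 mm diameter x 21.84 mm length) centred on
the focus with its long axis along the beam axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, PoseError

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class CouchGeometry:
    """Vertical couch calibration relative to the magnetic isocentre (mm)."""

    isocentre: tuple = (0.0, 0.0, 0.0)
    home_below_isocentre: float = 140.0
    membrane_below_isocentre: float = 72.5

    @property
    def membrane_to_home(self) -> float:
        """Calibrated distance from the undeformed membrane down to home."""
        return self.home_below_isocentre - self.membrane_below_isocentre

    @property
    def home(self) -> np.ndarray:
        iso = np.asarray(self.isocentre, dtype=float)
        return iso - np.array([0.0, self.home_below_isocentre, 0.0])

    def with_isocentre(self, isocentre) -> "CouchGeometry":
        return replace(self, isocentre=tuple(np.asarray(isocentre, dtype=float)))

    @classmethod
    def from_yaml(cls, path) -> "CouchGeometry":
        cfg = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            isocentre=tuple(cfg.get("isocentre_mm", (0.0, 0.0, 0.0))),
            home_below_isocentre=float(cfg.get("home_below_isocentre_mm", 140.0)),
            membrane_below_isocentre=float(cfg.get("membrane_below_isocentre_mm", 72.5)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "isocentre_mm": [float(v) for v in self.isocentre],
                    "home_below_isocentre_mm": self.home_below_isocentre,
                    "membrane_below_isocentre_mm": self.membrane_below_isocentre,
                },
                sort_keys=False,
            )
        )


@dataclass(frozen=True)
class PoseLimits:
    """Device motion limits (mm / degrees) and search-grid steps."""

    lr: float = 72.5
    is_: float = 72.5
    ap_toward_patient: float = 34.0
    ap_away: float = 33.0
    tilt_max: float = 10.0
    tilt_step: float = 2.5
    translation_step: float = 4.0  # 4 mm whole-pelvis targets, 2 mm tumors


@dataclass(frozen=True)
class TransducerPose:
    """One translation (lr, ap, is) from home plus a left-right tilt."""

    translation: tuple = (0.0, 0.0, 0.0)
    tilt_lr: float = 0.0

    def check(self, limits: PoseLimits) -> None:
        lr, ap, is_ = self.translation
        eps = 1e-9
        if abs(lr) > limits.lr + eps:
            raise PoseError(f"LR translation {lr} mm exceeds ±{limits.lr} mm")
        if abs(is_) > limits.is_ + eps:
            raise PoseError(f"IS translation {is_} mm exceeds ±{limits.is_} mm")
        if not (-limits.ap_away - eps <= ap <= limits.ap_toward_patient + eps):
            raise PoseError(
                f"AP translation {ap} mm outside [-{limits.ap_away}, "
                f"{limits.ap_toward_patient}] mm"
            )
        if abs(self.tilt_lr) > limits.tilt_max + eps:
            raise PoseError(f"tilt {self.tilt_lr} deg exceeds ±{limits.tilt_max} deg")


@dataclass
class TransducerModel:
    """Element layout of the spherical-cap phased array.

    ``element_positions`` are offsets (mm) of the element centres from the
    transducer apex in the device's local frame: apex at the origin, beam
    axis along +AP, focus at ``(0, focal_length, 0)``. Every element lies
    exactly ``focal_length`` from the focus and within
    ``aperture_diameter/2`` of the beam axis in projection.
    """

    n_elements: int = 256
    aperture_diameter: float = 130.0
    focal_length: float = 140.0
    frequency_mhz: float = 1.22  # metadata only; no acoustics are modelled
    element_positions: np.ndarray = None
    _ray_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def focus_local(self) -> np.ndarray:
        return np.array([0.0, self.focal_length, 0.0])

    def ray_points_local(self, sample_spacing: float = 0.2) -> np.ndarray:
        """Sampled ray points in the local frame, cached per spacing.

        Shape ``(n_elements, n_points, 3)``; points run from each element
        centre toward the focus, inclusive of the element end and exclusive
        of the focus itself (the focus lies inside the target). The point
        count per ray is ``floor(ray_length / sample_spacing)``.
        """
        key = float(sample_spacing)
        if key not in self._ray_cache:
            if sample_spacing <= 0:
                raise ConfigError("sample_spacing must be positive")
            elems = self.element_positions
            vecs = self.focus_local - elems  # (n, 3)
            lengths = np.linalg.norm(vecs, axis=1)
            # tolerance so an exact multiple (140 / 0.2) is not lost to fp error
            n_pts = int(np.floor(lengths.min() / sample_spacing + 1e-6))
            # all rays share one length on a spherical cap; guard anyway
            units = vecs / lengths[:, None]
            s = sample_spacing * np.arange(n_pts)
            pts = elems[:, None, :] + s[None, :, None] * units[:, None, :]
            self._ray_cache[key] = pts
        return self._ray_cache[key]


def build_transducer(
    n_elements: int = 256,
    aperture_diameter: float = 130.0,
    focal_length: float = 140.0,
    frequency_mhz: float = 1.22,
    layout: str = "fermat",
) -> TransducerModel:
    """Deterministically place element centres on the spherical cap.

    The default layout is a Fermat (sunflower) spiral giving near-uniform
    area density from the apex to the rim; ``layout="rings"`` places the
    elements on concentric rings instead. Both layouts include an element
    at the apex and reach the full aperture.
    """
    if n_elements < 1:
        raise ConfigError("n_elements must be >= 1")
    if not aperture_diameter < 2.0 * focal_length:
        raise ConfigError(
            f"aperture ({aperture_diameter} mm) must be smaller than twice "
            f"the focal length ({focal_length} mm)"
        )
    theta_max = np.arcsin(0.5 * aperture_diameter / focal_length)
    if layout == "fermat":
        if n_elements == 1:
            theta = np.zeros(1)
        else:
            frac = np.arange(n_elements) / (n_elements - 1)
            theta = np.arccos(1.0 - frac * (1.0 - np.cos(theta_max)))
        phi = GOLDEN_ANGLE * np.arange(n_elements)
    elif layout == "rings":
        n_rings = max(1, int(round(np.sqrt(n_elements))))
        ring_of = np.minimum((np.arange(n_elements) * n_rings) // n_elements, n_rings - 1)
        theta = theta_max * ring_of / max(n_rings - 1, 1)
        phi = np.empty(n_elements)
        for r in range(n_rings):
            sel = ring_of == r
            phi[sel] = 2.0 * np.pi * np.arange(sel.sum()) / max(sel.sum(), 1)
    else:
        raise ConfigError(f"unknown element layout '{layout}'")

    # unit vectors from the focus toward each element (beam axis is +AP)
    u = np.stack(
        [np.sin(theta) * np.cos(phi), -np.cos(theta), np.sin(theta) * np.sin(phi)],
        axis=1,
    )
    focus_local = np.array([0.0, focal_length, 0.0])
    elements = focus_local + focal_length * u
    return TransducerModel(
        n_elements=n_elements,
        aperture_diameter=aperture_diameter,
        focal_length=focal_length,
        frequency_mhz=frequency_mhz,
        element_positions=elements,
    )


def transducer_from_yaml(path) -> tuple[TransducerModel, PoseLimits, "TreatmentCell"]:
    """Read device geometry (transducer, limits, cell) from a YAML config."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    model = build_transducer(
        n_elements=int(cfg.get("n_elements", 256)),
        aperture_diameter=float(cfg.get("aperture_mm", 130.0)),
        focal_length=float(cfg.get("focal_length_mm", 140.0)),
        frequency_mhz=float(cfg.get("frequency_mhz", 1.22)),
        layout=cfg.get("layout", "fermat"),
    )
    lim = cfg.get("limits", {})
    limits = PoseLimits(
        lr=float(lim.get("lr_mm", 72.5)),
        is_=float(lim.get("is_mm", 72.5)),
        ap_toward_patient=float(lim.get("ap_toward_patient_mm", 34.0)),
        ap_away=float(lim.get("ap_away_mm", 33.0)),
        tilt_max=float(lim.get("tilt_max_deg", 10.0)),
        tilt_step=float(lim.get("tilt_step_deg", 2.5)),
        translation_step=float(lim.get("translation_step_mm", 4.0)),
    )
    cell = TreatmentCell(
        diameter=float(cfg.get("cell_diameter_mm", 8.0)),
        length=float(cfg.get("cell_length_mm", 21.84)),
    )
    return model, limits, cell


# ---------------------------------------------------------------------------
# poses
# ---------------------------------------------------------------------------

def tilt_rotation(tilt_deg: float) -> np.ndarray:
    """Rotation about the IS axis; positive tilt leans the beam toward +LR."""
    t = np.deg2rad(tilt_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def pose_to_focus(
    pose: TransducerPose, transducer: TransducerModel, couch: CouchGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """World focus position and unit beam axis for a pose.

    At zero translation and tilt the focus sits at the magnetic isocentre
    (home + focal length along +AP). Tilt rotates the beam about the IS
    axis through the transducer apex, so a tilted focus moves laterally by
    ``F sin(t)`` and down by ``F (1 - cos(t))``.
    """
    apex = couch.home + np.asarray(pose.translation, dtype=float)
    axis = tilt_rotation(pose.tilt_lr) @ np.array([0.0, 1.0, 0.0])
    focus = apex + transducer.focal_length * axis
    return focus, axis


@dataclass(frozen=True)
class SearchBounds:
    """Per-axis translation intervals (mm from home) restricting the sweep.

    ``lr`` and ``is_`` normally come from the target extents; ``ap`` is
    ``None`` to sweep the full anterior-posterior device range.
    """

    lr: tuple = None
    is_: tuple = None
    ap: tuple = None


def _axis_values(lo: float, hi: float, step: float) -> np.ndarray:
    if hi < lo:
        return np.empty(0)
    n = int(np.floor((hi - lo) / step + 1e-9))
    return lo + step * np.arange(n + 1)


def enumerate_poses(
    limits: PoseLimits,
    search_bounds: SearchBounds = None,
    step: float = None,
) -> list[TransducerPose]:
    """Regular pose grid over the intersection of bounds and device limits.

    LR and IS run over ``search_bounds`` clipped to the device limits; AP
    runs over its full device range unless bounded; tilt runs from
    ``-tilt_max`` to ``+tilt_max`` in ``tilt_step`` increments. Ordering is
    deterministic: LR, then IS, then AP, then tilt, each ascending. An
    empty intersection yields an empty list with a warning.
    """
    if search_bounds is None:
        search_bounds = SearchBounds()
    if step is None:
        step = limits.translation_step

    def clipped(bounds, lo_dev, hi_dev, name):
        lo, hi = (bounds if bounds is not None else (lo_dev, hi_dev))
        vals = _axis_values(max(lo, lo_dev), min(hi, hi_dev), step)
        if vals.size == 0:
            warnings.warn(
                f"{name} search bounds {bounds} do not intersect the device "
                f"limits [{lo_dev}, {hi_dev}]; no poses generated",
                stacklevel=3,
            )
        return vals

    lr_vals = clipped(search_bounds.lr, -limits.lr, limits.lr, "LR")
    is_vals = clipped(search_bounds.is_, -limits.is_, limits.is_, "IS")
    ap_vals = clipped(search_bounds.ap, -limits.ap_away, limits.ap_toward_patient, "AP")
    n_tilt = int(np.floor(limits.tilt_max / limits.tilt_step + 1e-9))
    tilt_vals = limits.tilt_step * np.arange(-n_tilt, n_tilt + 1)
    if min(lr_vals.size, is_vals.size, ap_vals.size) == 0:
        return []
    return [
        TransducerPose(translation=(float(lr), float(ap), float(is_)), tilt_lr=float(t))
        for lr in lr_vals
        for is_ in is_vals
        for ap in ap_vals
        for t in tilt_vals
    ]


def trace_beam(
    pose: TransducerPose,
    transducer: TransducerModel,
    couch: CouchGeometry,
    sample_spacing: float = 0.2,
) -> np.ndarray:
    """World-frame ray samples for one pose, shape ``(n_elements, n_pts, 3)``.

    Each ray runs from an element centre to the focus, discretised at
    ``sample_spacing`` mm (element end included, focus excluded).
    """
    local = transducer.ray_points_local(sample_spacing)
    rot = tilt_rotation(pose.tilt_lr)
    apex = couch.home + np.asarray(pose.translation, dtype=float)
    return local @ rot.T + apex


# ---------------------------------------------------------------------------
# treatment cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreatmentCell:
    """Idealised ellipsoidal ablation volume of a single sonication."""

    diameter: float = 8.0
    length: float = 21.84
    center: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (0.0, 1.0, 0.0)

    @property
    def semi_axes(self) -> tuple:
        return (self.diameter / 2.0, self.diameter / 2.0, self.length / 2.0)

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def at(self, center, axis) -> "TreatmentCell":
        return TreatmentCell(self.diameter, self.length, tuple(center), tuple(axis))


def point_in_cell(points, cell: TreatmentCell):
    """True where a world point lies inside (or on) the cell ellipsoid."""
    pts = np.asarray(points, dtype=float)
    center = np.asarray(cell.center, dtype=float)
    axis = np.asarray(cell.axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rel = pts - center
    w = rel @ axis
    r2 = np.einsum("...i,...i", rel, rel) - w * w
    a = cell.diameter / 2.0
    c = cell.length / 2.0
    return r2 / (a * a) + (w * w) / (c * c) <= 1.0 + 1e-12
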