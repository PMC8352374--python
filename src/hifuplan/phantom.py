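"""Deterministic digital pelvis-on-couch phantoms.

Every pipeline stage is testable without clinical data: the generator
emulates a subject lying (optionally tilted toward oblique supine
decubitus) on a compressed gel-pad over the bowed oil-bath membrane of
the HIFU couch. Anatomy is parametric: an elliptic-cylinder body flattened
where it presses into the pad, a pelvic-ring bone shell with one angular
gap playing the role of the sciatic-notch acoustic window, an ellipsoidal
tumor target, optional organ-at-risk ellipsoids, and optional lens-shaped
air gaps carved out of the gel-pad top (coupling defects). Intensities
are Gaussian per tissue class with a fixed seed, so identical specs give
bit-identical phantoms.

The couch arithmetic is self-consistent: with membrane bowing ``b`` and
compressed pad thickness ``t``, the skin plane sits at
``-(membrane_below_isocentre + b) + t`` so that the home-position chain
``skin - t + b - membrane_to_home`` lands exactly 140 mm below the
isocentre.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .registration import AffineTransform, LandmarkSet
from .transducer import CouchGeometry, tilt_rotation
from .volume import (
    LabelMask,
    LabelledAnatomy,
    VoxelVolume,
    write_anatomy,
    write_mask,
)


@dataclass(frozen=True)
class BodySpec:
    """Elliptic-cylinder trunk (axis along IS), flattened on the couch."""

    center_lr: float = 0.0
    center_ap: float = 0.0
    half_lr: float = 115.0
    half_ap: float = 85.0


@dataclass(frozen=True)
class BoneRingSpec:
    """Pelvic-ring shell with an angular acoustic-window gap.

    The gap is centred on the posterior (-AP) direction, where the beam
    enters from the transducer below; ``window_halfangle_deg`` is the
    half-width of the bone-free arc.
    """

    inner_radius: float = 40.0
    outer_radius: float = 55.0
    half_length_is: float = 45.0
    window_halfangle_deg: float = 55.0
    center: tuple = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class EllipsoidSpec:
    center: tuple = (0.0, 0.0, 0.0)
    half_axes: tuple = (17.0, 17.0, 17.0)


@dataclass(frozen=True)
class GelPadSpec:
    nominal_thickness: float = 15.0
    compressed_thickness: float = 9.8
    bowing: float = 10.0
    half_width_lr: float = 110.0


@dataclass(frozen=True)
class AirDefectSpec:
    """Lens-shaped coupling gap carved downward from the gel-pad top."""

    center_lr: float = 0.0
    center_is: float = 0.0
    radius: float = 35.0
    depth: float = 3.0


@dataclass(frozen=True)
class IntensitySpec:
    """Per-class (mean, noise SD) intensities, arbitrary units."""

    air: tuple = (50.0, 20.0)
    gelpad: tuple = (700.0, 20.0)
    body: tuple = (1000.0, 20.0)
    oar: tuple = (900.0, 20.0)
    tumor: tuple = (1150.0, 20.0)
    bone: tuple = (1300.0, 20.0)


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple = (192, 160, 96)
    spacing: tuple = (1.5, 1.5, 1.5)
    ap_min: float = -100.5  # world AP of the lowest voxel centre
    body: BodySpec = field(default_factory=BodySpec)
    bone: BoneRingSpec = field(default_factory=BoneRingSpec)  # None -> no ring
    bone_boxes: tuple = ()  # extra axis-aligned obstruction boxes
    tumor: EllipsoidSpec = field(default_factory=EllipsoidSpec)
    oars: tuple = ()
    gelpad: GelPadSpec = field(default_factory=GelPadSpec)
    has_gelpad: bool = True
    air_defects: tuple = ()
    tilt_deg: float = 0.0
    intensities: IntensitySpec = field(default_factory=IntensitySpec)
    couch: CouchGeometry = field(default_factory=CouchGeometry)
    seed: int = 0
    n_landmarks: int = 12

    @property
    def skin_plane_ap(self) -> float:
        """World AP of the flattened skin surface resting on the pad."""
        iso_ap = float(self.couch.isocentre[1])
        return (
            iso_ap
            - self.couch.membrane_below_isocentre
            - self.gelpad.bowing
            + self.gelpad.compressed_thickness
        )

    @property
    def origin(self) -> np.ndarray:
        sx, sy, sz = self.spacing
        nx, ny, nz = self.shape
        return np.array(
            [-(nx - 1) * sx / 2.0, self.ap_min, -(nz - 1) * sz / 2.0]
        )

    @classmethod
    def mini(cls, **overrides) -> "PhantomSpec":
        """Tiny 48^3 profile for oracle tests: no couch hardware in-grid."""
        defaults = dict(
            shape=(48, 48, 48),
            spacing=(2.0, 2.0, 2.0),
            ap_min=-62.0,
            body=BodySpec(half_lr=40.0, half_ap=40.0),
            bone=None,
            tumor=EllipsoidSpec(half_axes=(10.0, 10.0, 10.0)),
            has_gelpad=False,
            n_landmarks=10,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def validate(self) -> None:
        if self.gelpad.compressed_thickness > self.gelpad.nominal_thickness:
            raise ConfigError(
                "compressed gel-pad thickness exceeds the nominal thickness"
            )
        if min(self.spacing) <= 0:
            raise ConfigError("voxel spacing must be positive")
        if self.bone is not None and self.bone.inner_radius >= self.bone.outer_radius:
            raise ConfigError("bone ring inner radius must be below the outer radius")


@dataclass
class Phantom:
    spec: PhantomSpec
    anatomy: LabelledAnatomy
    landmarks: LandmarkSet
    gelpad_mask: LabelMask
    truth: dict


@dataclass
class PhantomPair:
    referral: Phantom
    treatment: Phantom
    true_affine: AffineTransform


def _tilt_affine(tilt_deg: float, isocentre) -> AffineTransform:
    rot = tilt_rotation(tilt_deg)
    iso = np.asarray(isocentre, dtype=float)
    return AffineTransform(rot, iso - rot @ iso)


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelise one phantom: image, exact masks, landmarks and truth record.

    Shapes are defined in the untilted body frame and rotated about the IS
    axis through the isocentre by ``tilt_deg``; when a gel-pad is present
    (or the subject lies on a flat couch) the body is clipped at the skin
    plane, emulating soft-tissue flattening under load.
    """
    spec.validate()
    origin = spec.origin
    nx, ny, nz = spec.shape
    sx, sy, sz = spec.spacing
    x = origin[0] + sx * np.arange(nx)
    y = origin[1] + sy * np.arange(ny)
    z = origin[2] + sz * np.arange(nz)
    X = x[:, None, None]
    Y = y[None, :, None]
    Z = z[None, None, :]
    iso = np.asarray(spec.couch.isocentre, dtype=float)

    # body-frame coordinates: rotate world by -tilt about IS through the isocentre
    a = np.deg2rad(spec.tilt_deg)
    c, s = np.cos(a), np.sin(a)
    xb = (X - iso[0]) * c + (Y - iso[1]) * s + iso[0]  # (nx, ny, 1)
    yb = -(X - iso[0]) * s + (Y - iso[1]) * c + iso[1]

    b = spec.body
    body2d = ((xb - b.center_lr) / b.half_lr) ** 2 + (
        (yb - b.center_ap) / b.half_ap
    ) ** 2 <= 1.0
    y_skin = spec.skin_plane_ap
    body = np.broadcast_to(body2d & (Y >= y_skin), spec.shape).copy()

    bone = np.zeros(spec.shape, dtype=bool)
    if spec.bone is not None:
        r = spec.bone
        rcx, rcy, rcz = r.center
        rad = np.hypot(xb - rcx, yb - rcy)
        ang = np.degrees(np.arctan2(yb - rcy, xb - rcx))
        from_window = np.abs((ang + 90.0 + 180.0) % 360.0 - 180.0)
        ring2d = (
            (rad >= r.inner_radius)
            & (rad <= r.outer_radius)
            & (from_window > r.window_halfangle_deg)
        )
        bone |= ring2d & (np.abs(Z - rcz) <= r.half_length_is)
    for box in spec.bone_boxes:
        (x0, x1), (y0, y1), (z0, z1) = box
        bone |= np.broadcast_to(
            (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1) & (Z >= z0) & (Z <= z1),
            spec.shape,
        )
    bone &= body

    def ellipsoid(e: EllipsoidSpec) -> np.ndarray:
        ex, ey, ez = e.center
        ax, ay, az = e.half_axes
        return ((xb - ex) / ax) ** 2 + ((yb - ey) / ay) ** 2 + (
            (Z - ez) / az
        ) ** 2 <= 1.0

    tumor_raw = ellipsoid(spec.tumor)
    tumor = tumor_raw & body & ~bone
    if tumor.sum() == 0:
        raise ConfigError("tumor ellipsoid lies outside the body")
    if (tumor_raw & bone).any():
        raise ConfigError(
            f"tumor overlaps the bone shell in {int((tumor_raw & bone).sum())} voxel(s)"
        )

    oar = np.zeros(spec.shape, dtype=bool)
    for e in spec.oars:
        oar |= ellipsoid(e)
    oar &= body & ~bone & ~tumor

    gelpad = np.zeros(spec.shape, dtype=bool)
    air = np.zeros(spec.shape, dtype=bool)
    if spec.has_gelpad:
        g = spec.gelpad
        y_mem = iso[1] - spec.couch.membrane_below_isocentre - g.bowing
        gelpad = np.broadcast_to(
            (np.abs(X - iso[0]) <= g.half_width_lr) & (Y >= y_mem) & (Y <= y_skin),
            spec.shape,
        ).copy()
        gelpad &= ~body
        for d in spec.air_defects:
            r2 = ((X - d.center_lr) ** 2 + (Z - d.center_is) ** 2) / (d.radius**2)
            carve_depth = d.depth * np.maximum(1.0 - r2, 0.0)
            lens = (Y > y_skin - carve_depth) & (Y <= y_skin) & (r2 <= 1.0)
            lens = np.broadcast_to(lens, spec.shape) & gelpad
            air |= lens
        gelpad &= ~air

    ints = spec.intensities
    mean_map = np.full(spec.shape, ints.air[0])
    sd_map = np.full(spec.shape, ints.air[1])
    for mask, (mu, sd) in (
        (gelpad, ints.gelpad),
        (body, ints.body),
        (oar, ints.oar),
        (tumor, ints.tumor),
        (bone, ints.bone),
    ):
        mean_map[mask] = mu
        sd_map[mask] = sd
    rng = np.random.default_rng(spec.seed)
    data = mean_map + sd_map * rng.standard_normal(spec.shape)

    image = VoxelVolume(data, spec.spacing, origin)
    anatomy = LabelledAnatomy(
        image=image,
        body=LabelMask.like(body, image),
        bone=LabelMask.like(bone, image),
        target=LabelMask.like(tumor, image),
        extracorporeal_air=LabelMask.like(air, image),
        oar=LabelMask.like(oar, image),
        couch=spec.couch,
    )
    anatomy.validate()

    landmarks = _bone_landmarks(spec)
    affine = _tilt_affine(spec.tilt_deg, iso)
    truth = {
        "seed": spec.seed,
        "tilt_deg": spec.tilt_deg,
        "isocentre_mm": [float(v) for v in iso],
        "skin_plane_ap_mm": y_skin,
        "gelpad_thickness_mm": spec.gelpad.compressed_thickness,
        "membrane_bowing_mm": spec.gelpad.bowing,
        "has_gelpad": spec.has_gelpad,
        "n_air_defects": len(spec.air_defects),
        "affine_from_supine": affine.to_json(),
        "tumor_center_mm": [float(v) for v in spec.tumor.center],
        "tumor_half_axes_mm": [float(v) for v in spec.tumor.half_axes],
    }
    return Phantom(
        spec=spec,
        anatomy=anatomy,
        landmarks=landmarks,
        gelpad_mask=LabelMask.like(gelpad, image),
        truth=truth,
    )


def _bone_landmarks(spec: PhantomSpec) -> LandmarkSet:
    """Deterministic bony landmarks on the (tilted) pelvic ring surface.

    Points sit on the outer ring radius, spread over the bone-bearing arc
    at three IS levels; they are analytic (not voxelised), so they rotate
    exactly with the phantom tilt. Without a bone ring they fall back to
    the body surface so a landmark file always exists.
    """
    n = max(int(spec.n_landmarks), 10)
    iso = np.asarray(spec.couch.isocentre, dtype=float)
    if spec.bone is not None:
        r = spec.bone
        margin = 12.0
        start = -90.0 + r.window_halfangle_deg + margin
        stop = 270.0 - r.window_halfangle_deg - margin
        radius = r.outer_radius
        center = np.asarray(r.center, dtype=float)
        z_levels = np.array([-0.5, 0.0, 0.5]) * r.half_length_is
    else:
        start, stop = 0.0, 360.0 * (n - 1) / n
        radius = 0.8 * spec.body.half_lr
        center = np.array([spec.body.center_lr, spec.body.center_ap, 0.0])
        z_levels = np.array([-20.0, 0.0, 20.0])
    angles = np.deg2rad(np.linspace(start, stop, n))
    pts = np.stack(
        [
            center[0] + radius * np.cos(angles),
            center[1] + radius * np.sin(angles),
            center[2] + z_levels[np.arange(n) % len(z_levels)],
        ],
        axis=1,
    )
    world = _tilt_affine(spec.tilt_deg, iso).apply(pts)
    names = [f"L{i:02d}" for i in range(n)]
    return LandmarkSet(names, world)


def make_referral_treatment_pair(spec: PhantomSpec) -> PhantomPair:
    """A supine referral phantom and its tilted on-couch treatment twin.

    The referral subject lies flat (tilt 0) on a plain couch: no gel-pad,
    no coupling defects, independent image noise. The treatment phantom
    follows ``spec``. Landmarks are paired one-to-one and the exact affine
    linking referral to treatment space is returned.
    """
    treatment = generate_phantom(spec)
    referral_spec = replace(
        spec,
        tilt_deg=0.0,
        has_gelpad=False,
        air_defects=(),
        seed=(spec.seed + 1000003) % (2**31),
    )
    referral = generate_phantom(referral_spec)
    return PhantomPair(
        referral=referral,
        treatment=treatment,
        true_affine=_tilt_affine(spec.tilt_deg, spec.couch.isocentre),
    )


def write_phantom(phantom: Phantom, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_anatomy(phantom.anatomy, d)
    if phantom.gelpad_mask.n_voxels:
        write_mask(phantom.gelpad_mask, d / "gelpad.nii.gz")
    phantom.landmarks.write_csv(d / "landmarks.csv")
    (d / "truth.json").write_text(json.dumps(phantom.truth, indent=2))
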