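"""Transducer home-position estimation for a registered-referral dataset.

In treatment imaging the magnetic isocentre (and hence the home position,
a fixed 140 mm below it) is known. For a registered-referral dataset only
the anterior-posterior coordinate must be derived. The chain: drop a
vertical line from the isocentre to the skin; from that skin point go
down the compressed gel-pad thickness t to the bowed membrane, up the
bowing distance b to the undeformed membrane plane, then down the
calibrated membrane-to-home distance (67.5 mm):

    home_AP = skin_AP - t + b - membrane_to_home

The chain is linear, so assuming wrong deformations (t_a, b_a) when the
truth is (t, b) displaces home by exactly (b_a - b) - (t_a - t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PositioningError
from .transducer import CouchGeometry
from .volume import LabelMask


@dataclass(frozen=True)
class DeformationParams:
    """Couch-loading deformation assumptions (mm).

    Defaults are the volunteer-cohort means for a nominal 15 mm gel-pad:
    9.8 mm compressed thickness and 10.0 mm membrane bowing at the
    isocentre line.
    """

    gelpad_thickness: float = 9.8
    membrane_bowing: float = 10.0
    nominal_gelpad: float = 15.0  # metadata

    def __post_init__(self):
        if self.gelpad_thickness <= 0:
            raise ValueError("gel-pad thickness must be positive")
        if self.membrane_bowing < 0:
            raise ValueError("membrane bowing must be non-negative")


def find_skin_point(
    body: LabelMask, isocentre_lr_is, neighborhood_mm: float = 0.0
) -> np.ndarray:
    """Most-posterior body voxel centre on the vertical isocentre line.

    ``isocentre_lr_is`` is the (LR, IS) world position of the line. With
    ``neighborhood_mm`` > 0, the skin AP is averaged over the columns in a
    square LR-IS neighbourhood of that size (off by default; single-column
    sampling matches the reference workflow).
    """
    x, z = float(isocentre_lr_is[0]), float(isocentre_lr_is[1])
    half = neighborhood_mm / 2.0
    lr = body.axis_coords(0)
    is_ = body.axis_coords(2)
    sel_i = np.where(np.abs(lr - x) <= max(half, body.spacing[0] / 2.0))[0]
    sel_k = np.where(np.abs(is_ - z) <= max(half, body.spacing[2] / 2.0))[0]
    if sel_i.size == 0 or sel_k.size == 0:
        raise PositioningError(
            f"isocentre column (LR={x}, IS={z}) lies outside the volume"
        )
    cols = body.data[np.ix_(sel_i, np.arange(body.shape[1]), sel_k)]
    has = cols.any(axis=1)
    if not has.any():
        raise PositioningError(
            f"vertical line at (LR={x}, IS={z}) does not intersect the body"
        )
    first = np.argmax(cols, axis=1)  # lowest body voxel per column (+AP is up)
    ap = body.axis_coords(1)
    skin_ap = float(ap[first[has]].mean())
    return np.array([x, skin_ap, z])


def estimate_home_position(
    skin_point, params: DeformationParams, couch: CouchGeometry = None
) -> np.ndarray:
    """Home position from a skin point via the deformation chain.

    LR/IS are inherited from the isocentre column; the AP coordinate is
    ``skin_AP - t + b - membrane_to_home``.
    """
    couch = couch if couch is not None else CouchGeometry()
    p = np.asarray(skin_point, dtype=float).reshape(3)
    home_ap = p[1] - params.gelpad_thickness + params.membrane_bowing - couch.membrane_to_home
    return np.array([p[0], home_ap, p[2]])


def isocentre_from_home(home, couch: CouchGeometry = None) -> np.ndarray:
    """The magnetic isocentre lies a fixed distance straight above home."""
    couch = couch if couch is not None else CouchGeometry()
    h = np.asarray(home, dtype=float).reshape(3)
    return h + np.array([0.0, couch.home_below_isocentre, 0.0])
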