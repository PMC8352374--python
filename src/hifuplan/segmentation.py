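"""Automatic body-outline and extracorporeal-air segmentation.

The body outline separates the subject from surrounding air and from the
gel-pad they lie on: Otsu thresholding, connected-components labelling,
morphological closing and slice-wise hole filling. Extracorporeal air at
the body/gel-pad interface defines where acoustic coupling fails; it is
found as below-threshold voxels outside the body within a band of the
interface. Both are deterministic (no randomness).

Body/gel-pad separation: the primary rule is connected-component
separation after thresholding (an air or membrane gap splits them). When
the pad is fused to the body, a guarded second-stage Otsu split inside
the foreground removes the lower-intensity pad component; the guard
requires the candidate pad to be a minority of the foreground, clearly
posterior to (below) the body, and separated in intensity by well more
than the within-class noise, so a pad-free image is never split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu

from .errors import SegmentationError
from .volume import LabelMask, VoxelVolume


@dataclass(frozen=True)
class SegmentationParams:
    closing_radius: float = 3.0  # mm (~2 voxels at 1.5 mm)
    min_component_volume: float = 10000.0  # mm^3
    air_band_height: float = 10.0  # mm above/below the coupling interface

    def __post_init__(self):
        if min(self.closing_radius, self.min_component_volume, self.air_band_height) < 0:
            raise ValueError("segmentation parameters must be non-negative")


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lbl, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    return lbl == (1 + int(np.argmax(sizes)))


def _split_off_gelpad(fg: np.ndarray, data: np.ndarray, volume: VoxelVolume) -> np.ndarray:
    """Remove a fused gel-pad from a foreground component, if one is present.

    The pad is the lowest-intensity tissue class inside the foreground, so
    the lowest of the 3-class multi-Otsu thresholds separates it even when
    brighter classes (bone, tumor) would dominate a plain 2-class split.
    """
    vals = data[fg]
    if vals.size < 2 or np.ptp(vals) == 0:
        return fg
    try:
        th2 = threshold_multiotsu(vals, classes=3)[0]
    except ValueError:  # too few distinct values for a 3-class split
        th2 = threshold_otsu(vals)
    low = fg & (data <= th2)
    high = fg & (data > th2)
    if not low.any() or not high.any():
        return fg
    frac = low.sum() / fg.sum()
    if not 0.005 < frac < 0.45:
        return fg
    ap = volume.axis_coords(1)
    low_ap = float(np.average(ap, weights=low.sum(axis=(0, 2))))
    high_ap = float(np.average(ap, weights=high.sum(axis=(0, 2))))
    if low_ap >= high_ap - 2.0 * volume.spacing[1]:
        return fg
    sep = float(data[high].mean() - data[low].mean())
    noise = 0.5 * (float(data[high].std()) + float(data[low].std()))
    if sep <= 4.0 * noise:
        return fg
    return high


def segment_body_outline(
    image: VoxelVolume, params: SegmentationParams = None
) -> LabelMask:
    """Segment the body outline from an intensity volume.

    Expects bimodal foreground/background intensities. Returns a single
    connected component with internal holes filled slice-wise (axial
    planes) and the gel-pad excluded.
    """
    params = params or SegmentationParams()
    data = np.asarray(image.data, dtype=float)
    if np.ptp(data) == 0:
        raise SegmentationError("image is constant; nothing to segment")
    th = threshold_otsu(data)
    fg = data > th

    min_vox = max(1, int(round(params.min_component_volume / image.voxel_volume_mm3)))
    lbl, n = ndimage.label(fg)
    if n == 0:
        raise SegmentationError("no foreground found above the Otsu threshold")
    sizes = ndimage.sum_labels(np.ones_like(lbl), lbl, index=np.arange(1, n + 1))
    if sizes.max() < min_vox:
        raise SegmentationError(
            f"largest foreground component ({int(sizes.max())} voxels) is below "
            f"the minimum body volume ({min_vox} voxels)"
        )
    body = lbl == (1 + int(np.argmax(sizes)))
    body = _split_off_gelpad(body, data, image)
    body = _largest_component(body)
    if body.sum() < min_vox:
        raise SegmentationError("body candidate shrank below the minimum volume")

    r = max(1, int(round(params.closing_radius / float(image.spacing.min()))))
    ball = _ball_structure(r)
    body = ndimage.binary_closing(np.pad(body, r), structure=ball)[r:-r, r:-r, r:-r]
    # fill internal holes (e.g. bowel gas) slice-wise in axial (LR-AP) planes
    for k in range(body.shape[2]):
        body[:, :, k] = ndimage.binary_fill_holes(body[:, :, k])
    body = _largest_component(body)
    return LabelMask.like(body, image)


def _ball_structure(radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return x * x + y * y + z * z <= radius * radius


def _interface_map(body: np.ndarray, image: VoxelVolume):
    """Per-(LR, IS) column AP height of the body's inferior surface."""
    has = body.any(axis=1)
    first = np.argmax(body, axis=1)  # first True along +AP
    ap = image.axis_coords(1)
    bottom = np.where(has, ap[first], np.nan)
    return bottom, has


def _contact_columns(bottom: np.ndarray, has: np.ndarray, spacing_ap: float) -> np.ndarray:
    """Columns belonging to the flattened skin/pad contact plane.

    The plane is the modal inferior-surface height (the flattened region
    shares one lattice row); a mode is robust to single-column outliers
    from morphological closing, unlike the global minimum. Curving flanks
    beside the pad are excluded.
    """
    vals, counts = np.unique(bottom[has], return_counts=True)
    plane = vals[np.argmax(counts)]
    return has & (np.abs(bottom - plane) <= 0.51 * spacing_ap)


def segment_extracorporeal_air(
    image: VoxelVolume,
    body: LabelMask,
    gelpad_surface=None,
    params: SegmentationParams = None,
) -> LabelMask:
    """Air at the body/gel-pad interface (failed acoustic coupling).

    Low-intensity (below-Otsu) voxels outside the body, lying within
    ``air_band_height`` of the coupling interface. The interface is the
    gel-pad top surface if a height map / scalar is given, else the body's
    inferior surface per column; only contact-plane columns (inferior
    surface within a band of its global minimum) are searched, so air
    beside or above the pelvis is not picked up. Trapped and
    exterior-connected air are both included. An empty mask is valid.
    """
    params = params or SegmentationParams()
    data = np.asarray(image.data, dtype=float)
    th = threshold_otsu(data)
    airish = (data <= th) & ~body.data

    bottom, has = _interface_map(body.data, image)
    if gelpad_surface is not None:
        surf = np.broadcast_to(np.asarray(gelpad_surface, dtype=float), bottom.shape)
        interface = np.where(has, surf, np.nan)
    else:
        interface = bottom
    if not has.any():
        return LabelMask.empty_like(image)

    contact = _contact_columns(bottom, has, image.spacing[1])
    ap = image.axis_coords(1)[None, :, None]
    iface = np.where(contact, interface, np.nan)[:, None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # NaN comparisons
        band = (ap >= iface - params.air_band_height) & (ap <= iface + params.air_band_height)
    return LabelMask.like(airish & band, image)


def coupling_extent(air: LabelMask, body: LabelMask, params: SegmentationParams = None):
    """LR interval (mm) of the coupled part of the body's inferior surface.

    A contact column counts as coupled when no interface air lies within
    the band just below the body surface there. Returns the largest
    contiguous coupled run as ``(lo, hi)`` world mm, or ``None`` (with a
    warning) when nothing is coupled.
    """
    params = params or SegmentationParams()
    if not body.same_grid(air):
        raise SegmentationError("air and body masks live on different grids")
    bottom, has = _interface_map(body.data, body)
    if not has.any():
        warnings.warn("body mask is empty; no coupled surface")
        return None
    contact = _contact_columns(bottom, has, body.spacing[1])

    ap = body.axis_coords(1)[None, :, None]
    iface = np.where(contact, bottom, np.nan)[:, None, :]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        band = (ap >= iface - params.air_band_height) & (ap <= iface + 1e-9)
    air_below = (air.data & band).any(axis=1)  # (LR, IS)
    coupled_cols = contact & ~air_below
    coupled_lr = coupled_cols.any(axis=1)
    if not coupled_lr.any():
        warnings.warn("no coupled body/gel-pad surface found")
        return None
    # largest contiguous coupled run along LR
    padded = np.concatenate([[False], coupled_lr, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    best = int(np.argmax(stops - starts))
    lr = body.axis_coords(0)
    return float(lr[starts[best]]), float(lr[stops[best] - 1])
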