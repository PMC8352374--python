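"""Segmentation-quality metrics and descriptive statistics.

Dice similarity coefficient, symmetric mean contour-to-contour distance
(slice-wise 2D by default, matching axial-slice validation; 3D optional)
and mean/SD/range summaries.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InputError
from .volume import LabelMask


def dice(a: LabelMask, b: LabelMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|); 1.0 if both empty."""
    if not a.same_grid(b):
        raise InputError("dice: masks live on different grids")
    na, nb = a.n_voxels, b.n_voxels
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a.data & b.data).sum()) / (na + nb)


_CROSS_2D = ndimage.generate_binary_structure(2, 1)
_CROSS_3D = ndimage.generate_binary_structure(3, 1)


def _boundary_2d(sl: np.ndarray) -> np.ndarray:
    return sl & ~ndimage.binary_erosion(sl, structure=_CROSS_2D, border_value=0)


def _directed_distances_2d(a, b, spacing):
    """Distances from every boundary pixel of a to the nearest of b, per slice."""
    out = []
    in_plane = np.asarray(spacing[:2], dtype=float)
    for k in range(a.shape[2]):
        sa, sb = a[:, :, k], b[:, :, k]
        if not sa.any() or not sb.any():
            continue
        pa = np.argwhere(_boundary_2d(sa)) * in_plane
        pb = np.argwhere(_boundary_2d(sb)) * in_plane
        d, _ = cKDTree(pb).query(pa)
        out.append(d)
    if not out:
        raise InputError(
            "mean_contour_distance: no axial slice contains both contours"
        )
    return np.concatenate(out)


def mean_contour_distance(a: LabelMask, b: LabelMask, mode: str = "slicewise-2d") -> float:
    """Symmetric mean contour-to-contour distance in mm.

    Boundary voxels are mask voxels with a face-adjacent background
    neighbour (4-connectivity in-plane, 6-connectivity in 3D). The metric
    averages the two directed means (A-boundary to nearest B-boundary and
    vice versa). ``slicewise-2d`` matches per-axial-slice validation and
    uses in-plane spacing only; ``3d`` uses full 3D distances.
    """
    if not a.same_grid(b):
        raise InputError("mean_contour_distance: masks live on different grids")
    if a.n_voxels == 0 or b.n_voxels == 0:
        raise InputError("mean_contour_distance: empty mask")
    if mode == "slicewise-2d":
        d_ab = _directed_distances_2d(a.data, b.data, a.spacing)
        d_ba = _directed_distances_2d(b.data, a.data, a.spacing)
    elif mode == "3d":
        ba = a.data & ~ndimage.binary_erosion(a.data, structure=_CROSS_3D, border_value=0)
        bb = b.data & ~ndimage.binary_erosion(b.data, structure=_CROSS_3D, border_value=0)
        pa = np.argwhere(ba) * a.spacing
        pb = np.argwhere(bb) * a.spacing
        d_ab, _ = cKDTree(pb).query(pa)
        d_ba, _ = cKDTree(pa).query(pb)
    else:
        raise InputError(f"unknown contour-distance mode '{mode}'")
    return 0.5 * (float(np.mean(d_ab)) + float(np.mean(d_ba)))


def directed_contour_distance(a: LabelMask, b: LabelMask) -> float:
    """One-directional (A to B) slice-wise mean contour distance in mm."""
    if not a.same_grid(b):
        raise InputError("contour distance: masks live on different grids")
    if a.n_voxels == 0 or b.n_voxels == 0:
        raise InputError("contour distance: empty mask")
    return float(np.mean(_directed_distances_2d(a.data, b.data, a.spacing)))


def descriptive_stats(values) -> dict:
    """Mean, sample SD (n-1), min and max of a list of measurements."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise InputError("descriptive_stats: empty value list")
    if not np.all(np.isfinite(v)):
        raise InputError("descriptive_stats: non-finite values")
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
        "min": float(v.min()),
        "max": float(v.max()),
    }
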