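"""Independent naive reference implementations used as test oracles.

These deliberately share no code with the package's coverage engine: the
pose sweep loops over rays one by one, builds its own rotation matrices,
and marks covered voxels with an explicit ellipsoid inequality. Slow but
transparently correct at tiny problem sizes.
"""

import numpy as np


def _rot_z(tilt_deg):
    # positive tilt leans the beam axis toward +LR (same convention as the
    # package contract, re-derived here rather than imported)
    t = np.deg2rad(tilt_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def naive_pose_clear(pose, transducer, couch, obstruction, sample_spacing=0.2):
    """Per-ray walk: any sampled point in an obstruction voxel blocks the pose."""
    rot = _rot_z(pose.tilt_lr)
    apex = couch.home + np.asarray(pose.translation, dtype=float)
    focus = apex + rot @ np.array([0.0, transducer.focal_length, 0.0])
    data = obstruction.data
    shape = np.asarray(data.shape)
    for elem_local in transducer.element_positions:
        elem = rot @ elem_local + apex
        vec = focus - elem
        length = np.linalg.norm(vec)
        n = int(np.floor(length / sample_spacing + 1e-6))
        s = sample_spacing * np.arange(n)
        pts = elem + np.outer(s / length, vec)
        idx = np.rint((pts - obstruction.origin) / obstruction.spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        ii = idx[ok]
        if data[ii[:, 0], ii[:, 1], ii[:, 2]].any():
            return False
    return True


def naive_ray_blocked_walk(element_world, focus_world, obstruction, step=0.01):
    """Brute-force 0.01 mm walk along one ray; True if any point is obstructed."""
    vec = focus_world - element_world
    length = np.linalg.norm(vec)
    n = int(np.floor(length / step + 1e-6))
    s = step * np.arange(n)
    pts = element_world + np.outer(s / length, vec)
    idx = np.rint((pts - obstruction.origin) / obstruction.spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < np.asarray(obstruction.shape)), axis=1)
    ii = idx[ok]
    return bool(obstruction.data[ii[:, 0], ii[:, 1], ii[:, 2]].any())


def naive_covered_points(pose, transducer, couch, points, cell_diameter=8.0, cell_length=21.84):
    """Boolean flags for target points inside the cell at this pose's focus."""
    rot = _rot_z(pose.tilt_lr)
    apex = couch.home + np.asarray(pose.translation, dtype=float)
    axis = rot @ np.array([0.0, 1.0, 0.0])
    focus = apex + transducer.focal_length * axis
    a = cell_diameter / 2.0
    c = cell_length / 2.0
    out = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        rel = p - focus
        w = float(rel @ axis)
        perp2 = float(rel @ rel) - w * w
        out[i] = perp2 / (a * a) + (w * w) / (c * c) <= 1.0 + 1e-12
    return out


def naive_coverage(anatomy, transducer, couch, poses, sample_spacing=0.2,
                   cell_diameter=8.0, cell_length=21.84):
    """Full naive sweep; returns (covered voxel mask, n_poses_clear)."""
    obstruction = anatomy.obstruction_mask()
    tgt_idx = np.argwhere(anatomy.target.data)
    pts = anatomy.target.voxel_to_world(tgt_idx)
    covered = np.zeros(len(pts), dtype=bool)
    n_clear = 0
    for pose in poses:
        if naive_pose_clear(pose, transducer, couch, obstruction, sample_spacing):
            n_clear += 1
            covered |= naive_covered_points(
                pose, transducer, couch, pts, cell_diameter, cell_length
            )
    mask = np.zeros(anatomy.target.shape, dtype=bool)
    sel = tgt_idx[covered]
    mask[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return mask, n_clear
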