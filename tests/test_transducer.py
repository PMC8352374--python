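"""Transducer element layout, pose kinematics, beam tracing and cell shape."""

import numpy as np
import pytest

import hifuplan as hp
from hifuplan.transducer import tilt_rotation


@pytest.fixture(scope="module")
def transducer():
    return hp.build_transducer()


@pytest.fixture(scope="module")
def couch():
    return hp.CouchGeometry()


class TestElementLayout:
    def test_all_elements_on_focal_sphere(self, transducer):
        d = np.linalg.norm(transducer.element_positions - transducer.focus_local, axis=1)
        assert np.all(np.abs(d - 140.0) < 1e-9)

    def test_projected_radius_within_aperture(self, transducer):
        proj = np.hypot(
            transducer.element_positions[:, 0], transducer.element_positions[:, 2]
        )
        assert proj.max() <= 65.0 + 1e-9

    def test_single_element_sits_at_apex(self):
        t = hp.build_transducer(n_elements=1)
        assert np.allclose(t.element_positions[0], [0.0, 0.0, 0.0], atol=1e-12)

    def test_layout_is_deterministic(self):
        a = hp.build_transducer().element_positions
        b = hp.build_transducer().element_positions
        assert np.array_equal(a, b)

    def test_rings_layout_also_satisfies_invariants(self):
        t = hp.build_transducer(layout="rings")
        d = np.linalg.norm(t.element_positions - t.focus_local, axis=1)
        assert np.all(np.abs(d - 140.0) < 1e-9)
        assert np.hypot(t.element_positions[:, 0], t.element_positions[:, 2]).max() <= 65 + 1e-9

    def test_nonphysical_aperture_rejected(self):
        with pytest.raises(hp.ConfigError):
            hp.build_transducer(aperture_diameter=300.0, focal_length=140.0)


class TestPoseKinematics:
    def test_zero_pose_focuses_at_isocentre(self, transducer, couch):
        focus, axis = hp.pose_to_focus(hp.TransducerPose(), transducer, couch)
        assert np.allclose(focus, couch.isocentre, atol=1e-12)
        assert np.allclose(axis, [0, 1, 0], atol=1e-12)

    def test_translation_shifts_focus_rigidly(self, transducer, couch):
        focus, _ = hp.pose_to_focus(
            hp.TransducerPose(translation=(10.0, 0.0, 0.0)), transducer, couch
        )
        assert np.allclose(focus, [10.0, 0.0, 0.0], atol=1e-12)

    def test_tilt_displaces_focus_by_closed_form(self, transducer, couch):
        focus, _ = hp.pose_to_focus(hp.TransducerPose(tilt_lr=10.0), transducer, couch)
        t = np.deg2rad(10.0)
        assert abs(focus[0] - 140.0 * np.sin(t)) < 1e-9  # ~24.31 mm lateral
        assert abs(-focus[1] - 140.0 * (1.0 - np.cos(t))) < 1e-9  # ~2.13 mm lower

    def test_pose_outside_limits_rejected(self):
        with pytest.raises(hp.PoseError):
            hp.TransducerPose(translation=(80.0, 0.0, 0.0)).check(hp.PoseLimits())
        with pytest.raises(hp.PoseError):
            hp.TransducerPose(translation=(0.0, -34.0, 0.0)).check(hp.PoseLimits())
        with pytest.raises(hp.PoseError):
            hp.TransducerPose(tilt_lr=12.5).check(hp.PoseLimits())


class TestEnumeratePoses:
    def test_small_grid_arithmetic(self):
        limits = hp.PoseLimits(tilt_max=2.5, tilt_step=2.5)
        poses = hp.enumerate_poses(
            limits, hp.SearchBounds(lr=(-8, 8), is_=(0, 0), ap=(0, 0)), step=4.0
        )
        assert len(poses) == 5 * 1 * 1 * 3

    def test_default_tilt_grid_has_nine_values(self):
        poses = hp.enumerate_poses(
            hp.PoseLimits(), hp.SearchBounds(lr=(0, 0), is_=(0, 0), ap=(0, 0))
        )
        tilts = sorted({p.tilt_lr for p in poses})
        assert len(tilts) == 9
        assert tilts[0] == -10.0 and tilts[-1] == 10.0 and tilts[4] == 0.0

    def test_full_ap_range_swept_by_default(self):
        poses = hp.enumerate_poses(
            hp.PoseLimits(tilt_max=0.0, tilt_step=2.5),
            hp.SearchBounds(lr=(0, 0), is_=(0, 0)),
        )
        aps = sorted({p.translation[1] for p in poses})
        assert aps[0] == -33.0 and aps[-1] == pytest.approx(31.0)
        assert len(aps) == 17

    def test_bounds_outside_limits_give_empty_list_with_warning(self):
        with pytest.warns(UserWarning):
            poses = hp.enumerate_poses(
                hp.PoseLimits(), hp.SearchBounds(lr=(100, 120), is_=(0, 0), ap=(0, 0))
            )
        assert poses == []

    def test_no_duplicates_and_product_size(self):
        limits = hp.PoseLimits(tilt_max=5, tilt_step=2.5)
        poses = hp.enumerate_poses(
            limits, hp.SearchBounds(lr=(-4, 4), is_=(-4, 4), ap=(-4, 4)), step=4.0
        )
        assert len(poses) == 3 * 3 * 3 * 5
        assert len({(p.translation, p.tilt_lr) for p in poses}) == len(poses)

    def test_ordering_lr_outermost_tilt_innermost(self):
        limits = hp.PoseLimits(tilt_max=2.5, tilt_step=2.5)
        poses = hp.enumerate_poses(
            limits, hp.SearchBounds(lr=(-4, 4), is_=(0, 0), ap=(0, 0)), step=4.0
        )
        lrs = [p.translation[0] for p in poses]
        assert lrs == sorted(lrs)
        assert [p.tilt_lr for p in poses[:3]] == [-2.5, 0.0, 2.5]


class TestTraceBeam:
    def test_default_sampling_gives_700_points_per_ray(self, transducer, couch):
        pts = hp.trace_beam(hp.TransducerPose(), transducer, couch)
        assert pts.shape == (256, 700, 3)
        # first point of each ray is the element itself; focus excluded
        first = pts[:, 0, :]
        d_first = np.linalg.norm(first - couch.isocentre, axis=1)
        assert np.allclose(d_first, 140.0, atol=1e-9)
        d_last = np.linalg.norm(pts[:, -1, :] - np.asarray(couch.isocentre), axis=1)
        assert np.all(d_last > 0.19)

    def test_coarse_sampling_point_count(self, transducer, couch):
        pts = hp.trace_beam(hp.TransducerPose(), transducer, couch, sample_spacing=1.0)
        assert pts.shape[1] == 140

    def test_tilt_preserves_ray_lengths(self, transducer, couch):
        pose = hp.TransducerPose(tilt_lr=10.0)
        pts = hp.trace_beam(pose, transducer, couch)
        focus, _ = hp.pose_to_focus(pose, transducer, couch)
        d = np.linalg.norm(pts[:, 0, :] - focus, axis=1)
        assert np.allclose(d, 140.0, atol=1e-9)

    def test_translation_is_a_rigid_shift(self, transducer, couch):
        base = hp.trace_beam(hp.TransducerPose(), transducer, couch, sample_spacing=2.0)
        moved = hp.trace_beam(
            hp.TransducerPose(translation=(10.0, -5.0, 7.0)), transducer, couch,
            sample_spacing=2.0,
        )
        assert np.abs(moved - base - np.array([10.0, -5.0, 7.0])).max() < 1e-9


class TestTreatmentCell:
    def test_point_membership_examples(self):
        cell = hp.TreatmentCell()
        assert hp.point_in_cell([0.0, 0.0, 0.0], cell)
        assert not hp.point_in_cell([4.1, 0.0, 0.0], cell)
        assert hp.point_in_cell([0.0, 10.92, 0.0], cell)  # on-boundary counts
        assert not hp.point_in_cell([0.0, 11.0, 0.0], cell)

    def test_membership_follows_tilted_axis(self):
        axis = tilt_rotation(30.0) @ np.array([0.0, 1.0, 0.0])
        cell = hp.TreatmentCell(center=(5.0, -2.0, 1.0), axis=tuple(axis))
        along = np.array(cell.center) + 10.0 * axis
        across = np.array(cell.center) + 5.0 * np.array([axis[1], -axis[0], 0.0])
        assert hp.point_in_cell(along, cell)
        assert not hp.point_in_cell(across, cell)

    def test_monte_carlo_volume_matches_closed_form(self):
        # oracle: analytic ellipsoid volume 4/3 pi a^2 c with a=4, c=10.92
        cell = hp.TreatmentCell()
        rng = np.random.default_rng(42)
        n = 200_000
        box = np.array([8.0, 22.0, 8.0])
        pts = rng.uniform(-0.5, 0.5, (n, 3)) * box
        frac = np.mean(hp.point_in_cell(pts, cell))
        estimate = frac * np.prod(box)
        assert estimate == pytest.approx(cell.volume_mm3, rel=0.02)
        assert cell.volume_mm3 == pytest.approx(731.9, abs=0.1)
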