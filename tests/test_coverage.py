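"""Beam-obstruction testing, cell accumulation and the coverage sweep."""

import numpy as np
import pytest

import hifuplan as hp
from hifuplan.coverage import TargetGrid, _BeamTester
from hifuplan.phantom import PhantomSpec, generate_phantom
from hifuplan.transducer import tilt_rotation

from _naive import (
    naive_coverage,
    naive_covered_points,
    naive_pose_clear,
    naive_ray_blocked_walk,
)

COARSE_LIMITS = hp.PoseLimits(tilt_max=5.0, tilt_step=5.0)
COARSE_BOUNDS = hp.SearchBounds(lr=(-8.0, 8.0), is_=(-8.0, 8.0), ap=(-4.0, 4.0))


@pytest.fixture(scope="module")
def transducer():
    return hp.build_transducer()


class TestBeamClear:
    def test_no_obstructions_always_clear(self, mini_phantom, transducer):
        for tilt in (-10.0, 0.0, 10.0):
            assert hp.is_beam_clear(
                hp.TransducerPose(tilt_lr=tilt), transducer, mini_phantom.anatomy
            )

    def test_full_slab_blocks_every_pose(self, transducer):
        spec = PhantomSpec.mini(
            seed=0, bone_boxes=(((-48.0, 48.0), (-32.0, -28.0), (-48.0, 48.0)),)
        )
        anatomy = generate_phantom(spec).anatomy
        assert not hp.is_beam_clear(hp.TransducerPose(), transducer, anatomy)

    def test_edge_clipping_cube_blocks_by_any_ray_rule(self, transducer):
        # a 5 mm bone cube near the beam edge: only peripheral rays cross it
        spec = PhantomSpec.mini(
            seed=0, bone_boxes=(((-19.0, -14.0), (-36.0, -31.0), (-2.0, 3.0)),)
        )
        anatomy = generate_phantom(spec).anatomy
        pose = hp.TransducerPose()
        assert not hp.is_beam_clear(pose, transducer, anatomy)

        # cross-check against a brute-force 0.01 mm per-ray walk
        obstruction = anatomy.obstruction_mask()
        couch = anatomy.couch
        rot = tilt_rotation(pose.tilt_lr)
        apex = couch.home + np.asarray(pose.translation)
        focus = apex + rot @ np.array([0.0, transducer.focal_length, 0.0])
        blocked = [
            naive_ray_blocked_walk(rot @ e + apex, focus, obstruction)
            for e in transducer.element_positions
        ]
        n_blocked = sum(blocked)
        assert 0 < n_blocked < transducer.n_elements  # genuinely edge-only
        tester = _BeamTester(transducer, couch, obstruction)
        assert tester.blocked_fraction(pose) == pytest.approx(
            n_blocked / transducer.n_elements, abs=2 / transducer.n_elements
        )

    def test_matches_naive_per_pose_decision(self, blocked_mini_phantom, transducer):
        anatomy = blocked_mini_phantom.anatomy
        couch = anatomy.couch
        obstruction = anatomy.obstruction_mask()
        for pose in hp.enumerate_poses(COARSE_LIMITS, COARSE_BOUNDS, step=8.0):
            assert hp.is_beam_clear(pose, transducer, anatomy) == naive_pose_clear(
                pose, transducer, couch, obstruction
            )

    def test_tolerated_blocked_fraction_relaxes_rule(self, transducer):
        spec = PhantomSpec.mini(
            seed=0, bone_boxes=(((-19.0, -14.0), (-36.0, -31.0), (-2.0, 3.0)),)
        )
        anatomy = generate_phantom(spec).anatomy
        pose = hp.TransducerPose()
        assert not hp.is_beam_clear(pose, transducer, anatomy)
        assert hp.is_beam_clear(
            pose, transducer, anatomy, tolerated_blocked_fraction=0.5
        )


class TestAccumulateCell:
    def test_focus_point_becomes_covered(self, mini_phantom, transducer):
        anatomy = mini_phantom.anatomy
        grid = TargetGrid.from_mask(anatomy.target)
        hp.accumulate_cell(hp.TransducerPose(), grid, transducer, anatomy.couch)
        at_focus = np.linalg.norm(grid.points - np.zeros(3), axis=1) < 1.0
        assert grid.covered[at_focus].all()

    def test_idempotent_and_monotone(self, mini_phantom, transducer):
        anatomy = mini_phantom.anatomy
        grid = TargetGrid.from_mask(anatomy.target)
        hp.accumulate_cell(hp.TransducerPose(), grid, transducer, anatomy.couch)
        once = grid.covered.copy()
        hp.accumulate_cell(hp.TransducerPose(), grid, transducer, anatomy.couch)
        assert np.array_equal(grid.covered, once)
        hp.accumulate_cell(
            hp.TransducerPose(translation=(4.0, 0.0, 0.0)), grid, transducer, anatomy.couch
        )
        assert grid.covered.sum() >= once.sum()

    @pytest.mark.parametrize("pose", [
        hp.TransducerPose(),
        hp.TransducerPose(translation=(4.0, -4.0, 8.0), tilt_lr=7.5),
    ])
    def test_matches_direct_enumeration_oracle(self, mini_phantom, transducer, pose):
        anatomy = mini_phantom.anatomy
        grid = TargetGrid.from_mask(anatomy.target)
        hp.accumulate_cell(pose, grid, transducer, anatomy.couch)
        expected = naive_covered_points(pose, transducer, anatomy.couch, grid.points)
        assert np.array_equal(grid.covered, expected)


class TestComputeCoverage:
    def test_unobstructed_in_envelope_target_fully_covered(self, mini_phantom, transducer):
        result = hp.compute_coverage(mini_phantom.anatomy, transducer)
        assert result.tvc_pat == 100.0
        assert result.n_poses_clear == result.n_poses_tested

    def test_fully_shielded_target_has_zero_coverage(self, transducer):
        spec = PhantomSpec.mini(
            seed=0, bone_boxes=(((-48.0, 48.0), (-32.0, -28.0), (-48.0, 48.0)),)
        )
        anatomy = generate_phantom(spec).anatomy
        result = hp.compute_coverage(
            anatomy, transducer, limits=COARSE_LIMITS, search_bounds=COARSE_BOUNDS
        )
        assert result.tvc_pat == 0.0 and result.n_poses_clear == 0

    def test_matches_naive_sweep_exactly(self, blocked_mini_phantom, transducer):
        anatomy = blocked_mini_phantom.anatomy
        result = hp.compute_coverage(
            anatomy, transducer, limits=COARSE_LIMITS, search_bounds=COARSE_BOUNDS
        )
        poses = hp.enumerate_poses(COARSE_LIMITS, COARSE_BOUNDS)
        expected_mask, expected_clear = naive_coverage(
            anatomy, transducer, anatomy.couch, poses
        )
        assert result.n_poses_clear == expected_clear
        assert 0 < result.n_poses_clear < result.n_poses_tested
        assert np.array_equal(result.covered_mask.data, expected_mask)

    def test_removing_obstructions_never_decreases_coverage(self, transducer):
        slab = (((-40.0, -4.0), (-34.0, -26.0), (-40.0, 40.0)),)
        half = (((-40.0, -22.0), (-34.0, -26.0), (-40.0, 40.0)),)
        tvc = {}
        for name, boxes in (("slab", slab), ("half", half), ("none", ())):
            anatomy = generate_phantom(PhantomSpec.mini(seed=2, bone_boxes=boxes)).anatomy
            tvc[name] = hp.compute_coverage(
                anatomy, transducer, limits=COARSE_LIMITS, search_bounds=COARSE_BOUNDS
            ).tvc_pat
        assert tvc["slab"] <= tvc["half"] <= tvc["none"]

    def test_discretisation_stable_under_grid_refinement(self, transducer):
        # same geometry at 2 mm and 1 mm voxels: tvc_pat within 2 points
        results = {}
        for spacing, shape in ((2.0, (48, 48, 48)), (1.0, (96, 96, 96))):
            spec = PhantomSpec.mini(
                seed=2,
                shape=shape,
                spacing=(spacing,) * 3,
                bone_boxes=(((-40.0, -4.0), (-34.0, -26.0), (-40.0, 40.0)),),
            )
            anatomy = generate_phantom(spec).anatomy
            results[spacing] = hp.compute_coverage(
                anatomy, transducer, limits=COARSE_LIMITS, search_bounds=COARSE_BOUNDS
            ).tvc_pat
        assert abs(results[2.0] - results[1.0]) < 2.0

    def test_empty_target_rejected(self, mini_phantom, transducer):
        anatomy = mini_phantom.anatomy
        bad = hp.LabelledAnatomy(
            image=anatomy.image,
            body=anatomy.body,
            bone=anatomy.bone,
            target=hp.LabelMask.empty_like(anatomy.image),
            couch=anatomy.couch,
        )
        with pytest.raises(hp.InputError):
            hp.compute_coverage(bad, transducer)


class TestCoverageMetrics:
    @pytest.mark.parametrize("cv, tv, expected", [
        (250.0, 1000.0, 25.0), (1000.0, 1000.0, 100.0), (0.0, 1000.0, 0.0),
    ])
    def test_tvc_pat_values(self, cv, tv, expected):
        assert hp.tvc_pat(cv, tv) == expected

    def test_tvc_pat_rejects_empty_target(self):
        with pytest.raises(hp.InputError):
            hp.tvc_pat(0.0, 0.0)

    def test_tvc_vol_identical_disjoint_partial(self):
        a = np.zeros((5, 5, 5), bool)
        a[:2] = True
        assert hp.tvc_vol(a, a) == 100.0
        b = np.zeros_like(a)
        b[3:] = True
        assert hp.tvc_vol(a, b) == 0.0
        c = np.zeros_like(a)
        c[1:3] = True  # |c|=50, overlap with a = 25
        assert hp.tvc_vol(a, c) == 50.0

    def test_tvc_vol_ignores_voxels_outside_reference_set(self):
        rng = np.random.default_rng(0)
        b = rng.random((6, 6, 6)) > 0.6
        a = rng.random((6, 6, 6)) > 0.4
        a2 = a | ~b  # adding voxels outside b must not change the score
        assert hp.tvc_vol(a, b) == hp.tvc_vol(a2, b)

    def test_tvc_vol_rejects_empty_reference(self):
        with pytest.raises(hp.InputError):
            hp.tvc_vol(np.ones((2, 2, 2), bool), np.zeros((2, 2, 2), bool))


class TestSearchBounds:
    def test_single_voxel_target_gives_zero_width_bounds(self):
        mask = hp.LabelMask(np.zeros((11, 11, 11), bool), (1, 1, 1), (-5, -5, -5))
        mask.data[5, 5, 5] = True
        bounds = hp.target_search_bounds(mask, hp.CouchGeometry())
        assert bounds.lr == (0.0, 0.0) and bounds.is_ == (0.0, 0.0) and bounds.ap is None

    def test_bounding_box_and_margin(self):
        mask = hp.LabelMask(np.zeros((80, 11, 60), bool), (1, 1, 1), (-40, -5, -30))
        mask.data[10:51, 5, 20:36] = True  # LR extent [-30, 10], IS [-10, 5]
        bounds = hp.target_search_bounds(mask, hp.CouchGeometry())
        assert bounds.lr == (-30.0, 10.0) and bounds.is_ == (-10.0, 5.0)
        widened = hp.target_search_bounds(mask, hp.CouchGeometry(), margin=8.0)
        assert widened.lr == (-38.0, 18.0) and widened.is_ == (-18.0, 13.0)

    def test_empty_target_rejected(self):
        mask = hp.LabelMask(np.zeros((4, 4, 4), bool), (1, 1, 1), (0, 0, 0))
        with pytest.raises(hp.InputError):
            hp.target_search_bounds(mask, hp.CouchGeometry())
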