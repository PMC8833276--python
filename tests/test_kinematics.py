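import numpy as np
import pytest

from gantryclear.kinematics import (
    BeamConfig,
    GantryLimitError,
    IndexingError,
    PlanContext,
    ReachabilityError,
    SixDofCorrection,
    couch_top_transform,
    couch_transform,
    gantry_transform,
    is_gantry_angle_allowed,
    patient_to_room_transform,
    solve_pps_pose,
)


def make_ctx(jct_cm, beams, couch="civco"):
    return PlanContext(jct_cm, tuple(beams), couch_top_kind=couch, couch_surface_y_ct=100.0)


class TestGantryArc:
    def test_arc_boundaries(self):
        assert is_gantry_angle_allowed(185.0)
        assert is_gantry_angle_allowed(355.0)
        assert not is_gantry_angle_allowed(270.0)
        assert not is_gantry_angle_allowed(185.1)
        assert not is_gantry_angle_allowed(354.9)

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ValueError):
            is_gantry_angle_allowed(360.0)
        with pytest.raises(ValueError):
            is_gantry_angle_allowed(-5.0)

    def test_gantry_transform_identity_and_quarter_turn(self):
        assert gantry_transform(0.0).is_identity()
        # at 90 degrees the source direction becomes horizontal (+x)
        assert np.allclose(gantry_transform(90.0).apply([0, 0, 1]), [1, 0, 0], atol=1e-12)

    def test_disallowed_angle_raises_gantry_limit_error(self):
        with pytest.raises(GantryLimitError, match="355"):
            gantry_transform(200.0)

    def test_opposite_rotations_cancel_where_both_are_allowed(self):
        # only angles up to 5 deg have their negative on the allowed arc
        for a in (1.0, 2.5, 5.0):
            combined = gantry_transform(a) @ gantry_transform(360.0 - a)
            assert combined.is_identity(tol=1e-12)


class TestCouchTransform:
    def test_identity_and_half_turn(self):
        assert couch_transform(0.0).is_identity()
        half = couch_transform(180.0)
        assert (half @ half).is_identity(tol=1e-12)

    def test_quarter_turn_maps_couch_axis(self):
        # couch long axis +y rotates to -x at T=90 (counterclockwise from above)
        assert np.allclose(couch_transform(90.0).apply([0, 1, 0]), [-1, 0, 0], atol=1e-12)

    def test_sixdof_limits_enforced(self):
        with pytest.raises(ValueError, match="yaw"):
            SixDofCorrection(yaw=5.0)
        with pytest.raises(ValueError, match="dz"):
            SixDofCorrection(dz=60.0)

    def test_sixdof_translation_applied(self):
        s = SixDofCorrection(dx=10.0, dy=-5.0, dz=2.0)
        out = couch_transform(0.0, s).apply([0, 0, 0])
        assert np.allclose(out, [10.0, -5.0, 2.0])


class TestPatientIndexing:
    def test_isocenter_lands_on_room_origin_and_junction_distance(self):
        beam = BeamConfig("b", 0.0, 0.0)
        ctx = make_ctx(94.7, [beam], couch="orfit")
        xf = patient_to_room_transform(ctx, beam)
        assert np.allclose(xf.apply([0, 0, 0]), [0, 0, 0], atol=1e-12)
        junction = xf.apply([0.0, 100.0, -947.0])
        assert np.linalg.norm(junction - xf.apply([0.0, 100.0, 0.0])) == pytest.approx(947.0)

    def test_isocenter_shift_moves_patient_oppositely(self):
        b1 = BeamConfig("b1", 0.0, 0.0, (0.0, 0.0, 0.0))
        b2 = BeamConfig("b2", 0.0, 0.0, (0.0, 0.0, 50.0))
        ctx = make_ctx(94.7, [b1, b2], couch="orfit")
        probe = np.array([[10.0, 20.0, 30.0], [0.0, 0.0, 0.0]])
        p1 = patient_to_room_transform(ctx, b1).apply(probe)
        p2 = patient_to_room_transform(ctx, b2).apply(probe)
        # +50 mm superior isocenter shift moves all points 50 mm inferior (-y)
        assert np.allclose(p1 - p2, [[0.0, 50.0, 0.0]] * 2, atol=1e-9)

    def test_jct_difference_displaces_couch_by_exactly_that_amount(self, default_dims):
        beam = BeamConfig("b", 0.0, 0.0)
        out = []
        for jct in (60.0, 75.0):
            ctx = make_ctx(jct, [beam])
            out.append(couch_top_transform(ctx, beam, default_dims).apply([0, 0, 0]))
        delta = out[1] - out[0]
        assert np.allclose(delta, [0.0, -150.0, 0.0], atol=1e-9)

    def test_beam_must_belong_to_context(self):
        b1 = BeamConfig("b1", 0.0, 0.0)
        stranger = BeamConfig("x", 0.0, 0.0, (1.0, 0.0, 0.0))
        ctx = make_ctx(60.0, [b1])
        with pytest.raises(ValueError, match="not part of the plan"):
            patient_to_room_transform(ctx, stranger)

    def test_junction_off_couch_raises_indexing_error(self, default_dims):
        # isocenter 1 m inferior of the mark with a short JCT: iso beyond span
        beam = BeamConfig("b", 0.0, 0.0, (0.0, 0.0, -1000.0))
        ctx = make_ctx(50.0, [beam])
        with pytest.raises(IndexingError, match="couch span"):
            couch_top_transform(ctx, beam, default_dims)

    def test_unsupported_orientation_rejected(self):
        with pytest.raises(ValueError, match="head-first-supine"):
            PlanContext(60.0, (BeamConfig("b", 0, 0),), patient_orientation="feet-first-prone")

    def test_context_invariants(self):
        with pytest.raises(ValueError, match="jct"):
            PlanContext(0.0, (BeamConfig("b", 0, 0),))
        with pytest.raises(ValueError, match="at least one beam"):
            PlanContext(60.0, ())


class TestPpsSolver:
    def test_end_effector_closure_on_random_reachable_poses(self, default_dims):
        """Forward kinematics of the solved pose lands on the mount point."""
        rng = np.random.default_rng(2024)
        _, l1, l2, knuckle = default_dims.arm_link_lengths
        checked = 0
        signs = set()
        base = np.asarray(default_dims.base_position)
        while checked < 1000:
            beam = BeamConfig("b", 0.0, float(rng.uniform(0, 360)) % 360.0,
                              (0.0, float(rng.uniform(-100, 100)), float(rng.uniform(-150, 150))))
            ctx = make_ctx(float(rng.uniform(45, 120)), [beam])
            try:
                couch_xf = couch_top_transform(ctx, beam, default_dims)
                pose = solve_pps_pose(couch_xf, default_dims)
            except (ReachabilityError, IndexingError):
                continue
            wrist_fwd = pose["pps_upper_arm_knuckle"].apply([l2 + knuckle, 0.0, 0.0])
            assert np.linalg.norm(wrist_fwd - pose["wrist"]) < 0.1
            # left-handedness: the base-elbow-wrist signed area keeps one sign
            elbow = pose["pps_upper_arm_knuckle"].translation
            wrist = pose["wrist"]
            v1 = elbow[:2] - base[:2]
            v2 = wrist[:2] - elbow[:2]
            cross = v1[0] * v2[1] - v1[1] * v2[0]
            if abs(cross) > 1e-6:
                signs.add(np.sign(cross))
            checked += 1
        assert len(signs) == 1

    def test_unreachable_mount_reports_shortfall(self, default_dims):
        # a huge isocenter offset drags the couch far beyond the arm's reach
        from gantryclear.transforms import RigidTransform

        far = RigidTransform.from_translation([6000.0, 0.0, 0.0])
        with pytest.raises(ReachabilityError) as err:
            solve_pps_pose(far, default_dims)
        assert err.value.shortfall_mm > 0

    def test_maximum_reach_boundary_has_a_unique_solution(self, default_dims):
        from gantryclear.transforms import RigidTransform

        _, l1, l2, knuckle = default_dims.arm_link_lengths
        base = np.asarray(default_dims.base_position)
        reach = l1 + l2 + knuckle
        ct = default_dims.couch_tops["civco"]
        mount_local = np.array([0.0, -150.0, -ct.thickness - 140.0])
        target = base + np.array([reach, 0.0, 500.0])
        pose = solve_pps_pose(
            RigidTransform.from_translation(target - mount_local), default_dims
        )
        wrist = pose["wrist"]
        elbow = pose["pps_upper_arm_knuckle"].translation
        # collinear links: elbow lies on the base-wrist segment
        v1 = (elbow - [base[0], base[1], elbow[2]])[:2]
        v2 = (wrist - elbow)[:2]
        assert abs(v1[0] * v2[1] - v1[1] * v2[0]) < 1e-3
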