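import numpy as np
import pytest
import trimesh

from gantryclear.collision import (
    CollisionType,
    NotMonitoredError,
    brute_force_distance,
    classify_pair,
    contains_point,
    intersects,
    min_distance,
    point_mesh_distance,
)
from gantryclear.transforms import RigidTransform, rot_y, rot_z

from conftest import random_mesh_pair


def boxes_apart(gap):
    a = trimesh.creation.box((10, 10, 10))
    b = trimesh.creation.box((10, 10, 10))
    b.apply_translation([10 + gap, 0, 0])
    return a, b


class TestMinDistance:
    def test_parallel_faces_exact(self):
        a, b = boxes_apart(5.0)
        d, pa, pb = min_distance(a, b)
        assert d == pytest.approx(5.0, abs=1e-12)
        assert np.linalg.norm(pa - pb) == pytest.approx(d, abs=1e-9)

    def test_tessellated_spheres_match_analytic_clearance(self):
        # centers 300 mm apart, radii 100: analytic surface clearance 100 mm;
        # inscribed tessellation underestimates radii by at most the sagitta
        s1 = trimesh.creation.icosphere(subdivisions=3, radius=100.0)
        s2 = s1.copy()
        s2.apply_translation([300.0, 0, 0])
        edge = s1.edges_unique_length.max()
        sagitta = 100.0 - np.sqrt(100.0**2 - (edge / 2) ** 2)
        d, _, _ = min_distance(s1, s2)
        assert 100.0 <= d <= 100.0 + 2 * sagitta + 1e-9

    def test_mesh_against_itself_is_zero(self):
        a = trimesh.creation.box((10, 10, 10))
        assert min_distance(a, a)[0] == 0.0

    def test_contained_solid_counts_as_overlap(self):
        outer = trimesh.creation.box((20, 20, 20))
        inner = trimesh.creation.box((2, 2, 2))
        assert min_distance(outer, inner)[0] == 0.0
        assert intersects(outer, inner)

    def test_empty_mesh_rejected(self):
        a = trimesh.creation.box((1, 1, 1))
        empty = trimesh.Trimesh()
        with pytest.raises(ValueError, match="empty"):
            min_distance(a, empty)
        with pytest.raises(ValueError, match="empty"):
            intersects(empty, a)

    def test_cutoff_result_is_a_valid_upper_bound(self):
        a, b = boxes_apart(80.0)
        d_exact, _, _ = min_distance(a, b)
        d_cut, _, _ = min_distance(a, b, cutoff=10.0)
        assert d_cut >= d_exact
        assert d_cut > 10.0  # correctly reported as exceeding the cutoff

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a, b = random_mesh_pair(rng)
            assert min_distance(a, b)[0] == pytest.approx(min_distance(b, a)[0], abs=1e-9)

    def test_rigid_invariance(self):
        """Moving both meshes by one rigid transform leaves clearance fixed."""
        rng = np.random.default_rng(11)
        a, b = boxes_apart(17.0)
        d0 = min_distance(a, b)[0]
        for _ in range(50):
            xf = (
                rot_z(rng.uniform(0, 360))
                @ rot_y(rng.uniform(0, 360))
                @ RigidTransform.from_translation(rng.uniform(-500, 500, 3))
            )
            a2, b2 = a.copy(), b.copy()
            a2.vertices = xf.apply(a2.vertices.view(np.ndarray))
            b2.vertices = xf.apply(b2.vertices.view(np.ndarray))
            assert min_distance(a2, b2)[0] == pytest.approx(d0, abs=1e-6)

    def test_translation_obeys_triangle_inequality(self):
        rng = np.random.default_rng(3)
        a, b = random_mesh_pair(rng)
        d0 = min_distance(a, b)[0]
        for _ in range(20):
            v = rng.uniform(-30, 30, 3)
            b2 = b.copy()
            b2.apply_translation(v)
            assert abs(min_distance(a, b2)[0] - d0) <= np.linalg.norm(v) + 1e-9


class TestBruteForceOracle:
    def test_matches_bvh_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            a, b = random_mesh_pair(rng)
            assert min_distance(a, b)[0] == pytest.approx(
                brute_force_distance(a, b), abs=1e-6
            )

    def test_known_cases(self):
        a, b = boxes_apart(5.0)
        assert brute_force_distance(a, b) == pytest.approx(5.0, abs=1e-12)
        a, b = boxes_apart(0.0)  # shared face
        assert brute_force_distance(a, b) == 0.0

    def test_size_guard(self):
        big = trimesh.creation.icosphere(subdivisions=4)
        with pytest.raises(ValueError, match="2000"):
            brute_force_distance(big, big)


class TestIntersects:
    def test_overlap_and_separation(self):
        a, b = boxes_apart(-2.0)
        assert intersects(a, b)
        a, b = boxes_apart(5.0)
        assert not intersects(a, b)

    def test_agreement_with_distance_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b = random_mesh_pair(rng)
            assert intersects(a, b) == (brute_force_distance(a, b) <= 1e-9)


class TestClassification:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("gantry_head", "couch_top", CollisionType.type1_gantry_vs_couch),
            ("range_shifter", "body", CollisionType.type2_gantry_vs_patient),
            ("touch_guard", "pps_upper_arm_knuckle", CollisionType.type3_gantry_vs_pps_arm),
            ("gantry_head", "immobilization", CollisionType.type4_gantry_vs_immobilization),
            ("range_shifter", "bolus_device", CollisionType.type4_gantry_vs_immobilization),
        ],
    )
    def test_monitored_pairs(self, a, b, expected):
        assert classify_pair(a, b) is expected

    def test_unmonitored_pairs_rejected(self):
        with pytest.raises(NotMonitoredError):
            classify_pair("couch_top", "body")  # patient rests on the couch
        with pytest.raises(NotMonitoredError):
            classify_pair("gantry_head", "kv_field")


def test_point_queries():
    box = trimesh.creation.box((10, 10, 10))
    assert point_mesh_distance([0, 0, 20], box) == pytest.approx(15.0, abs=1e-12)
    assert contains_point(box, [1, 1, 1])
    assert not contains_point(box, [20, 0, 0])
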