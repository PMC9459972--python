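"""Midsagittal plane construction and the two static symmetry metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from facesym import (
    MidsagittalPlane,
    aggregate_by_muscle,
    angle_symmetry,
    angle_symmetry_flattened,
    compute_symmetry_report,
    distance_symmetry,
    generate_session,
    midsagittal_plane,
    reflect_across_plane,
    similarity_transform,
)
from facesym.errors import DegenerateGeometryError


def _plane_x0():
    return MidsagittalPlane(point=np.zeros(3), normal=np.array([1.0, 0, 0]))


class TestMidsagittalPlane:
    def test_plane_from_iris_landmarks(self, template_478):
        ls, topo = template_478
        plane = midsagittal_plane(ls, topo)
        li = ls.points[topo.left_iris_index]
        ri = ls.points[topo.right_iris_index]
        assert np.allclose(plane.point, (li + ri) / 2)
        assert np.allclose(plane.normal, [1, 0, 0])  # template irises differ only in x

    @pytest.mark.parametrize(
        "left,right,point,normal",
        [
            ((-1, 0, 0), (1, 0, 0), (0, 0, 0), (1, 0, 0)),
            ((0, 0, 0), (0, 2, 0), (0, 1, 0), (0, 1, 0)),
        ],
    )
    def test_worked_plane_examples(self, template_68, left, right, point, normal):
        ls, topo = template_68
        pts = np.array(ls.points)
        pts[topo.left_iris_index] = left
        pts[topo.right_iris_index] = right
        plane = midsagittal_plane(ls.with_points(pts), topo)
        assert np.allclose(plane.point, point) and np.allclose(plane.normal, normal)

    def test_coincident_irises_degenerate(self, template_68):
        ls, topo = template_68
        pts = np.array(ls.points)
        pts[topo.right_iris_index] = pts[topo.left_iris_index]
        with pytest.raises(DegenerateGeometryError):
            midsagittal_plane(ls.with_points(pts), topo)


class TestReflection:
    def test_point_on_plane_is_fixed(self):
        assert np.allclose(reflect_across_plane(np.array([0.0, 3, -2]), _plane_x0()), [0, 3, -2])

    def test_mirror_across_x0(self):
        assert np.allclose(reflect_across_plane(np.array([1.0, 0, 0]), _plane_x0()), [-1, 0, 0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=hnp.arrays(np.float64, 3, elements=st.floats(-10, 10, allow_nan=False)),
        n=hnp.arrays(np.float64, 3, elements=st.floats(-1, 1, allow_nan=False)),
        q=hnp.arrays(np.float64, 3, elements=st.floats(-5, 5, allow_nan=False)),
    )
    def test_reflection_is_an_involution(self, p, n, q):
        norm = np.linalg.norm(n)
        if norm < 1e-3:
            n = np.array([1.0, 0, 0])
            norm = 1.0
        plane = MidsagittalPlane(point=q, normal=n / norm)
        assert np.allclose(reflect_across_plane(reflect_across_plane(p, plane), plane), p, atol=1e-9)


class TestDistanceSymmetry:
    def test_mirror_symmetric_template_scores_zero(self, template_478):
        ls, topo = template_478
        values = distance_symmetry(ls, topo)
        assert len(values) == len(topo.pairs)
        assert max(values.values()) == 0.0

    def test_worked_offset_pair(self, template_68):
        # left (-1,0,0) reflects to (1,0,0); right at (1.5,0,0) -> d = 0.5
        ls, topo = template_68
        pts = np.array(ls.points)
        left, right = topo.pairs[0]
        pts[left] = (-1, 0, 0)
        pts[right] = (1.5, 0, 0)
        pts[topo.left_iris_index] = (-1, 0, 0.5)
        pts[topo.right_iris_index] = (1, 0, 0.5)
        values = distance_symmetry(ls.with_points(pts), topo)
        assert values[(left, right)] == pytest.approx(0.5, abs=1e-12)

    def test_matches_coordinatewise_reimplementation_on_palsy_face(self):
        session = generate_session(palsy_side="left", palsy_attenuation=0.4, seed=3)
        ls, topo = session.smile.landmarks, session.topology
        plane = midsagittal_plane(ls, topo)
        values = distance_symmetry(ls, topo, plane)
        for left, right in topo.pairs[::17]:
            pl = ls.points[left]
            # reflect manually, coordinate by coordinate
            offset = sum((pl[j] - plane.point[j]) * plane.normal[j] for j in range(3))
            refl = [pl[j] - 2.0 * offset * plane.normal[j] for j in range(3)]
            pr = ls.points[right]
            expected = math.sqrt(sum((pr[j] - refl[j]) ** 2 for j in range(3)))
            assert values[(left, right)] == pytest.approx(expected, abs=1e-12)


class TestAngleSymmetry:
    def test_mirror_symmetric_template_scores_one(self, template_478):
        ls, topo = template_478
        values = angle_symmetry(ls, topo)
        assert min(values.values()) == 1.0

    def test_pair_vector_parallel_and_oblique(self, template_68):
        ls, topo = template_68
        pts = np.array(ls.points)
        pts[topo.left_iris_index] = (-1, 0, 0)
        pts[topo.right_iris_index] = (1, 0, 0)
        (l0, r0), (l1, r1), (l2, r2) = topo.pairs[:3]
        pts[l0], pts[r0] = (-2, 1, 1), (3, 1, 1)        # parallel to normal
        pts[l1], pts[r1] = (-1, -1, 2), (-1, 1, 2)      # perpendicular (pure +y)
        pts[l2], pts[r2] = (0, 0, 3), (1, 1, 3)         # 45 degrees in xy
        values = angle_symmetry(ls.with_points(pts), topo)
        assert values[(l0, r0)] == pytest.approx(1.0, abs=1e-12)
        assert values[(l1, r1)] == pytest.approx(0.0, abs=1e-12)
        assert values[(l2, r2)] == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    def test_zero_length_pair_vector_excluded(self, template_68):
        ls, topo = template_68
        pts = np.array(ls.points)
        left, right = topo.pairs[0]
        pts[right] = pts[left]
        values = angle_symmetry(ls.with_points(pts), topo)
        assert (left, right) not in values
        assert len(values) == len(topo.pairs) - 1


class TestAggregation:
    def test_zero_values_aggregate_to_zero(self, template_478):
        _, topo = template_478
        values = {p: 0.0 for p in topo.pairs}
        agg = aggregate_by_muscle(values, topo)
        assert agg[8] == 0.0

    def test_mean_times_hundred_rounding(self, template_478):
        _, topo = template_478
        pairs8 = topo.group_pairs(8)
        values = {p: 0.0 for p in topo.pairs}
        values[pairs8[0]] = 0.01
        values[pairs8[1]] = 0.03
        sub = {pairs8[0]: 0.01, pairs8[1]: 0.03}
        agg = aggregate_by_muscle(sub, topo)
        assert agg[8] == pytest.approx(2.0)  # mean 0.02 * 100

    def test_all_cosines_one_gives_hundred(self, template_478):
        _, topo = template_478
        agg = aggregate_by_muscle({p: 1.0 for p in topo.pairs}, topo)
        assert agg[8] == 100.0

    def test_empty_group_marker(self, template_68):
        _, topo = template_68
        agg = aggregate_by_muscle({p: 1.0 for p in topo.pairs}, topo)
        assert agg[1] is None  # Frontalis empty in compact mode
        assert agg[8] == 100.0


class TestInvariances:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_invariance_of_both_metrics(self, seed):
        session = generate_session(palsy_side="left", palsy_attenuation=0.5, seed=seed)
        ls, topo = session.smile.landmarks, session.topology
        rng = np.random.default_rng(seed)
        angles = rng.uniform(-40, 40, 3)
        shift = rng.uniform(-1, 1, 3)
        moved = ls.with_points(similarity_transform(1.0, angles, shift).apply(ls.points))
        base_d = distance_symmetry(ls, topo)
        base_c = angle_symmetry(ls, topo)
        new_d = distance_symmetry(moved, topo)
        new_c = angle_symmetry(moved, topo)
        for p in topo.pairs:
            assert new_d[p] == pytest.approx(base_d[p], abs=1e-9)
            assert new_c[p] == pytest.approx(base_c[p], abs=1e-9)

    def test_scaling_behaviour(self):
        session = generate_session(palsy_side="left", palsy_attenuation=0.5, seed=1)
        ls, topo = session.smile.landmarks, session.topology
        scaled = ls.with_points(2.0 * ls.points)
        base_d = distance_symmetry(ls, topo)
        base_c = angle_symmetry(ls, topo)
        for p, v in distance_symmetry(scaled, topo).items():
            assert v == pytest.approx(2.0 * base_d[p], abs=1e-9)  # linear in scale
        for p, v in angle_symmetry(scaled, topo).items():
            assert v == pytest.approx(base_c[p], abs=1e-12)  # scale-invariant

    def test_monotone_in_palsy_severity(self):
        affected = 8  # Orbicularis Oris: fully inside the smile field
        dist_vals, angle_vals = [], []
        for alpha in (1.0, 0.75, 0.5, 0.25, 0.0):
            session = generate_session(palsy_side="left", palsy_attenuation=alpha, seed=0)
            rep = compute_symmetry_report(session.smile.landmarks, session.topology)
            dist_vals.append(rep.per_muscle_distance[affected])
            angle_vals.append(rep.per_muscle_angle[affected])
        assert dist_vals == sorted(dist_vals)  # distance grows with severity
        assert angle_vals == sorted(angle_vals, reverse=True)  # cosine shrinks

    def test_flattened_variant_at_perfect_symmetry(self, template_478):
        # stacking pair vectors of unequal magnitude against copies of the
        # normal caps the flattened cosine strictly below 1 (Cauchy-Schwarz
        # equality needs equal magnitudes) - the reason the averaged per-pair
        # form is the reporting default
        ls, topo = template_478
        flat = angle_symmetry_flattened(ls, topo)
        a = np.array([ls.points[r] - ls.points[l] for l, r in topo.group_pairs(8)])
        expected = a[:, 0].sum() / (math.sqrt(len(a)) * np.linalg.norm(a))
        assert flat[8] == pytest.approx(expected, abs=1e-12)
        assert 0.9 < flat[8] < 1.0
        assert flat[2] is None  # Corrugator has no internal pairs
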