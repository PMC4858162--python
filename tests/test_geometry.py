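"""COM metrics: distances, angles, dihedrals, handedness, Kabsch, RMSD100."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from clampdyn.geometry import (
    DegenerateGeometryError,
    GeometrySeries,
    com_angle,
    com_dihedral,
    com_distance,
    handedness_sum,
    inter_domain_rotation,
    kabsch_superpose,
    rmsd100,
    rotation_angle_axis,
    series_summary,
    unwrap_degrees,
)
from clampdyn.synthetic import (
    DeformationSpec,
    RingSpec,
    apply_deformation,
    build_ideal_ring,
    mirror_z,
)
from clampdyn.topology import assign_domains


# ------------------------------------------------------------------ oracles

def dihedral_oracle(p1, p2, p3, p4):
    """Praxeolitic formula: project the outer bonds onto the plane normal to
    the central bond and take the signed angle between the projections —
    independent of the implementation's algebra."""
    b0 = p1 - p2
    b1 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    b2 = p4 - p3
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return math.degrees(math.atan2(y, x))


def quaternion_superpose_rmsd(X, Y):
    """Horn's quaternion method for optimal superposition RMSD."""
    X0 = X - X.mean(axis=0)
    Y0 = Y - Y.mean(axis=0)
    M = X0.T @ Y0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    msd = ((X0**2).sum() + (Y0**2).sum() - 2 * lam) / len(X)
    return math.sqrt(max(msd, 0.0))


# ------------------------------------------------------------- point metrics

class TestDistanceAngle:
    def test_distance_examples_and_norm_oracle(self):
        assert com_distance([0, 0, 0], [0, 0, 0]) == 0.0
        assert com_distance([0, 0, 0], [3, 4, 0]) == pytest.approx(5.0)
        rng = np.random.default_rng(0)
        for _ in range(100):
            p, q = rng.normal(size=(2, 3)) * 10
            assert com_distance(p, q) == pytest.approx(
                float(np.sqrt(((p - q) ** 2).sum())), abs=1e-12
            )

    def test_angle_examples(self):
        assert com_angle([0, 0, 0], [1, 0, 0], [2, 0, 0]) == pytest.approx(180.0)
        assert com_angle([1, 0, 0], [0, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_angle_degenerate_vertex(self):
        with pytest.raises(DegenerateGeometryError):
            com_angle([0, 0, 0], [0, 0, 0], [1, 0, 0])


class TestDihedral:
    def test_cis_trans(self):
        assert com_dihedral([0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]) == (
            pytest.approx(0.0, abs=1e-12)
        )
        assert com_dihedral([0, 0, 0], [1, 0, 0], [1, 1, 0], [2, 1, 0]) == (
            pytest.approx(180.0)
        )

    @pytest.mark.parametrize("angle", [25.0, -25.0, 90.0, 179.0, -170.0])
    def test_constructed_rotation_recovered(self, angle):
        p1, p2, p3 = np.array([0.0, 0, 0]), np.array([1.0, 0, 0]), np.array([1.0, 1, 0])
        p4_cis = np.array([0.0, 1, 0])
        axis = (p3 - p2) / np.linalg.norm(p3 - p2)
        R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
        p4 = (p4_cis - p2) @ R.T + p2
        assert com_dihedral(p1, p2, p3, p4) == pytest.approx(angle, abs=1e-9)

    def test_matches_plane_normal_oracle_on_random_configurations(self):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < 1000:
            pts = rng.normal(size=(4, 3)) * 5
            try:
                got = com_dihedral(*pts)
            except DegenerateGeometryError:
                continue
            assert got == pytest.approx(dihedral_oracle(*pts), abs=1e-9)
            checked += 1

    def test_collinear_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            com_dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_rigid_motion_invariance_and_mirror_antisymmetry(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(4, 3)) * 5
        ref = com_dihedral(*pts)
        R = Rotation.random(random_state=3).as_matrix()
        t = rng.normal(size=3)
        moved = pts @ R.T + t
        assert com_dihedral(*moved) == pytest.approx(ref, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        assert com_dihedral(*mirrored) == pytest.approx(-ref, abs=1e-9)


class TestHandedness:
    def test_planar_ring_is_achiral(self, ideal_ring):
        s, topo, a = ideal_ring
        assert handedness_sum(s, topo, a) == pytest.approx(0.0, abs=1e-6)

    def test_constructed_rh_spiral_sums_to_plus_sixty(self, ideal_ring):
        s, topo, a = ideal_ring
        d = DeformationSpec(mode="rh_spiral", twist_deg=20.0)
        s2, _ = apply_deformation(s, topo, d)
        assert handedness_sum(s2, topo, a) == pytest.approx(60.0, abs=1e-6)

    def test_mirror_negates(self, ideal_ring):
        s, topo, a = ideal_ring
        d = DeformationSpec(mode="rh_spiral", twist_deg=13.0)
        s2, _ = apply_deformation(s, topo, d)
        hs = handedness_sum(s2, topo, a)
        assert handedness_sum(mirror_z(s2), topo, a) == pytest.approx(-hs, abs=1e-9)

    def test_additivity_over_individual_torsions(self, ideal_ring):
        from clampdyn.topology import domain_com

        s, topo, a = ideal_ring
        d = DeformationSpec(mode="rh_spiral", twist_deg=8.5)
        s2, _ = apply_deformation(s, topo, d)
        coms = {lab: domain_com(s2, a, lab) for lab in topo.labels}
        total = sum(
            com_dihedral(*(coms[q] for q in quad))
            for quad in topo.torsion_quadruples
        )
        assert handedness_sum(s2, topo, a) == total  # exact, same arithmetic path


class TestKabsch:
    def test_self_superposition_identity(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        R, t, rmsd = kabsch_superpose(X, X)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_exact_fit_recovers_rotation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(8, 3)) * 4
        R_true = Rotation.random(random_state=5).as_matrix()
        t_true = np.array([1.0, -2.0, 3.0])
        Y = X @ R_true.T + t_true
        R, t, rmsd = kabsch_superpose(X, Y)
        np.testing.assert_allclose(R, R_true, atol=1e-9)
        np.testing.assert_allclose(t, t_true, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_agrees_with_quaternion_oracle_on_random_clouds(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            X = rng.normal(size=(10, 3)) * 3
            Y = rng.normal(size=(10, 3)) * 3
            _, _, rmsd = kabsch_superpose(X, Y)
            assert rmsd == pytest.approx(quaternion_superpose_rmsd(X, Y), abs=1e-9)

    def test_superposed_rmsd_not_above_raw(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            X = rng.normal(size=(12, 3)) * 3
            Y = rng.normal(size=(12, 3)) * 3
            _, _, rmsd = kabsch_superpose(X, Y)
            raw = math.sqrt((((X - X.mean(0)) - (Y - Y.mean(0))) ** 2)
                            .sum(axis=1).mean())
            assert rmsd <= raw + 1e-12

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestRmsd100:
    def test_identity_at_n100(self):
        assert rmsd100(1.7, 100) == pytest.approx(1.7)

    def test_formula_at_n200(self):
        assert rmsd100(2.0, 200) == pytest.approx(2.0 / (1.0 + math.log(2.0)),
                                                  abs=1e-12)

    def test_zero_rmsd(self):
        assert rmsd100(0.0, 366) == 0.0

    def test_monotone_decreasing_in_n(self):
        vals = [rmsd100(2.0, n) for n in (100, 150, 366, 774)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rmsd100(1.0, 0)
        with pytest.raises(ValueError):
            rmsd100(-1.0, 100)


class TestInterDomainRotation:
    def _clouds(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(15, 3)) * np.array([3.0, 2.0, 1.0])
        b = rng.normal(size=(15, 3)) * np.array([3.0, 1.5, 1.0]) + np.array([10.0, 0, 0])
        return a, b

    def test_rigid_co_rotation_gives_zero(self):
        a, b = self._clouds()
        R = Rotation.random(random_state=2).as_matrix()
        # SVD round-off near the identity limits precision to ~1e-6 deg
        assert inter_domain_rotation(a, a @ R.T, b, b @ R.T) == pytest.approx(
            0.0, abs=1e-5
        )

    @pytest.mark.parametrize("angle", [15.0, -15.0, 4.1, 170.0])
    def test_constructed_rotation_about_interdomain_axis(self, angle):
        a, b = self._clouds(1)
        axis = b.mean(axis=0) - a.mean(axis=0)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.radians(angle) * axis).as_matrix()
        b_cur = (b - b.mean(axis=0)) @ R.T + b.mean(axis=0)
        got = inter_domain_rotation(a, a, b, b_cur)
        assert got == pytest.approx(angle, abs=1e-7)

    def test_mirror_flips_sign_preserves_magnitude(self):
        a, b = self._clouds(2)
        axis = b.mean(axis=0) - a.mean(axis=0)
        axis = axis / np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.radians(12.0) * axis).as_matrix()
        b_cur = (b - b.mean(axis=0)) @ R.T + b.mean(axis=0)
        M = np.diag([1.0, 1.0, -1.0])
        got = inter_domain_rotation(a @ M, a @ M, b @ M, b_cur @ M)
        assert got == pytest.approx(-12.0, abs=1e-7)

    def test_rotation_angle_axis_consistency(self):
        R = Rotation.from_rotvec(np.radians(37.0) * np.array([0, 0, 1.0])).as_matrix()
        ang, axis = rotation_angle_axis(R)
        assert ang == pytest.approx(37.0, abs=1e-9)
        np.testing.assert_allclose(axis, [0, 0, 1.0], atol=1e-9)


class TestSeriesSummary:
    def test_constant_series(self):
        s = GeometrySeries("d", "A", np.full(20, 5.0),
                           time_ps=np.arange(20.0), discard_ps=0.0)
        mean, sd = series_summary(s)
        assert (mean, sd) == (5.0, 0.0)

    def test_hand_computed_after_discard(self):
        s = GeometrySeries(
            "d", "A", np.array([99.0, 99.0, 1.0, 2.0, 3.0]),
            time_ps=np.array([0.0, 5000.0, 10_000.0, 11_000.0, 12_000.0]),
        )
        mean, sd = series_summary(s)
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_angular_series_unwrapped_across_branch_cut(self):
        vals = np.array([170.0, 175.0, -180.0, -175.0, -170.0])
        s = GeometrySeries("phi", "deg", vals, time_ps=np.arange(5.0),
                           discard_ps=0.0)
        mean, _ = series_summary(s)
        assert mean == pytest.approx(180.0)  # continuation 170,175,180,185,190

    def test_insufficient_data_error(self):
        s = GeometrySeries("d", "A", np.array([1.0, 2.0]),
                           time_ps=np.array([0.0, 1.0]), discard_ps=10.0)
        with pytest.raises(ValueError):
            series_summary(s)

    def test_gaussian_recovery_within_sampling_error(self):
        rng = np.random.default_rng(99)
        vals = rng.normal(13.9, 4.4, size=1000)
        s = GeometrySeries("rot", "deg", vals, time_ps=np.arange(1000.0),
                           discard_ps=0.0)
        mean, sd = series_summary(s)
        assert abs(mean - 13.9) < 3 * 4.4 / math.sqrt(1000)
        assert sd == pytest.approx(4.4, rel=0.15)

    def test_unwrap_degrees_no_spurious_jumps(self):
        truth = np.linspace(0.0, 720.0, 200)
        wrapped = ((truth + 180.0) % 360.0) - 180.0
        np.testing.assert_allclose(unwrap_degrees(wrapped), truth, atol=1e-9)
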