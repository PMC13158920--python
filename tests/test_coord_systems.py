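import math

import numpy as np
import pytest

from intcoords import (
    CartesianGeometry,
    ConversionGraphError,
    IncompleteSystemError,
    InternalSystem,
    angle,
    compose_expansions,
    convert_systems,
    coordinate_derivatives,
    coordinate_value,
    delocalize,
    dihedral,
    dihedral_complete,
    direct_mode_coordinate,
    distance,
    make_fixture,
    relocalize,
    symmetric_combination,
    system_derivatives,
    system_values,
    triangle_complete,
)
from intcoords.coord_systems import b_matrix, check_complete
from tests.conftest import richardson_diff


def embed_triangle(r_ij, r_jk, theta):
    """Place j at origin, k on x, i in the xy-plane; return r_ik."""
    i = np.array([r_ij * math.cos(theta), r_ij * math.sin(theta), 0.0])
    k = np.array([r_jk, 0.0, 0.0])
    return float(np.linalg.norm(i - k))


def embed_chain(r_ij, r_jk, r_kl, t1, t2, tau):
    """Canonical Cartesian embedding of the 4-atom chain; return r_il."""
    i = np.array([r_ij * math.cos(t1), r_ij * math.sin(t1), 0.0])
    l = np.array(
        [
            r_jk - r_kl * math.cos(t2),
            r_kl * math.sin(t2) * math.cos(tau),
            r_kl * math.sin(t2) * math.sin(tau),
        ]
    )
    return float(np.linalg.norm(i - l))


class TestSystemDerivatives:
    def test_water_stack_shape_and_rank(self, water, water_system):
        exp = system_derivatives(water_system, water, 1)
        assert exp[1].shape == (9, 3)
        assert np.linalg.matrix_rank(exp[1]) == 3
        assert check_complete(water_system, water) == 3

    def test_stack_matches_per_coordinate_tensors(self, water, water_system):
        exp = system_derivatives(water_system, water, 3)
        for q, defn in enumerate(water_system.coords):
            per = coordinate_derivatives(defn, water, 3)
            for k in (1, 2, 3):
                np.testing.assert_array_equal(exp[k][..., q], per[k][..., 0])

    def test_linear_molecule_null_space_dimension(self):
        """Exactly linear acetylene has a 5-dimensional rigid-body null
        space, leaving 3N−5 = 7 internal dimensions; a bent chain reaches
        the full 3N−6 rank with primitive coordinates."""
        from intcoords import EckartFrame

        linear = make_fixture("acetylene")
        assert linear.is_linear()
        frame = EckartFrame(linear)
        assert frame.generators.shape[0] == 5
        assert linear.n_cartesian - frame.generators.shape[0] == 7

        bent = make_fixture("acetylene", perturbation=0.02, seed=3)
        assert not bent.is_linear()
        sys6 = InternalSystem(
            [
                distance(0, 1),
                distance(1, 2),
                distance(2, 3),
                angle(0, 1, 2),
                angle(1, 2, 3),
                dihedral(0, 1, 2, 3),
            ]
        )
        assert check_complete(sys6, bent) == 6

    def test_degeneracy_reports_coordinate_index(self):
        geom = CartesianGeometry(["C"] * 3, [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        sys_bad = InternalSystem([distance(0, 1), angle(0, 1, 2)])
        with pytest.raises(Exception, match="coordinate 1"):
            system_derivatives(sys_bad, geom, 1)


class TestTriangleComplete:
    def test_pythagorean(self):
        v, _ = triangle_complete(3.0, 4.0, math.pi / 2)
        assert v == pytest.approx(5.0, abs=1e-12)

    def test_collinear_limit(self):
        v, _ = triangle_complete(2.0, 3.0, math.pi)
        assert v == pytest.approx(5.0, rel=1e-9)

    def test_random_triangles_match_embedding(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            r1, r2 = rng.uniform(0.5, 3.0, 2)
            th = rng.uniform(0.1, math.pi - 0.1)
            v, _ = triangle_complete(r1, r2, th)
            assert v == pytest.approx(embed_triangle(r1, r2, th), abs=1e-10)

    def test_derivatives_match_finite_differences(self):
        x0 = np.array([1.1, 1.7, 1.9])
        _, derivs = triangle_complete(*x0, order=3)
        fd1 = richardson_diff(lambda x: np.array(triangle_complete(*x)[0]), x0)
        np.testing.assert_allclose(fd1, derivs[0], atol=1e-8)
        fd2 = richardson_diff(lambda x: triangle_complete(*x, order=1)[1][0], x0)
        np.testing.assert_allclose(fd2, derivs[1], atol=1e-7)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            triangle_complete(-1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            triangle_complete(1.0, 1.0, 3.5)


class TestDihedralComplete:
    def test_orthogonal_chain_gives_sqrt3(self):
        v, _ = dihedral_complete(1, 1, 1, math.pi / 2, math.pi / 2, math.pi / 2)
        assert v == pytest.approx(math.sqrt(3.0), abs=1e-12)

    def test_cis_shorter_than_trans(self):
        common = (1.0, 1.2, 1.0, 1.9, 1.9)
        cis, _ = dihedral_complete(*common, 1e-9)
        trans, _ = dihedral_complete(*common, math.pi - 1e-9)
        assert cis < trans

    def test_random_chains_match_embedding(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            r = rng.uniform(0.7, 2.0, 3)
            t = rng.uniform(0.2, math.pi - 0.2, 2)
            tau = rng.uniform(-math.pi, math.pi)
            v, _ = dihedral_complete(*r, *t, tau)
            assert v == pytest.approx(embed_chain(*r, *t, tau), abs=1e-10)

    def test_embedding_consistent_with_primitive_dihedral(self):
        """The canonical embedding reproduces the requested dihedral with
        the package's own sign convention."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            r = rng.uniform(0.7, 2.0, 3)
            t = rng.uniform(0.3, math.pi - 0.3, 2)
            tau = rng.uniform(-math.pi + 0.05, math.pi - 0.05)
            j = np.zeros(3)
            k = np.array([r[1], 0, 0])
            i = np.array([r[0] * math.cos(t[0]), r[0] * math.sin(t[0]), 0.0])
            l = np.array(
                [
                    r[1] - r[2] * math.cos(t[1]),
                    r[2] * math.sin(t[1]) * math.cos(tau),
                    r[2] * math.sin(t[1]) * math.sin(tau),
                ]
            )
            geom = CartesianGeometry(["C"] * 4, np.array([i, j, k, l]))
            assert coordinate_value(dihedral(0, 1, 2, 3), geom) == pytest.approx(tau, abs=1e-10)

    def test_derivatives_match_finite_differences(self):
        x0 = np.array([1.1, 1.4, 0.9, 1.8, 2.0, 0.8])
        _, derivs = dihedral_complete(*x0, order=2)
        fd1 = richardson_diff(lambda x: np.array(dihedral_complete(*x)[0]), x0)
        np.testing.assert_allclose(fd1, derivs[0], atol=1e-8)


def acetylene_like_system():
    return InternalSystem(
        [
            distance(1, 2),
            distance(1, 0),
            distance(2, 3),
            angle(0, 1, 2),
            angle(1, 2, 3),
            dihedral(0, 1, 2, 3),
        ]
    )


def vinylidene_like_system():
    return InternalSystem(
        [
            distance(1, 2),
            distance(1, 0),
            distance(1, 3),
            angle(0, 1, 2),
            angle(2, 1, 3),
            dihedral(0, 1, 2, 3),
        ]
    )


class TestConvertSystems:
    def test_sas_to_sss(self):
        src = InternalSystem([distance(0, 1), distance(1, 2), angle(0, 1, 2)])
        tgt = InternalSystem([distance(0, 1), distance(1, 2), distance(0, 2)])
        vals, exp = convert_systems([3.0, 4.0, math.pi / 2], src, tgt, order=1)
        np.testing.assert_allclose(vals, [3.0, 4.0, 5.0], atol=1e-12)
        # Jacobian of the shared coordinates is the identity block
        np.testing.assert_allclose(exp[1][:, :2], np.eye(3)[:, :2], atol=1e-12)

    def test_identity_conversion(self, chain4, chain4_system):
        vals = system_values(chain4_system, chain4)
        out, exp = convert_systems(vals, chain4_system, chain4_system, order=2)
        np.testing.assert_allclose(out, vals, atol=1e-12)
        np.testing.assert_allclose(exp[1], np.eye(6), atol=1e-12)
        np.testing.assert_allclose(exp[2], 0.0, atol=1e-12)

    def test_acetylene_vinylidene_round_trip(self, chain4):
        A, V = acetylene_like_system(), vinylidene_like_system()
        vals_A = system_values(A, chain4)
        vals_V, _ = convert_systems(vals_A, A, V, order=1)
        np.testing.assert_allclose(vals_V, system_values(V, chain4), atol=1e-10)
        back, _ = convert_systems(vals_V, V, A, order=1)
        np.testing.assert_allclose(back, vals_A, atol=1e-10)

    def test_composition_with_cartesian_tensors(self, chain4):
        """X→A tensors chained through the A→V conversion equal direct X→V
        tensors (path independence through an intermediate system)."""
        A, V = acetylene_like_system(), vinylidene_like_system()
        vals_A = system_values(A, chain4)
        _, a_to_v = convert_systems(vals_A, A, V, order=2)
        x_to_a = system_derivatives(A, chain4, 2)
        x_to_v = system_derivatives(V, chain4, 2)
        comp = compose_expansions(x_to_a, a_to_v)
        for k in (1, 2):
            np.testing.assert_allclose(
                comp[k], x_to_v[k], atol=1e-8 * max(1.0, np.abs(x_to_v[k]).max())
            )

    def test_unreachable_target_raises(self):
        src = InternalSystem([distance(0, 1)])
        tgt = InternalSystem([distance(2, 3)])
        with pytest.raises(ConversionGraphError, match="unreachable"):
            convert_systems([1.0], src, tgt)


class TestSymmetricCombination:
    def test_five_equal_distances(self):
        """S = (1/√5)(r₁+..+r₅) of five equal ring-to-metal distances
        evaluates to √5·r."""
        geom = make_fixture("ring5_metal_toy")
        dists = [distance(i, 5) for i in range(5)]
        S = symmetric_combination(dists, [1 / math.sqrt(5)] * 5)
        r = coordinate_value(dists[0], geom)
        assert coordinate_value(S, geom) == pytest.approx(math.sqrt(5.0) * r, abs=1e-12)

    def test_single_coordinate_identity(self, water):
        S = symmetric_combination([distance(0, 1)], [1.0])
        assert coordinate_value(S, water) == pytest.approx(
            coordinate_value(distance(0, 1), water)
        )

    def test_orthogonal_complement_coefficients(self):
        s = np.full(5, 1 / math.sqrt(5))
        # any orthonormal completion of s has zero overlap with it
        basis = np.linalg.svd(np.eye(5) - np.outer(s, s))[0][:, :4]
        np.testing.assert_allclose(basis.T @ s, 0.0, atol=1e-12)

    def test_no_higher_order_dependence_on_primitives(self, water):
        """∇_R^(n) of a linear combination vanishes for n > 1: its Cartesian
        tensors are exactly the coefficient-weighted primitive tensors."""
        defs = [distance(1, 0), distance(2, 0)]
        S = symmetric_combination(defs, [0.7, -0.3])
        e = coordinate_derivatives(S, water, 3)
        parts = [coordinate_derivatives(d, water, 3) for d in defs]
        for k in (1, 2, 3):
            np.testing.assert_allclose(
                e[k], 0.7 * parts[0][k] - 0.3 * parts[1][k], atol=1e-12
            )


class TestDelocalize:
    def water_redundant(self, water):
        return InternalSystem(
            [distance(1, 0), distance(2, 0), angle(1, 0, 2), distance(1, 2)]
        )

    def test_water_redundant_gives_three(self, water):
        deloc, C = delocalize(self.water_redundant(water), water)
        assert len(deloc.coords) == 3
        np.testing.assert_allclose(C @ C.T, np.eye(3), atol=1e-12)

    def test_nonredundant_recovered_up_to_orthogonal_mixing(self, water, water_system):
        deloc, C = delocalize(water_system, water)
        assert C.shape == (3, 3)
        np.testing.assert_allclose(C.T @ C, np.eye(3), atol=1e-12)

    def test_projector_equals_b_pinv_b(self, water):
        red = self.water_redundant(water)
        _, C = delocalize(red, water)
        B = b_matrix(red, water)
        # projector onto the retained coordinate-space span
        np.testing.assert_allclose(C.T @ C, np.linalg.pinv(B.T @ B) @ (B.T @ B), atol=1e-8)

    def test_rank_deficient_raises(self, water):
        small = InternalSystem([distance(1, 0), distance(2, 0)])
        with pytest.raises(IncompleteSystemError):
            delocalize(small, water)


class TestRelocalize:
    def test_identity_like_input_unchanged(self, water, water_system):
        deloc, C = delocalize(water_system, water)
        _, newC = relocalize(deloc)
        # objective at the result is no worse than at the input
        def objective(M):
            axes = np.argsort(-np.einsum("rm,rm->m", M, M))[: M.shape[0]]
            E = np.zeros_like(M)
            for r, ax in enumerate(sorted(axes)):
                E[r, ax] = 1.0
            return np.linalg.norm(M - E)

        assert objective(newC) <= objective(C) + 1e-12

    def test_protected_row_is_pure(self, water):
        red = InternalSystem(
            [distance(1, 0), distance(2, 0), angle(1, 0, 2), distance(1, 2)]
        )
        deloc, C = delocalize(red, water)
        v = C.T @ (C @ np.array([1.0, 1.0, 0.0, 0.0]))
        v /= np.linalg.norm(v)
        prot = symmetric_combination(red.coords, v)
        _, newC = relocalize(deloc, protected=[prot])
        np.testing.assert_allclose(newC[0], v, atol=1e-10)
        assert np.abs(newC[1:] @ newC[0]).max() <= 1e-10
        assert np.linalg.norm(newC[0]) == pytest.approx(1.0)

    def test_span_preserved(self, water):
        red = InternalSystem(
            [distance(1, 0), distance(2, 0), angle(1, 0, 2), distance(1, 2)]
        )
        deloc, C = delocalize(red, water)
        _, newC = relocalize(deloc)
        np.testing.assert_allclose(newC.T @ newC, C.T @ C, atol=1e-10)

    def test_out_of_span_protected_raises(self, water):
        red = InternalSystem(
            [distance(1, 0), distance(2, 0), angle(1, 0, 2), distance(1, 2)]
        )
        deloc, _ = delocalize(red, water)
        with pytest.raises(IncompleteSystemError):
            relocalize(deloc, protected=[red.coords[0]])


class TestDirectModeCoordinate:
    def setup_case(self, water):
        red = InternalSystem(
            [distance(1, 0), distance(2, 0), angle(1, 0, 2), distance(1, 2)]
        )
        B = b_matrix(red, water)
        inv1 = np.linalg.pinv(B)  # (m, 3N): rows = Cartesian responses
        return red, B, inv1

    def test_own_response_recovered_exactly(self, water):
        red, B, inv1 = self.setup_case(water)
        combo, coeffs, res = direct_mode_coordinate(
            red, water, inv1[2], inv1, mass_weighted=False
        )
        expected = np.zeros(4)
        expected[2] = 1.0
        # responses of a redundant set are linearly dependent, so compare the
        # fitted displacement rather than raw coefficients
        np.testing.assert_allclose(inv1.T @ coeffs, inv1[2], atol=1e-10)
        assert res <= 1e-10

    def test_orthogonal_displacement_gives_zero(self, water):
        red, B, inv1 = self.setup_case(water)
        # translation along x is orthogonal to all internal responses only
        # after Eckart projection; use an exactly orthogonal vector instead
        U, sv, Vt = np.linalg.svd(inv1, full_matrices=True)
        null_dir = Vt[-1]  # outside the span of the responses
        combo, coeffs, res = direct_mode_coordinate(
            red, water, null_dir, inv1, mass_weighted=False
        )
        np.testing.assert_allclose(coeffs, 0.0, atol=1e-10)
        assert res == pytest.approx(np.linalg.norm(null_dir), abs=1e-10)

    def test_residual_decreases_as_coordinates_added(self):
        """Nested least squares on an idealized ring-metal stretch: residual
        is monotonically non-increasing in the number of fit coordinates."""
        geom = make_fixture("ring5_metal_toy")
        coords = [distance(i, 5) for i in range(5)] + [distance(0, 2), distance(1, 3)]
        # idealized complex-stretch displacement: metal moves along +z
        disp = np.zeros((6, 3))
        disp[5, 2] = 1.0
        disp = disp.reshape(-1)
        prev = np.inf
        for m in range(1, len(coords) + 1):
            sub = InternalSystem(coords[:m])
            B = b_matrix(sub, geom)
            inv1 = np.linalg.pinv(B)
            _, _, res = direct_mode_coordinate(sub, geom, disp, inv1, mass_weighted=True)
            assert res <= prev + 1e-12
            prev = res
        assert prev < np.linalg.norm(disp * np.sqrt(np.repeat(geom.masses, 3)))
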