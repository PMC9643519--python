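"""Total-Lagrangian FEM core: assembly consistency, patch test, follower
pressures, prescribed rotations, and solver behaviour."""

import numpy as np
import pytest

from ontether.constitutive import ReducedPolynomialParams
from ontether.errors import MeshError, SolverError
from ontether.fem import (
    BoundaryConditionSet,
    FemModel,
    PressureLoad,
    SolveSchedule,
    adduction_rotation_matrix,
    prescribe_adduction,
    solve,
)
from ontether.fem.elements import SolidElement, FacetElement
from ontether.meshing import boundary_facets, mesh_box_block_3d, mesh_rect_block_2d
from ontether.units import mmhg_to_mpa

CARD = ReducedPolynomialParams((0.5, 0.1), (0.1, 0.0), "test")


@pytest.fixture(scope="module")
def block2d():
    m = mesh_rect_block_2d(2.0, 1.0, nx=3, ny=2)
    facets, _ = boundary_facets(m.elements, 2)
    m.node_sets["boundary"] = np.unique(facets)
    return m


@pytest.fixture(scope="module")
def block3d():
    m = mesh_box_block_3d(1.0, 1.0, 1.0, 2, 2, 2)
    facets, _ = boundary_facets(m.elements, 3)
    m.node_sets["boundary"] = np.unique(facets)
    return m


class TestElements:
    @pytest.mark.parametrize("dim", [2, 3])
    def test_partition_of_unity(self, dim):
        fam = SolidElement(dim)
        assert np.allclose(fam.N.sum(axis=1), 1.0)
        assert np.allclose(fam.dN.sum(axis=1), 0.0, atol=1e-14)

    @pytest.mark.parametrize("dim", [2, 3])
    def test_quadrature_measures(self, dim):
        fam = SolidElement(dim)
        ref = 0.5 if dim == 2 else 1.0 / 6.0
        assert fam.qw.sum() == pytest.approx(ref)
        assert FacetElement(dim).qw.sum() == pytest.approx(
            2.0 if dim == 2 else 0.5)


class TestAssembly:
    def test_zero_state_zero_residual(self, block2d):
        model = FemModel(block2d, {"block": CARD})
        f, K = model.internal_force_and_tangent(np.zeros(model.n_dof))
        assert np.abs(f).max() == 0.0
        assert K.shape == (model.n_dof, model.n_dof)

    @pytest.mark.parametrize("dim", [2, 3])
    def test_tangent_matches_finite_differences(self, dim, block2d, block3d,
                                                rng):
        mesh = block2d if dim == 2 else block3d
        model = FemModel(mesh, {"block": CARD})
        u = 0.01 * rng.standard_normal(model.n_dof)
        f, K = model.internal_force_and_tangent(u)
        du = 1e-6 * rng.standard_normal(model.n_dof)
        f2, _ = model.internal_force_and_tangent(u + du, need_tangent=False)
        df = K @ du
        assert np.linalg.norm(f2 - f - df) < 1e-4 * np.linalg.norm(df)

    def test_missing_material_rejected(self, block2d):
        with pytest.raises(MeshError):
            FemModel(block2d, {})


class _LinearFieldBC(BoundaryConditionSet):
    """Prescribes u = A X on the clamped node set."""

    def __init__(self, A, **kw):
        super().__init__(**kw)
        self._A = np.asarray(A)

    def prescribed_values(self, mesh, load_factor):
        return (mesh.nodes @ self._A.T) * load_factor


class TestPatchTest:
    @pytest.mark.parametrize("dim", [2, 3])
    def test_constant_stress_reproduced_to_machine_precision(
            self, dim, block2d, block3d, rng):
        mesh = block2d if dim == 2 else block3d
        A = 1e-4 * rng.standard_normal((dim, dim))
        model = FemModel(mesh, {"block": CARD})
        bc = _LinearFieldBC(A, fixed_sets=("boundary",), adduction_rad=0.0)
        sol = solve(model, bc,
                    SolveSchedule(increments=(1.0,), newton_tol=1e-12,
                                  max_bisections=0))
        F = model.deformation_gradients(sol.u)
        Fexp = np.eye(3)
        Fexp[:dim, :dim] += A
        assert np.abs(F - Fexp).max() < 1e-11
        sig = model.quadrature_cauchy(sol.u)
        spread = np.abs(sig - sig.reshape(-1, 3, 3).mean(axis=0)).max()
        assert spread < 1e-10 * np.abs(sig).max()


class TestRigidMotion:
    def test_rigid_rotation_produces_no_stress(self, block2d):
        # free-floating block, all boundary nodes carried through a large
        # rigid rotation (partial rotations per increment): discrete
        # objectivity requires a stress-free interior
        ang = np.radians(30.0)

        class _RotBC(BoundaryConditionSet):
            def prescribed_values(self, mesh, load_factor):
                a = ang * load_factor
                c, s = np.cos(a), np.sin(a)
                R = np.array([[c, -s], [s, c]])
                return mesh.nodes @ R.T - mesh.nodes

        model = FemModel(block2d, {"block": CARD})
        bc = _RotBC(fixed_sets=("boundary",), adduction_rad=0.0)
        # small rotation steps keep the interior in the rotating basin
        sol = solve(model, bc, SolveSchedule(
            increments=tuple(np.linspace(1 / 12, 1, 12))))
        sig = model.quadrature_cauchy(sol.u)
        assert np.abs(sig).max() < 1e-6


class TestPressure:
    def test_zero_pressure_zero_load(self, eye_mesh_2d):
        load = PressureLoad(eye_mesh_2d, "inner_scleral_surface", 0.0)
        f, K = load.force_and_stiffness(
            np.zeros(eye_mesh_2d.n_nodes * 2))
        assert np.abs(f).max() == 0.0

    def test_flat_facet_resultant(self):
        # single boundary edge of a unit square: |F| = p * area, inward
        m = mesh_rect_block_2d(1.0, 1.0, 1, 1)
        facets, _ = boundary_facets(m.elements, 2)
        mids = m.nodes[facets].mean(axis=1)
        bottom = facets[np.abs(mids[:, 1]) < 1e-12]
        m.facet_sets["bottom"] = bottom
        p = 0.25
        load = PressureLoad(m, "bottom", p)
        f, _ = load.force_and_stiffness(np.zeros(m.n_nodes * 2),
                                        need_stiffness=False)
        resultant = f.reshape(-1, 2).sum(axis=0)
        # outward normal of the bottom edge is -y; pressure pushes +y
        assert resultant[0] == pytest.approx(0.0, abs=1e-14)
        assert resultant[1] == pytest.approx(p * 1.0, rel=1e-12)

    def test_closed_surface_self_equilibrated(self, eye_mesh_2d):
        p = mmhg_to_mpa(15.0)
        load = PressureLoad(eye_mesh_2d, "inner_scleral_surface", p)
        u0 = np.zeros(eye_mesh_2d.n_nodes * 2)
        f, _ = load.force_and_stiffness(u0, need_stiffness=False)
        area = load.current_area(u0)
        net = np.linalg.norm(f.reshape(-1, 2).sum(axis=0))
        assert net < 1e-8 * p * area

    def test_load_stiffness_consistent(self, eye_mesh_2d, rng):
        load = PressureLoad(eye_mesh_2d, "inner_scleral_surface", 0.01)
        u = 0.01 * rng.standard_normal(eye_mesh_2d.n_nodes * 2)
        f, K = load.force_and_stiffness(u)
        du = 1e-6 * rng.standard_normal(len(u))
        f2, _ = load.force_and_stiffness(u + du, need_stiffness=False)
        assert np.linalg.norm(f2 - f - K @ du) < 1e-5 * np.linalg.norm(f2 - f)

    def test_unknown_facet_set(self, eye_mesh_2d):
        with pytest.raises(MeshError):
            PressureLoad(eye_mesh_2d, "no_such_surface", 1.0)


class TestPrescribedAdduction:
    def test_zero_angle_identity(self, eye_mesh_2d):
        ids, disp = prescribe_adduction(eye_mesh_2d, 0.0)
        assert np.abs(disp).max() == 0.0

    def test_rotation_matrix_oracle(self):
        R = adduction_rotation_matrix(np.radians(6.0), 3)
        x = np.array([12.0, 0.0, 0.0])
        expected = np.array([12 * np.cos(np.radians(6)), 0.0,
                             12 * np.sin(np.radians(6))])
        assert R @ x == pytest.approx(expected)
        # the corneal pole (anterior, -z) must move nasally (+x)
        cornea = np.array([0.0, 0.0, -12.0])
        assert (R @ cornea)[0] > 0

    def test_rigidity_of_constrained_set(self, eye_mesh_2d):
        ids, disp = prescribe_adduction(eye_mesh_2d, np.radians(6.0))
        X = eye_mesh_2d.nodes[ids]
        x = X + disp
        take = np.linspace(0, len(ids) - 1, 12).astype(int)
        d0 = np.linalg.norm(X[take][:, None] - X[take][None], axis=-1)
        d1 = np.linalg.norm(x[take][:, None] - x[take][None], axis=-1)
        assert np.abs(d0 - d1).max() < 1e-12


class TestSolver:
    def test_unloaded_solve_is_identically_zero(self, block2d):
        model = FemModel(block2d, {"block": CARD})
        block2d.node_sets.setdefault("corner", np.array([0]))
        bc = BoundaryConditionSet(fixed_sets=("boundary",),
                                  adduction_rad=0.0)
        sol = solve(model, bc, SolveSchedule(increments=(1.0,)))
        assert np.abs(sol.u).max() == 0.0
        assert np.abs(sol.cauchy_stress_qp()).max() == 0.0

    def test_schedule_validation(self):
        with pytest.raises(SolverError):
            SolveSchedule(increments=(0.5, 0.2))
        with pytest.raises(SolverError):
            SolveSchedule(increments=())
        with pytest.raises(SolverError):
            SolveSchedule(newton_tol=-1.0)

    def test_solution_invariant_under_element_reordering(self, rng):
        m1 = mesh_rect_block_2d(1.0, 1.0, 2, 2)
        facets, _ = boundary_facets(m1.elements, 2)
        m1.node_sets["boundary"] = np.unique(facets)
        A = np.array([[2e-3, 1e-3], [0.0, -1e-3]])
        model1 = FemModel(m1, {"block": CARD})
        bc = _LinearFieldBC(A, fixed_sets=("boundary",))
        u1 = solve(model1, bc, SolveSchedule(increments=(1.0,))).u

        m2 = mesh_rect_block_2d(1.0, 1.0, 2, 2)
        perm = rng.permutation(m2.n_elements)
        m2.elements = m2.elements[perm]
        m2.region_ids = m2.region_ids[perm]
        facets, _ = boundary_facets(m2.elements, 2)
        m2.node_sets["boundary"] = np.unique(facets)
        model2 = FemModel(m2, {"block": CARD})
        u2 = solve(model2, bc, SolveSchedule(increments=(1.0,))).u
        assert np.abs(u1 - u2).max() < 1e-10
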