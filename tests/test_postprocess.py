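"""Scalar fields, landmark patch summaries, and LC edge displacement."""

import numpy as np
import pytest

from ontether.errors import PostprocessError
from ontether.fem.bcs import adduction_rotation_matrix
from ontether.meshing import element_adjacency, element_centroids, \
    mesh_rect_block_2d
from ontether.postprocess import (
    LCDisplacement,
    RegionSummaryRule,
    lc_edge_displacement,
    max_principal_strain,
    principal_values,
    region_summary,
    select_patch,
    von_mises,
)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


class TestVonMises:
    def test_hydrostatic_is_zero(self):
        assert von_mises(-3.7 * np.eye(3)) == pytest.approx(0.0, abs=1e-14)

    def test_uniaxial_identity(self):
        s = np.zeros((3, 3))
        s[0, 0] = 2.5
        assert von_mises(s) == pytest.approx(2.5, rel=1e-14)

    def test_pure_shear_sqrt3(self):
        tau = 0.8
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = tau
        assert von_mises(s) == pytest.approx(np.sqrt(3.0) * tau, rel=1e-14)

    def test_rotation_invariance(self, rng):
        s = rng.standard_normal((3, 3))
        s = 0.5 * (s + s.T)
        v0 = von_mises(s)
        for _ in range(5):
            R = random_rotation(rng)
            assert von_mises(R @ s @ R.T) == pytest.approx(v0, rel=1e-12)

    def test_rejects_nonsymmetric(self):
        with pytest.raises(PostprocessError):
            von_mises(np.triu(np.ones((3, 3))))


class TestPrincipalStrain:
    def test_zero_strain(self):
        assert max_principal_strain(np.zeros((3, 3))) == 0.0

    def test_uniaxial_log_strain(self):
        lam = 1.17
        eps = np.diag([np.log(lam), -0.5 * np.log(lam), -0.5 * np.log(lam)])
        assert max_principal_strain(eps) == pytest.approx(np.log(lam),
                                                          rel=1e-14)

    def test_eigenvalues_non_increasing(self, rng):
        t = rng.standard_normal((3, 3))
        t = 0.5 * (t + t.T)
        w = principal_values(t)
        assert w[0] >= w[1] >= w[2]


@pytest.fixture(scope="module")
def block():
    return mesh_rect_block_2d(4.0, 1.0, nx=10, ny=3, region="block")


class TestRegionSummary:
    def test_k_bounds_enforced(self):
        with pytest.raises(PostprocessError):
            RegionSummaryRule(regions=("block",), element_count=11)
        with pytest.raises(PostprocessError):
            RegionSummaryRule(regions=("block",), element_count=17)
        RegionSummaryRule(regions=("block",), element_count=12)

    def test_uniform_field_returns_value(self, block):
        rule = RegionSummaryRule(regions=("block",), element_count=14)
        vals = np.full(block.n_elements, 3.25)
        out = region_summary(block, vals, rule, (0.0, 0.5))
        assert out == pytest.approx(3.25, rel=1e-15)

    def test_patch_is_contiguous_and_deterministic(self, block):
        adj = element_adjacency(block.elements, 2)
        p1 = select_patch(block, ("block",), (0.0, 0.5), 14, adj)
        p2 = select_patch(block, ("block",), (0.0, 0.5), 14, adj)
        assert np.array_equal(p1, p2)
        # contiguity: each element after the first touches an earlier one
        chosen = set()
        for e in p1:
            if chosen:
                assert adj[e] & chosen
            chosen.add(e)

    def test_mean_of_ranked_values(self, block):
        # values 1..12 planted on the selected patch -> mean 6.5
        adj = element_adjacency(block.elements, 2)
        patch = select_patch(block, ("block",), (2.0, 0.5), 12, adj)
        vals = np.zeros(block.n_elements)
        vals[patch] = np.arange(1, 13)
        rule = RegionSummaryRule(regions=("block",), element_count=12)
        assert region_summary(block, vals, rule, (2.0, 0.5)) == \
            pytest.approx(6.5)

    def test_too_small_region_errors(self, block):
        tiny = mesh_rect_block_2d(1.0, 1.0, 1, 1)
        rule = RegionSummaryRule(regions=("block",), element_count=14)
        with pytest.raises(PostprocessError):
            region_summary(tiny, np.zeros(tiny.n_elements), rule, (0.5, 0.5))


class _FakeSolution:
    def __init__(self, mesh, disp):
        self.displacements = disp
        self.mesh = mesh


class TestLCDisplacement:
    def test_zero_solution(self, block):
        sol = _FakeSolution(block, np.zeros_like(block.nodes))
        lc = lc_edge_displacement(sol, block, (0.0, 0.0))
        assert lc.as_tuple() == (0.0, 0.0)

    def test_rigid_translation(self, block):
        disp = np.tile([0.25, -0.1], (block.n_nodes, 1))
        sol = _FakeSolution(block, disp)
        lc = lc_edge_displacement(sol, block, (1.0, 0.5))
        assert lc.nasal_um == pytest.approx(250.0)
        assert lc.posterior_um == pytest.approx(-100.0)

    def test_rigid_rotation_matches_rotation_matrix(self, block):
        ang = np.radians(6.0)
        R = adduction_rotation_matrix(ang, 2)
        disp = block.nodes @ R.T - block.nodes
        sol = _FakeSolution(block, disp)
        lm = (3.0, 1.0)
        nid = np.argmin(np.linalg.norm(block.nodes - lm, axis=1))
        expected = (R @ block.nodes[nid] - block.nodes[nid]) * 1000.0
        lc = lc_edge_displacement(sol, block, lm)
        assert lc.nasal_um == pytest.approx(expected[0], abs=1e-9)
        assert lc.posterior_um == pytest.approx(expected[1], abs=1e-9)
        # compensating by the same angle recovers zero (globe-fixed frame)
        rel = lc_edge_displacement(sol, block, lm,
                                   rotation_compensation_rad=ang)
        assert abs(rel.nasal_um) < 1e-9
        assert abs(rel.posterior_um) < 1e-9

    def test_result_type(self):
        lc = LCDisplacement(nasal_um=1.0, posterior_um=2.0)
        assert lc.as_tuple() == (1.0, 2.0)
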