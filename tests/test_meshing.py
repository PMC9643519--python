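"""Structured quadratic meshing: validity, conformity, region tagging,
and the revolved 3-D eye mesh with its honeycomb partition."""

import numpy as np
import pytest
from scipy.integrate import quad

from ontether.errors import MeshError
from ontether.eyemesh import MeshDensity, generate_mesh
from ontether.geometry import OcularGeometryConfig, build_geometry
from ontether.meshing import (
    boundary_facets,
    check_jacobians,
    element_adjacency,
    element_centroids,
    element_volumes,
    elevate_to_quadratic,
    mesh_box_block_3d,
    mesh_rect_block_2d,
    mesh_spherical_shell_sector_3d,
    merge_duplicate_nodes,
)


class TestGenericMachinery:
    def test_merge_deduplicates_shared_interface(self):
        a = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0],
                      [1.0, 0.0], [2.0, 0.0], [2.0, 1.0], [1.0, 1.0]])
        cells = np.array([[0, 1, 2, 3], [4, 5, 6, 7]])
        nodes, remapped = merge_duplicate_nodes(a, cells)
        assert len(nodes) == 6
        assert len(np.intersect1d(remapped[0], remapped[1])) == 2

    def test_elevation_shares_midside_nodes(self):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        tris = np.array([[0, 1, 2], [1, 3, 2]])
        n2, conn = elevate_to_quadratic(nodes, tris, 2)
        assert conn.shape == (2, 6)
        # shared diagonal edge (1, 2) must produce a single mid node
        assert len(n2) == 4 + 5

    def test_block_meshes_are_valid(self):
        m2 = mesh_rect_block_2d(2.0, 1.0, 4, 2)
        assert len(check_jacobians(m2.nodes, m2.elements, 2)) == 0
        assert element_volumes(m2.nodes, m2.elements, 2).sum() == \
            pytest.approx(2.0, rel=1e-12)
        m3 = mesh_box_block_3d(1.0, 2.0, 3.0, 2, 1, 1)
        assert element_volumes(m3.nodes, m3.elements, 3).sum() == \
            pytest.approx(6.0, rel=1e-12)

    def test_boundary_facets_outward_2d(self):
        m = mesh_rect_block_2d(1.0, 1.0, 2, 2)
        facets, parents = boundary_facets(m.elements, 2)
        mids = m.nodes[facets].mean(axis=1)
        t = m.nodes[facets[:, 1]] - m.nodes[facets[:, 0]]
        normals = np.stack([t[:, 1], -t[:, 0]], axis=1)
        cen = element_centroids(m.nodes, m.elements)[parents]
        assert np.all(np.einsum("fi,fi->f", normals, mids - cen) > 0)

    def test_adjacency_symmetry(self):
        m = mesh_rect_block_2d(1.0, 1.0, 3, 3)
        adj = element_adjacency(m.elements, 2)
        for e, ns in enumerate(adj):
            for n in ns:
                assert e in adj[n]


class TestEyeMesh2D:
    def test_region_partition_complete(self, eye_mesh_2d):
        names = set(eye_mesh_2d.region_names)
        assert names == {"anterior_sclera", "equatorial_sclera",
                         "posterior_sclera", "peripapillary_sclera",
                         "lamina_cribrosa", "on_homogenized", "on_sheath"}
        assert len(eye_mesh_2d.region_ids) == eye_mesh_2d.n_elements

    def test_all_jacobians_positive(self, eye_mesh_2d):
        assert len(check_jacobians(eye_mesh_2d.nodes, eye_mesh_2d.elements,
                                   2)) == 0

    def test_facet_sets_lie_on_boundary(self, eye_mesh_2d):
        facets, _ = boundary_facets(eye_mesh_2d.elements, 2)
        bkeys = {tuple(sorted(f[:2])) for f in facets}
        for name, fs in eye_mesh_2d.facet_sets.items():
            assert len(fs) > 0
            for f in fs:
                assert tuple(sorted(f[:2])) in bkeys, name

    def test_refinement_increases_element_count(self, geometry):
        coarse = generate_mesh(geometry, density=MeshDensity().scaled(2.0),
                               mode="2d")
        fine = generate_mesh(geometry, density=MeshDensity().scaled(1.0),
                             mode="2d")
        assert fine.n_elements > coarse.n_elements

    def test_symmetry_plane_covers_all_nodes(self, eye_mesh_2d):
        assert len(eye_mesh_2d.node_sets["symmetry_plane"]) == \
            eye_mesh_2d.n_nodes

    def test_apex_and_rotation_sets_disjoint(self, eye_mesh_2d):
        apex = set(eye_mesh_2d.node_sets["apex_fixed_set"].tolist())
        rot = set(eye_mesh_2d.node_sets["anterior_rotation_set"].tolist())
        assert apex and rot
        assert not apex & rot

    def test_on_and_sheath_structures_mirror_in_x(self, eye_mesh_2d):
        # the ON/sheath assembly is nasal/temporal symmetric (only the
        # scleral thickness profile is allowed to differ between sides)
        for name in ("csf_inner_surface", "csf_outer_surface"):
            mid = eye_mesh_2d.nodes[eye_mesh_2d.facet_sets[name]].mean(axis=1)
            assert (mid[:, 0] > 0).sum() == (mid[:, 0] < 0).sum()


@pytest.fixture(scope="module")
def eye_mesh_3d(geometry):
    return generate_mesh(geometry,
                         density=MeshDensity(fine=0.45, coarse=2.4,
                                             axial_max=5.0,
                                             revolve_sectors=6),
                         mode="3d")


class TestEyeMesh3D:
    def test_valid_quadratic_tet_mesh(self, eye_mesh_3d):
        assert eye_mesh_3d.elements.shape[1] == 10
        assert len(check_jacobians(eye_mesh_3d.nodes, eye_mesh_3d.elements,
                                   3)) == 0

    def test_honeycomb_regions_present(self, eye_mesh_3d):
        names = set(eye_mesh_3d.region_names)
        assert {"on_connective", "on_neural"} <= names
        assert "on_homogenized" not in names

    def test_honeycomb_area_ratio(self, eye_mesh_3d, geometry):
        # prismatic channels: slab volume fractions realise the configured
        # connective fraction of 9/25 within 5%
        vols = element_volumes(eye_mesh_3d.nodes, eye_mesh_3d.elements, 3)
        cen = element_centroids(eye_mesh_3d.nodes, eye_mesh_3d.elements)
        conn = eye_mesh_3d.elements_in_region("on_connective")
        neur = eye_mesh_3d.elements_in_region("on_neural")
        on = np.concatenate([conn, neur])
        sel = (cen[on][:, 2] > 16.0) & (cen[on][:, 2] < 36.0)
        on_band = on[sel]
        vc = vols[np.intersect1d(on_band, conn)].sum()
        vn = vols[np.intersect1d(on_band, neur)].sum()
        frac = vc / (vc + vn)
        assert frac == pytest.approx(geometry.config.connective_fraction,
                                     abs=0.05 * 9 / 25)

    def test_symmetry_plane_tagging(self, eye_mesh_3d):
        ids = eye_mesh_3d.node_sets["symmetry_plane"]
        assert len(ids) > 0
        assert np.abs(eye_mesh_3d.nodes[ids, 1]).max() < 1e-9
        # every y=0 node is tagged (closure under the symmetry tagging)
        all_sym = np.flatnonzero(np.abs(eye_mesh_3d.nodes[:, 1]) < 1e-9)
        assert set(all_sym.tolist()) == set(ids.tolist())

    def test_hemi_model_occupies_y_nonnegative(self, eye_mesh_3d):
        assert eye_mesh_3d.nodes[:, 1].min() > -1e-9


class TestShellVolumeOracle:
    def test_globe_shell_volume_matches_quadrature(self, geometry):
        # bare shell sector (no canal machinery): compare the meshed
        # volume of the revolved shell against direct numerical quadrature
        # of the thickness field over the sphere
        g = build_geometry(OcularGeometryConfig())
        mesh = generate_mesh(g, density=MeshDensity(fine=0.45, coarse=1.6,
                                                    axial_max=5.0,
                                                    revolve_sectors=10),
                             mode="3d")
        vols = element_volumes(mesh.nodes, mesh.elements, 3)
        shell = mesh.elements_in_region(
            "anterior_sclera", "equatorial_sclera", "posterior_sclera",
            "peripapillary_sclera")
        v_mesh = vols[shell].sum()

        # quadrature oracle, independent of the mesher: half shell minus
        # the canal opening; thickness from the axisymmetric profile used
        # in 3-D mode
        R = g.R

        def dv(theta):
            d = np.array([np.sin(theta), 0.0, np.cos(theta)])
            t = float(g.shell_thickness(d, tilted_pole=False))
            r0 = R - t
            return np.pi * (R**3 - r0**3) / 3.0 * np.sin(theta)

        v_exact, _ = quad(dv, g.alpha_canal, np.pi, limit=400)
        assert v_mesh == pytest.approx(v_exact, rel=0.02)


class TestDensityValidation:
    def test_lc_layer_compatibility_enforced(self, geometry):
        with pytest.raises(MeshError):
            generate_mesh(geometry, density=MeshDensity(radial_layers=4),
                          mode="2d")

    def test_bad_mode_rejected(self, geometry):
        with pytest.raises(MeshError):
            generate_mesh(geometry, mode="1d")
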