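"""Mesh container and structured quadratic mesh generation.

Meshes are built from mapped structured blocks of linear cells (quads in
2-D, hexahedra in 3-D), merged on shared interfaces by coordinate
deduplication, converted to simplices, and elevated to quadratic elements
(6-node triangles / 10-node tetrahedra) with a single mid-node per global
edge, which keeps independently generated blocks conforming.  Element
geometry is subparametric: mid-edge nodes sit on the chord, so every element
Jacobian is affine and positivity is easy to guarantee; curved boundaries
are resolved by mesh density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MeshError
from .fem.elements import (
    SolidElement,
    TET10_FACES,
    TET10_EDGES,
    TRI6_EDGES,
    tet10_shape,
    tri6_shape,
)

__all__ = [
    "RegionTaggedMesh",
    "merge_duplicate_nodes",
    "quads_to_tris",
    "hexes_to_tets",
    "elevate_to_quadratic",
    "build_linear_blocks",
    "boundary_facets",
    "check_jacobians",
    "element_volumes",
    "element_centroids",
    "element_adjacency",
    "structured_quad_block",
    "structured_hex_block",
    "mesh_rect_block_2d",
    "mesh_box_block_3d",
    "mesh_spherical_shell_sector_3d",
]


@dataclass
class RegionTaggedMesh:
    """Quadratic-element mesh with per-element region labels.

    Attributes
    ----------
    dim : 2 or 3.  In 2-D mode the mesh is the horizontal symmetry-plane
        cross section; coordinates are (x, z) = (nasal, posterior) and the
        out-of-plane direction is superior (plane-strain contract).
    nodes : (n_nodes, dim) float, mm.
    elements : (n_elem, 6) tri6 or (n_elem, 10) tet10 connectivity.
    region_ids : (n_elem,) int indices into ``region_names``.
    facet_sets : name -> (n_facets, 3 or 6) boundary facet connectivity,
        oriented so the facet normal points out of the solid.
    node_sets : name -> int array of node ids.
    """

    dim: int
    nodes: np.ndarray
    elements: np.ndarray
    region_ids: np.ndarray
    region_names: tuple
    facet_sets: dict = field(default_factory=dict)
    node_sets: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def region_name(self, eid: int) -> str:
        return self.region_names[self.region_ids[eid]]

    def elements_in_region(self, *names) -> np.ndarray:
        ids = [i for i, n in enumerate(self.region_names) if n in names]
        return np.flatnonzero(np.isin(self.region_ids, ids))

    def facet_set(self, name: str) -> np.ndarray:
        try:
            return self.facet_sets[name]
        except KeyError:
            raise MeshError(
                f"unknown facet set {name!r}; have {sorted(self.facet_sets)}"
            ) from None

    def validate(self) -> "RegionTaggedMesh":
        if len(self.region_ids) != self.n_elements:
            raise MeshError("one region label required per element")
        bad = check_jacobians(self.nodes, self.elements, self.dim)
        if len(bad):
            raise MeshError(
                f"{len(bad)} elements with non-positive Jacobian, e.g. {bad[:5]}"
            )
        return self


# ---------------------------------------------------------------------------
# linear-mesh utilities
# ---------------------------------------------------------------------------

def merge_duplicate_nodes(nodes: np.ndarray, cells: np.ndarray, tol: float = 1e-6):
    """Merge nodes closer than ``tol`` (by rounded-coordinate hashing)."""
    key = np.round(np.asarray(nodes, dtype=float) / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True,
                                  return_inverse=True)
    order = np.argsort(first)          # keep stable node ordering
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_nodes = nodes[np.sort(first)]
    remap = rank[inverse]
    return new_nodes, remap[cells]


def quads_to_tris(quads: np.ndarray) -> np.ndarray:
    """Split each quad (a,b,c,d) into triangles (a,b,c) and (a,c,d)."""
    q = np.asarray(quads)
    return np.concatenate([q[:, [0, 1, 2]], q[:, [0, 2, 3]]], axis=0)


_HEX_FACES = ((0, 3, 2, 1), (4, 5, 6, 7), (0, 1, 5, 4),
              (1, 2, 6, 5), (2, 3, 7, 6), (3, 0, 4, 7))


def hexes_to_tets(nodes: np.ndarray, hexes: np.ndarray, tol: float = 1e-6):
    """Split hexes into tets via face- and body-centre nodes (24 per hex).

    Handles degenerate (collapsed) hexes produced by revolving cells that
    touch the revolution axis: zero-volume tets are dropped.  Returns
    (nodes, tets, parent) where ``parent`` maps each tet to its hex.
    """
    h = np.asarray(hexes)
    X = np.asarray(nodes, dtype=float)
    n0 = len(X)
    nh = len(h)
    body = X[h].mean(axis=1)                       # (nh, 3)
    faces = np.stack([X[h[:, list(f)]].mean(axis=1) for f in _HEX_FACES], axis=1)
    new_nodes = np.concatenate([X, body, faces.reshape(-1, 3)], axis=0)
    body_id = n0 + np.arange(nh)
    face_id = n0 + nh + np.arange(nh * 6).reshape(nh, 6)

    tets = []
    parents = []
    for fi, f in enumerate(_HEX_FACES):
        for k in range(4):
            a, b = f[k], f[(k + 1) % 4]
            t = np.stack([h[:, a], h[:, b], face_id[:, fi], body_id], axis=1)
            tets.append(t)
            parents.append(np.arange(nh))
    tets = np.concatenate(tets, axis=0)
    parents = np.concatenate(parents, axis=0)

    v = new_nodes[tets]
    vol = np.einsum("ei,ei->e", np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
                    v[:, 3] - v[:, 0]) / 6.0
    scale = max(np.abs(vol).max(), 1.0)
    keep = np.abs(vol) > 1e-12 * scale
    tets, parents, vol = tets[keep], parents[keep], vol[keep]
    flip = vol < 0
    tets[flip, 1], tets[flip, 2] = tets[flip, 2], tets[flip, 1].copy()
    new_nodes, tets = merge_duplicate_nodes(new_nodes, tets, tol=tol)
    return new_nodes, tets, parents


def _orient_simplices(nodes, cells, dim):
    cells = np.asarray(cells).copy()
    v = nodes[cells]
    if dim == 2:
        a = v[:, 1, :2] - v[:, 0, :2]
        b = v[:, 2, :2] - v[:, 0, :2]
        s = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    else:
        s = np.einsum("ei,ei->e",
                      np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]),
                      v[:, 3] - v[:, 0])
    flip = s < 0
    cells[flip, 1], cells[flip, 2] = cells[flip, 2], cells[flip, 1].copy()
    return cells


def elevate_to_quadratic(nodes: np.ndarray, cells: np.ndarray, dim: int):
    """tri3 -> tri6 or tet4 -> tet10 with one shared mid-node per edge."""
    cells = _orient_simplices(np.asarray(nodes, dtype=float), cells, dim)
    edges = TRI6_EDGES if dim == 2 else TET10_EDGES
    edge_ids = {}
    mids = []
    n0 = len(nodes)
    conn = np.empty((len(cells), cells.shape[1] + len(edges)), dtype=np.int64)
    conn[:, : cells.shape[1]] = cells
    for j, (a, b) in enumerate(edges):
        pairs = np.sort(cells[:, [a, b]], axis=1)
        col = np.empty(len(cells), dtype=np.int64)
        for e, (p, q) in enumerate(map(tuple, pairs)):
            key = (p, q)
            mid = edge_ids.get(key)
            if mid is None:
                mid = n0 + len(mids)
                edge_ids[key] = mid
                mids.append(key)
            col[e] = mid
        conn[:, cells.shape[1] + j] = col
    mids = np.asarray(mids, dtype=np.int64)
    mid_xyz = 0.5 * (nodes[mids[:, 0]] + nodes[mids[:, 1]]) if len(mids) else \
        np.zeros((0, nodes.shape[1]))
    return np.concatenate([nodes, mid_xyz], axis=0), conn


def build_linear_blocks(blocks, dim: int, tol: float = 1e-6):
    """Merge (vertices, cells, region) quad/hex blocks into one simplex mesh.

    Returns (nodes, simplices, region_ids, region_names).
    """
    all_nodes, all_cells, labels = [], [], []
    offset = 0
    for verts, cells, region in blocks:
        verts = np.asarray(verts, dtype=float)
        cells = np.asarray(cells, dtype=np.int64) + offset
        all_nodes.append(verts)
        all_cells.append(cells)
        if isinstance(region, str):
            labels.extend([region] * len(cells))
        else:
            if len(region) != len(cells):
                raise MeshError("per-cell region array has wrong length")
            labels.extend(list(region))
        offset += len(verts)
    nodes = np.concatenate(all_nodes, axis=0)
    cells = np.concatenate(all_cells, axis=0)
    labels = np.asarray(labels)
    nodes, cells = merge_duplicate_nodes(nodes, cells, tol=tol)
    region_names = tuple(dict.fromkeys(labels))
    name_to_id = {n: i for i, n in enumerate(region_names)}
    rid = np.array([name_to_id[n] for n in labels], dtype=np.int64)
    if dim == 2:
        tris = quads_to_tris(cells)
        rid = np.concatenate([rid, rid])
        return nodes, tris, rid, region_names
    nodes, tets, parent = hexes_to_tets(nodes, cells, tol=tol)
    return nodes, tets, rid[parent], region_names


# ---------------------------------------------------------------------------
# quadratic-mesh queries
# ---------------------------------------------------------------------------

def _corner_count(dim):
    return 3 if dim == 2 else 4


def boundary_facets(elements: np.ndarray, dim: int):
    """Boundary facets of a quadratic mesh, outward oriented.

    Returns (facets, parent_elements); facets are (n, 3) edge3 rows in 2-D
    and (n, 6) tri6 rows in 3-D, ordered so that the facet normal (rotate
    tangent by -90 deg in 2-D; cross(x_xi, x_eta) in 3-D) points out of the
    solid, inherited from positively oriented parent elements.
    """
    el = np.asarray(elements)
    if dim == 2:
        local = [(0, 1, 3), (1, 2, 4), (2, 0, 5)]
    else:
        local = [list(f) for f in TET10_FACES]
    facets, parents, keys = [], [], []
    for lf in local:
        f = el[:, lf]
        facets.append(f)
        parents.append(np.arange(len(el)))
        keys.append(np.sort(f[:, : dim], axis=1))
    facets = np.concatenate(facets, axis=0)
    parents = np.concatenate(parents, axis=0)
    keys = np.concatenate(keys, axis=0)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True,
                               return_counts=True)
    on_boundary = counts[inv] == 1
    return facets[on_boundary], parents[on_boundary]


def check_jacobians(nodes, elements, dim):
    """Element ids whose Jacobian is non-positive at any quadrature point."""
    fam = SolidElement(dim)
    X = nodes[elements]                          # (ne, nen, dim)
    J = np.einsum("qad,ean->eqnd", fam.dN, X)    # dx/dxi (ne, nq, dim, dim)
    det = np.linalg.det(J)
    return np.flatnonzero(np.any(det <= 0.0, axis=1))


def element_volumes(nodes, elements, dim):
    fam = SolidElement(dim)
    X = nodes[elements]
    J = np.einsum("qad,ean->eqnd", fam.dN, X)
    det = np.linalg.det(J)
    return det @ fam.qw


def element_centroids(nodes, elements):
    return nodes[elements].mean(axis=1)


def element_adjacency(elements: np.ndarray, dim: int):
    """Map element id -> set of face/edge-sharing neighbour ids."""
    el = np.asarray(elements)
    nc = _corner_count(dim)
    if dim == 2:
        sides = [(0, 1), (1, 2), (2, 0)]
    else:
        sides = [f[:3] for f in TET10_FACES]
    owner = {}
    adj = [set() for _ in range(len(el))]
    for lf in sides:
        keys = np.sort(el[:, list(lf)], axis=1)
        for e, key in enumerate(map(tuple, keys)):
            other = owner.get(key)
            if other is None:
                owner[key] = e
            else:
                adj[e].add(other)
                adj[other].add(e)
    return adj


# ---------------------------------------------------------------------------
# structured blocks and benchmark meshes
# ---------------------------------------------------------------------------

def structured_quad_block(u, v, mapping):
    """Vertices and quad cells of a mapped (len(u) x len(v)) grid."""
    U, V = np.meshgrid(np.asarray(u, float), np.asarray(v, float),
                       indexing="ij")
    verts = mapping(U.ravel(), V.ravel())
    if isinstance(verts, tuple):
        verts = np.stack(verts, axis=-1)
    verts = np.asarray(verts, dtype=float)
    nu, nv = len(u), len(v)
    idx = np.arange(nu * nv).reshape(nu, nv)
    quads = np.stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(),
                      idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()], axis=1)
    return verts, quads


def structured_hex_block(u, v, w, mapping):
    """Vertices and hex cells of a mapped 3-D grid."""
    U, V, W = np.meshgrid(np.asarray(u, float), np.asarray(v, float),
                          np.asarray(w, float), indexing="ij")
    verts = mapping(U.ravel(), V.ravel(), W.ravel())
    verts = np.stack(verts, axis=-1) if isinstance(verts, tuple) else verts
    nu, nv, nw = len(u), len(v), len(w)
    idx = np.arange(nu * nv * nw).reshape(nu, nv, nw)
    c = [idx[:-1, :-1, :-1], idx[1:, :-1, :-1], idx[1:, 1:, :-1],
         idx[:-1, 1:, :-1], idx[:-1, :-1, 1:], idx[1:, :-1, 1:],
         idx[1:, 1:, 1:], idx[:-1, 1:, 1:]]
    hexes = np.stack([a.ravel() for a in c], axis=1)
    return verts.reshape(-1, 3), hexes


def _finalize(nodes, simplices, rid, names, dim, facet_rules=(),
              node_rules=(), tol=1e-6):
    nodes, conn = elevate_to_quadratic(nodes, simplices, dim)
    mesh = RegionTaggedMesh(dim=dim, nodes=nodes, elements=conn,
                            region_ids=np.asarray(rid),
                            region_names=tuple(names))
    facets, parents = boundary_facets(conn, dim)
    mid = nodes[facets].mean(axis=1)
    for name, pred in facet_rules:
        sel = pred(mid, mesh.region_ids[parents])
        mesh.facet_sets[name] = facets[sel]
    for name, pred in node_rules:
        mesh.node_sets[name] = np.flatnonzero(pred(nodes))
    return mesh.validate()


def mesh_rect_block_2d(lx=1.0, ly=1.0, nx=2, ny=2, region="block"):
    """Quadratic-triangle mesh of a rectangle (verification workhorse)."""
    u = np.linspace(0.0, lx, nx + 1)
    v = np.linspace(0.0, ly, ny + 1)
    verts, quads = structured_quad_block(u, v, lambda a, b: (a, b))
    nodes, tris, rid, names = build_linear_blocks([(verts, quads, region)], 2)
    return _finalize(nodes, tris, rid, names, 2)


def mesh_box_block_3d(lx=1.0, ly=1.0, lz=1.0, nx=1, ny=1, nz=1,
                      region="block"):
    """Quadratic-tet mesh of a box."""
    u = np.linspace(0.0, lx, nx + 1)
    v = np.linspace(0.0, ly, ny + 1)
    w = np.linspace(0.0, lz, nz + 1)
    verts, hexes = structured_hex_block(u, v, w, lambda a, b, c: (a, b, c))
    nodes, tets, rid, names = build_linear_blocks([(verts, hexes, region)], 3)
    return _finalize(nodes, tets, rid, names, 3)


def mesh_spherical_shell_sector_3d(r_inner, r_outer, nr=2, ntheta=4, nphi=4,
                                   theta_range=(np.pi / 3, np.pi / 2),
                                   phi_range=(0.0, np.pi / 6),
                                   region="shell"):
    """Sector of a thick spherical shell (inflation benchmark mesh).

    The sector avoids the poles; its four lateral faces are two meridian
    planes (phi = const) and two cones (theta = const), on which the
    radially symmetric inflation solution has zero normal displacement.
    Facet sets: ``inner``, ``outer``; node sets ``phi0``, ``phi1``,
    ``theta0``, ``theta1`` for slider constraints.
    """
    t0, t1 = theta_range
    p0, p1 = phi_range

    def mapping(u, v, w):
        r = r_inner + (r_outer - r_inner) * u
        th = t0 + (t1 - t0) * v
        ph = p0 + (p1 - p0) * w
        return (r * np.sin(th) * np.cos(ph), r * np.sin(th) * np.sin(ph),
                r * np.cos(th))

    u = np.linspace(0, 1, nr + 1)
    v = np.linspace(0, 1, ntheta + 1)
    w = np.linspace(0, 1, nphi + 1)
    verts, hexes = structured_hex_block(u, v, w, mapping)
    nodes, tets, rid, names = build_linear_blocks([(verts, hexes, region)], 3)

    rtol = 1e-4 * r_outer

    def radius(mid):
        return np.linalg.norm(mid, axis=1)

    facet_rules = [
        ("inner", lambda mid, reg: radius(mid) < r_inner * (1 + 5e-3)),
        ("outer", lambda mid, reg: radius(mid) > r_outer * (1 - 5e-3)),
    ]
    mesh = _finalize(nodes, tets, rid, names, 3, facet_rules)

    # Lateral-face node sets are selected facet-wise: a boundary facet
    # belongs to a face iff all its corner vertices (which lie exactly on
    # the analytic surface) do; mid-edge chord nodes are then included.
    facets, _ = boundary_facets(mesh.elements, 3)
    X = mesh.nodes

    # Split-generated face-centre nodes are chord averages that sit O(h^2)
    # off the analytic cone, so the theta test uses a quarter-grid-spacing
    # tolerance (interior nodes are at least half a spacing away).
    theta_tol = 0.25 * (t1 - t0) / ntheta

    def vert_on_phi(ids, phi):
        n = np.array([-np.sin(phi), np.cos(phi), 0.0])
        return np.abs(X[ids] @ n) < rtol

    def vert_on_theta(ids, theta):
        r = np.linalg.norm(X[ids], axis=1)
        th = np.arccos(np.clip(X[ids][:, 2] / np.maximum(r, 1e-12), -1, 1))
        return np.abs(th - theta) < theta_tol

    for name, pred in (("phi0", lambda i: vert_on_phi(i, p0)),
                       ("phi1", lambda i: vert_on_phi(i, p1)),
                       ("theta0", lambda i: vert_on_theta(i, t0)),
                       ("theta1", lambda i: vert_on_theta(i, t1))):
        corner_ok = pred(facets[:, :3].ravel()).reshape(-1, 3).all(axis=1)
        mesh.node_sets[name] = np.unique(facets[corner_ok])
    return mesh
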