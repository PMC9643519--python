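"""Quadratic element families: shape functions and quadrature.

Solid elements are 6-node triangles (2-D, plane strain) and 10-node
tetrahedra (3-D); boundary facets are 3-node edges and 6-node triangles.
Node ordering follows the Gmsh convention (corners first, then mid-edge
nodes: tri (01,12,20); tet (01,12,02,03,13,23)).
"""

from __future__ import annotations

import numpy as np

TRI6_EDGES = ((0, 1), (1, 2), (2, 0))
TET10_EDGES = ((0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (2, 3))
#: Faces of a tet4, outward when the tet is positively oriented.
TET_FACES = ((0, 2, 1), (0, 1, 3), (1, 2, 3), (0, 3, 2))
#: tri6 facet node ids on each tet10 face (corners + mid-edge).
TET10_FACES = ((0, 2, 1, 6, 5, 4), (0, 1, 3, 4, 8, 7),
               (1, 2, 3, 5, 9, 8), (0, 3, 2, 7, 9, 6))


def tri6_shape(points: np.ndarray):
    """Shape functions and reference gradients of the 6-node triangle.

    ``points`` is (nq, 2) in barycentric-style reference coordinates
    (xi, eta) with the triangle {xi>=0, eta>=0, xi+eta<=1}.
    Returns N (nq, 6) and dN (nq, 6, 2).
    """
    pts = np.asarray(points, dtype=float)
    xi, eta = pts[:, 0], pts[:, 1]
    l0 = 1.0 - xi - eta
    l1, l2 = xi, eta
    N = np.stack([
        l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
        4 * l0 * l1, 4 * l1 * l2, 4 * l2 * l0,
    ], axis=1)
    z = np.zeros_like(xi)
    dl0 = np.stack([-np.ones_like(xi), -np.ones_like(xi)], axis=1)
    dl1 = np.stack([np.ones_like(xi), z], axis=1)
    dl2 = np.stack([z, np.ones_like(xi)], axis=1)
    dN = np.stack([
        (4 * l0 - 1)[:, None] * dl0,
        (4 * l1 - 1)[:, None] * dl1,
        (4 * l2 - 1)[:, None] * dl2,
        4 * (l1[:, None] * dl0 + l0[:, None] * dl1),
        4 * (l2[:, None] * dl1 + l1[:, None] * dl2),
        4 * (l0[:, None] * dl2 + l2[:, None] * dl0),
    ], axis=1)
    return N, dN


def tet10_shape(points: np.ndarray):
    """Shape functions / gradients of the 10-node tetrahedron (nq, 3)."""
    pts = np.asarray(points, dtype=float)
    xi, eta, zet = pts[:, 0], pts[:, 1], pts[:, 2]
    l0 = 1.0 - xi - eta - zet
    l1, l2, l3 = xi, eta, zet
    ls = [l0, l1, l2, l3]
    one = np.ones_like(xi)
    z = np.zeros_like(xi)
    dls = [np.stack([-one, -one, -one], axis=1),
           np.stack([one, z, z], axis=1),
           np.stack([z, one, z], axis=1),
           np.stack([z, z, one], axis=1)]
    Ns = [l * (2 * l - 1) for l in ls]
    dNs = [(4 * l - 1)[:, None] * dl for l, dl in zip(ls, dls)]
    for a, b in TET10_EDGES:
        Ns.append(4 * ls[a] * ls[b])
        dNs.append(4 * (ls[a][:, None] * dls[b] + ls[b][:, None] * dls[a]))
    return np.stack(Ns, axis=1), np.stack(dNs, axis=1)


def edge3_shape(points: np.ndarray):
    """Quadratic edge on [-1, 1]: N (nq, 3), dN/dxi (nq, 3)."""
    xi = np.asarray(points, dtype=float).reshape(-1)
    N = np.stack([0.5 * xi * (xi - 1), 0.5 * xi * (xi + 1), 1 - xi**2], axis=1)
    dN = np.stack([xi - 0.5, xi + 0.5, -2 * xi], axis=1)
    return N, dN


def tri_quadrature(degree: int = 4):
    """Symmetric Gauss rules on the reference triangle (area 1/2)."""
    if degree <= 2:
        # 3-point, degree 2
        pts = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
        w = np.full(3, 1 / 6)
    else:
        # 6-point, degree 4 (Dunavant)
        a, b = 0.445948490915965, 0.091576213509771
        pts = np.array([
            [a, a], [1 - 2 * a, a], [a, 1 - 2 * a],
            [b, b], [1 - 2 * b, b], [b, 1 - 2 * b],
        ])
        wa, wb = 0.223381589678011, 0.109951743655322
        w = np.array([wa, wa, wa, wb, wb, wb]) / 2.0
    return pts, w


def tet_quadrature(degree: int = 2):
    """Gauss rules on the reference tetrahedron (volume 1/6)."""
    if degree <= 1:
        return np.array([[0.25, 0.25, 0.25]]), np.array([1 / 6])
    a = (5.0 - np.sqrt(5.0)) / 20.0
    b = (5.0 + 3.0 * np.sqrt(5.0)) / 20.0
    pts = np.array([[a, a, a], [b, a, a], [a, b, a], [a, a, b]])
    w = np.full(4, 1 / 24)
    return pts, w


def gauss_1d(n: int = 3):
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


class SolidElement:
    """Precomputed reference-element data for a solid element family."""

    def __init__(self, dim: int):
        self.dim = dim
        if dim == 2:
            self.n_nodes = 6
            self.qp, self.qw = tri_quadrature(4)
            self.N, self.dN = tri6_shape(self.qp)
        elif dim == 3:
            self.n_nodes = 10
            self.qp, self.qw = tet_quadrature(2)
            self.N, self.dN = tet10_shape(self.qp)
        else:
            raise ValueError(f"dim must be 2 or 3, got {dim}")
        self.n_qp = len(self.qw)


class FacetElement:
    """Precomputed reference data for a boundary facet family."""

    def __init__(self, dim: int):
        self.dim = dim
        if dim == 2:
            self.n_nodes = 3
            self.qp, self.qw = gauss_1d(3)
            self.N, self.dN = edge3_shape(self.qp)   # dN: (nq, 3)
        elif dim == 3:
            self.n_nodes = 6
            self.qp, self.qw = tri_quadrature(4)
            self.N, self.dN = tri6_shape(self.qp)    # dN: (nq, 6, 2)
        else:
            raise ValueError(f"dim must be 2 or 3, got {dim}")
        self.n_qp = len(self.qw)
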