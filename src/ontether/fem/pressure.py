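"""Consistent follower pressure loads on boundary facet sets.

A positive pressure acts along the *inward* normal of the solid (the fluid
pushes on the wetted surface).  Facets are stored outward-oriented, so the
nodal load is ``f_a = -p * int N_a n_out da`` evaluated on the *deformed*
surface (follower load), together with the load-stiffness contribution that
keeps Newton quadratically convergent.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ..errors import MeshError
from .elements import FacetElement

__all__ = ["PressureLoad"]

_R90 = np.array([[0.0, 1.0], [-1.0, 0.0]])  # rot(t) = R90 @ t : outward for CCW


def _skew(v):
    """Batched cross-product matrices [v]_x for v (..., 3)."""
    z = np.zeros(v.shape[:-1])
    return np.stack([
        np.stack([z, -v[..., 2], v[..., 1]], axis=-1),
        np.stack([v[..., 2], z, -v[..., 0]], axis=-1),
        np.stack([-v[..., 1], v[..., 0], z], axis=-1),
    ], axis=-2)


class PressureLoad:
    """Follower pressure on one facet set (pressure in MPa)."""

    def __init__(self, mesh, facet_set: str, pressure_mpa: float):
        self.mesh = mesh
        self.dim = mesh.dim
        self.facets = mesh.facet_set(facet_set)
        self.name = facet_set
        self.p = float(pressure_mpa)
        self.fam = FacetElement(self.dim)
        if self.facets.shape[1] != self.fam.n_nodes:
            raise MeshError(f"facet set {facet_set!r} has wrong arity")
        d = self.dim
        self.fdof = (self.facets[:, :, None] * d
                     + np.arange(d)[None, None, :]).reshape(len(self.facets), -1)
        nfd = self.fam.n_nodes * d
        self._rows = np.repeat(self.fdof, nfd, axis=1).ravel()
        self._cols = np.tile(self.fdof, (1, nfd)).ravel()

    def force_and_stiffness(self, u: np.ndarray, scale: float = 1.0,
                            need_stiffness: bool = True):
        """External force vector and load stiffness dfext/du (both global)."""
        p = self.p * scale
        n_dof = self.mesh.n_nodes * self.dim
        f = np.zeros(n_dof)
        if p == 0.0 or len(self.facets) == 0:
            return f, (sp.csc_matrix((n_dof, n_dof)) if need_stiffness else None)
        x = (self.mesh.nodes + u.reshape(-1, self.dim))[self.facets]
        fam = self.fam
        if self.dim == 2:
            # t = dx/dxi (nf, nq, 2); n|t| = R90 t
            t = np.einsum("qa,fad->fqd", fam.dN, x)
            nvec = np.einsum("ij,fqj->fqi", _R90, t)
            fe = -p * np.einsum("qa,fqi,q->fai", fam.N, nvec, fam.qw)
            np.add.at(f, self.fdof, fe.reshape(len(fe), -1))
            if not need_stiffness:
                return f, None
            # dfa = -p int N_a R90 dN_b dxi du_b
            coef = -p * np.einsum("qa,qb,q->ab", fam.N, fam.dN, fam.qw)
            Ke = np.einsum("ab,ik->aibk", coef, _R90)
            Ke = np.broadcast_to(Ke, (len(self.facets),) + Ke.shape)
        else:
            xu = np.einsum("qad,fae->fqde", fam.dN, x)    # (nf, nq, 2, 3)
            t1, t2 = xu[:, :, 0], xu[:, :, 1]
            nvec = np.cross(t1, t2)                       # n da / dxi deta
            fe = -p * np.einsum("qa,fqi,q->fai", fam.N, nvec, fam.qw)
            np.add.at(f, self.fdof, fe.reshape(len(fe), -1))
            if not need_stiffness:
                return f, None
            # d(t1 x t2) = [t1]x dN2_b du_b - [t2]x dN1_b du_b
            sk1 = _skew(t1)
            sk2 = _skew(t2)
            Ke = -p * (np.einsum("qa,fqik,qb,q->faibk", fam.N, sk1,
                                 fam.dN[:, :, 1], fam.qw)
                       - np.einsum("qa,fqik,qb,q->faibk", fam.N, sk2,
                                   fam.dN[:, :, 0], fam.qw))
        K = sp.coo_matrix(
            (np.ascontiguousarray(Ke).reshape(len(self.facets), -1).ravel(),
             (self._rows, self._cols)),
            shape=(n_dof, n_dof),
        ).tocsc()
        return f, K

    def current_area(self, u: np.ndarray) -> float:
        """Deformed area (length in 2-D) of the facet set."""
        x = (self.mesh.nodes + u.reshape(-1, self.dim))[self.facets]
        fam = self.fam
        if self.dim == 2:
            t = np.einsum("qa,fad->fqd", fam.dN, x)
            return float(np.einsum("fq,q->", np.linalg.norm(t, axis=-1), fam.qw))
        xu = np.einsum("qad,fae->fqde", fam.dN, x)
        nvec = np.cross(xu[:, :, 0], xu[:, :, 1])
        return float(np.einsum("fq,q->", np.linalg.norm(nvec, axis=-1), fam.qw))
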