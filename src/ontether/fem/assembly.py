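"""Total-Lagrangian assembly of residual and consistent tangent.

The weak form is assembled over quadratic elements with the second
Piola-Kirchhoff stress ``S`` and material tangent ``CC = 2 dS/dC`` from the
constitutive module:

    f_int[a,i] = sum_qp w  F_iI S_IJ dN_a/dX_J
    K[a,i,b,k] = sum_qp w ( (F dN_a)_J CC_IJKL? -- material part
                            + delta_ik dN_a . S . dN_b )    -- geometric part

In 2-D the mesh lives in the horizontal symmetry plane under a plane-strain
contract: the out-of-plane stretch is 1 and out-of-plane rows of F vanish,
so only in-plane blocks of S and CC enter.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from ..constitutive import as_reduced_polynomial, _stress_tangent_batch
from ..errors import MeshError
from .elements import SolidElement

__all__ = ["FemModel"]


class FemModel:
    """Precomputed assembly data for a mesh + material assignment.

    Parameters
    ----------
    mesh : RegionTaggedMesh
    materials : mapping region name -> material card.  Every region present
        in the mesh must be covered.
    """

    def __init__(self, mesh, materials):
        self.mesh = mesh
        self.dim = mesh.dim
        self.fam = SolidElement(self.dim)
        X = mesh.nodes[mesh.elements]                     # (ne, nen, dim)
        J0 = np.einsum("qad,ean->eqnd", self.fam.dN, X)   # dx/dxi
        det = np.linalg.det(J0)
        if np.any(det <= 0):
            raise MeshError("mesh contains elements with non-positive Jacobian")
        J0inv = np.linalg.inv(J0)
        # dN_a/dX_J at each (e, q): (ne, nq, nen, dim)
        self.dNdX = np.einsum("qan,eqnd->eqad", self.fam.dN, J0inv)
        self.wdet = det * self.fam.qw[None, :]            # (ne, nq)
        self.n_dof = mesh.n_nodes * self.dim
        # per-region element groups
        self.groups = []
        present = np.unique(mesh.region_ids)
        for rid in present:
            name = mesh.region_names[rid]
            if name not in materials:
                raise MeshError(f"no material assigned to region {name!r}")
            card = as_reduced_polynomial(materials[name])
            self.groups.append((np.flatnonzero(mesh.region_ids == rid), card))
        # element dof map (ne, nen*dim)
        nen = self.fam.n_nodes
        self.edof = (mesh.elements[:, :, None] * self.dim
                     + np.arange(self.dim)[None, None, :]).reshape(-1, nen * self.dim)
        rows = np.repeat(self.edof, nen * self.dim, axis=1).ravel()
        cols = np.tile(self.edof, (1, nen * self.dim)).ravel()
        self._rows, self._cols = rows, cols

    # ------------------------------------------------------------------
    def deformation_gradients(self, u: np.ndarray) -> np.ndarray:
        """F at every quadrature point, embedded 3x3: (ne, nq, 3, 3)."""
        ue = u.reshape(-1, self.dim)[self.mesh.elements]  # (ne, nen, dim)
        G = np.einsum("eai,eqaj->eqij", ue, self.dNdX)    # du/dX in-plane
        ne, nq = G.shape[:2]
        F = np.broadcast_to(np.eye(3), (ne, nq, 3, 3)).copy()
        F[..., : self.dim, : self.dim] += G
        return F

    def stress_state(self, u: np.ndarray):
        """(F, S) at quadrature points for the current displacement."""
        F = self.deformation_gradients(u)
        S = np.empty_like(F)
        for eids, card in self.groups:
            S[eids], _ = _stress_tangent_batch(card, F[eids],
                                               need_tangent=False)
        return F, S

    def internal_force_and_tangent(self, u: np.ndarray, need_tangent=True):
        """Internal nodal force vector and (optionally) tangent matrix."""
        d = self.dim
        F = self.deformation_gradients(u)
        S = np.empty_like(F)
        CC = np.empty(F.shape[:2] + (3, 3, 3, 3)) if need_tangent else None
        for eids, card in self.groups:
            Sg, Cg = _stress_tangent_batch(card, F[eids],
                                           need_tangent=need_tangent)
            S[eids] = Sg
            if need_tangent:
                CC[eids] = Cg

        Fd = F[..., :d, :d]
        Sd = S[..., :d, :d]
        fe = np.einsum("eqiI,eqIJ,eqaJ,eq->eai", Fd, Sd, self.dNdX, self.wdet)
        f = np.zeros(self.n_dof)
        np.add.at(f, self.edof.reshape(len(fe), -1),
                  fe.reshape(len(fe), -1))
        if not need_tangent:
            return f, None

        Cd = CC[..., :d, :d, :d, :d]
        A = np.einsum("eqiI,eqIJKL,eqkK->eqiJkL", Fd, Cd, Fd)
        Ke = np.einsum("eqaJ,eqiJkL,eqbL,eq->eaibk", self.dNdX, A,
                       self.dNdX, self.wdet)
        geo = np.einsum("eqaJ,eqJL,eqbL,eq->eab", self.dNdX, Sd,
                        self.dNdX, self.wdet)
        Ke += np.einsum("eab,ik->eaibk", geo, np.eye(d))
        nen = self.fam.n_nodes
        K = sp.coo_matrix(
            (Ke.reshape(len(Ke), -1).ravel(), (self._rows, self._cols)),
            shape=(self.n_dof, self.n_dof),
        ).tocsc()
        return f, K

    # convenience for tests -------------------------------------------------
    def quadrature_cauchy(self, u: np.ndarray) -> np.ndarray:
        """Cauchy stress (3x3) at every quadrature point."""
        F, S = self.stress_state(u)
        J = np.linalg.det(F)
        return np.einsum("eqiI,eqIJ,eqkJ->eqik", F, S, F) / J[..., None, None]
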