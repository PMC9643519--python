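"""Boundary conditions: fixed apex, symmetry/slider planes, prescribed
adduction rotation of the anterior globe, and pressure loads (mmHg)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import MeshError
from ..units import mmhg_to_mpa

__all__ = ["adduction_rotation_matrix", "prescribe_adduction",
           "BoundaryConditionSet"]


def adduction_rotation_matrix(angle_rad: float, dim: int = 3) -> np.ndarray:
    """Rotation that adducts the eye by ``angle_rad``.

    The rotation is about the +y (superior) axis through the globe centre,
    with the sense that carries the cornea (anterior, -z) nasally (+x).  In
    2-D the (x, z) in-plane block is returned.
    """
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    R = np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
    if dim == 2:
        return R[np.ix_([0, 2], [0, 2])]
    return R


def prescribe_adduction(mesh, angle_rad: float,
                        node_set: str = "anterior_rotation_set",
                        center=None):
    """Target displacements rotating a node set rigidly about the globe
    centre.  Returns (node_ids, displacement array (n, dim))."""
    if node_set not in mesh.node_sets:
        raise MeshError(f"mesh has no node set {node_set!r}")
    ids = mesh.node_sets[node_set]
    X = mesh.nodes[ids]
    c = np.zeros(mesh.dim) if center is None else np.asarray(center, float)
    R = adduction_rotation_matrix(angle_rad, mesh.dim)
    return ids, (X - c) @ R.T + c - X


@dataclass
class BoundaryConditionSet:
    """Declarative boundary conditions for one load case.

    Parameters
    ----------
    fixed_sets : node-set names whose nodes are fully fixed (orbital apex).
    rotation_set : node set receiving the rigid adduction rotation.
    adduction_rad : total further adduction angle (radians).
    pressures_mmhg : facet-set name -> pressure (mmHg); follower loads.
    slider_sets : node-set name -> unit-normal provider; nodes may slide in
        the plane (or cone) orthogonal to the given normal (zero normal
        displacement), used for symmetry planes and benchmark sectors.
        The provider maps node coordinates (n, dim) -> normals (n, dim).
    """

    fixed_sets: tuple = ("apex_fixed_set",)
    rotation_set: str = "anterior_rotation_set"
    adduction_rad: float = 0.0
    rotation_center: tuple = None
    pressures_mmhg: dict = field(default_factory=dict)
    slider_sets: dict = field(default_factory=dict)
    #: optional (z_globe, z_apex) range over which the solver's
    #: rigid-rotation predictor tapers from full rotation to zero (the ON
    #: tilts about the fixed apex rather than rotating with the globe)
    predictor_axial_range: tuple = None

    # ------------------------------------------------------------------
    def validate(self, mesh):
        for name in self.fixed_sets:
            if name not in mesh.node_sets:
                raise MeshError(f"mesh has no node set {name!r}")
        if self.adduction_rad != 0.0 and self.rotation_set not in mesh.node_sets:
            raise MeshError(f"mesh has no node set {self.rotation_set!r}")
        for name in self.pressures_mmhg:
            mesh.facet_set(name)
        if self.adduction_rad != 0.0:
            rot = set(mesh.node_sets[self.rotation_set].tolist())
            for name in self.fixed_sets:
                if rot & set(mesh.node_sets[name].tolist()):
                    raise MeshError(
                        f"rotation set and fixed set {name!r} overlap"
                    )
        return self

    def frames(self, mesh) -> np.ndarray | None:
        """Per-node orthonormal frames; first local axis = constrained
        normal on slider nodes.  None if every frame is the identity."""
        if not self.slider_sets:
            return None
        d = mesh.dim
        T = np.broadcast_to(np.eye(d), (mesh.n_nodes, d, d)).copy()
        for name, normal_fn in self.slider_sets.items():
            if name not in mesh.node_sets:
                raise MeshError(f"mesh has no node set {name!r}")
            ids = mesh.node_sets[name]
            n = np.asarray(normal_fn(mesh.nodes[ids]), dtype=float)
            n = n / np.linalg.norm(n, axis=1, keepdims=True)
            # build an orthonormal basis with n as first column
            for i, nid in enumerate(ids):
                B = np.eye(d)
                B[:, 0] = n[i]
                q, _ = np.linalg.qr(B)
                # keep the first axis aligned with +n
                if np.dot(q[:, 0], n[i]) < 0:
                    q[:, 0] *= -1
                    q[:, 1] *= -1
                T[nid] = q
        return T

    def constrained_mask(self, mesh) -> np.ndarray:
        """(n_nodes, dim) bool mask of constrained dofs in nodal frames."""
        d = mesh.dim
        mask = np.zeros((mesh.n_nodes, d), dtype=bool)
        for name in self.fixed_sets:
            mask[mesh.node_sets[name]] = True
        if self.adduction_rad != 0.0:
            mask[mesh.node_sets[self.rotation_set]] = True
        for name in self.slider_sets:
            mask[mesh.node_sets[name], 0] = True
        return mask

    def prescribed_values(self, mesh, load_factor: float) -> np.ndarray:
        """(n_nodes, dim) prescribed displacements in *global* frame at a
        given fraction of the final adduction angle (sliders stay zero)."""
        vals = np.zeros((mesh.n_nodes, mesh.dim))
        if self.adduction_rad != 0.0:
            ids, disp = prescribe_adduction(
                mesh, self.adduction_rad * load_factor, self.rotation_set,
                self.rotation_center)
            vals[ids] = disp
        return vals

    def pressure_loads(self, mesh):
        """List of (facet set name, pressure in MPa)."""
        return [(name, mmhg_to_mpa(p))
                for name, p in self.pressures_mmhg.items() if p != 0.0]
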