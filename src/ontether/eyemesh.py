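"""Region-tagged meshes of the eye / optic-nerve complex.

Two modes:

* ``2d`` -- the horizontal symmetry-plane cross section (plane-strain
  contract), meshed with quadratic triangles.  The full ring of the scleral
  shell, the lamina cribrosa plugging the canal, the tapered ON wall
  (homogenized connective+neural material), and the two sheath strips are
  built as conforming mapped blocks.
* ``3d`` -- the hemi-symmetric solid (y >= 0), generated by revolving the
  x >= 0 half section about the ON axis and splitting the resulting
  (possibly axis-degenerate) hexahedra into quadratic tetrahedra.  The ON
  interior is partitioned into prismatic connective / neural columns whose
  cross-sectional area fractions realise the configured 9:16 ratio.

Mesh density is controlled by a :class:`MeshDensity`: a fine target edge
length around the optic nerve head (canal, LC, sheath attachment) and a
coarse one for the remaining shell, with geometric grading along the ON.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import GeometryError, MeshError
from .geometry import OcularGeometry, build_geometry
from .meshing import (
    RegionTaggedMesh,
    boundary_facets,
    build_linear_blocks,
    elevate_to_quadratic,
    hexes_to_tets,
    merge_duplicate_nodes,
)

__all__ = ["MeshDensity", "generate_mesh"]

_GOLDEN = 0.6180339887498949


@dataclass(frozen=True)
class MeshDensity:
    """Target element sizes (mm) and structural counts."""

    fine: float = 0.22          # edge length near the optic nerve head
    coarse: float = 1.2         # far-field scleral arc length
    axial_max: float = 3.0      # max row height along the ON / sheath
    growth: float = 1.35        # geometric grading ratio
    radial_layers: int = 5      # through-thickness layers of the shell
    revolve_sectors: int = 8    # 3-D: sectors over the half revolve

    def validate(self, geometry: OcularGeometry) -> "MeshDensity":
        if min(self.fine, self.coarse, self.axial_max) <= 0:
            raise MeshError("edge lengths must be positive")
        if self.growth < 1.0:
            raise MeshError("growth ratio must be >= 1")
        c = geometry.config
        ratio = self.radial_layers * c.lc_thickness / c.scleral_thickness_canal
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise MeshError(
                "radial_layers must place the LC boundaries on shell layer "
                f"interfaces: layers*lc_thickness/canal_thickness = {ratio}")
        return self

    def scaled(self, factor: float) -> "MeshDensity":
        """Uniformly refined (factor < 1) or coarsened copy."""
        return replace(self, fine=self.fine * factor,
                       coarse=self.coarse * factor,
                       axial_max=self.axial_max * factor,
                       revolve_sectors=max(4, int(round(
                           self.revolve_sectors / factor))))


def _as_density(density) -> MeshDensity:
    if density is None:
        return MeshDensity()
    if isinstance(density, MeshDensity):
        return density
    if isinstance(density, (int, float)):
        return MeshDensity().scaled(float(density))
    if isinstance(density, dict):
        return MeshDensity(**density)
    raise MeshError(f"cannot interpret mesh density {density!r}")


def _graded(length: float, h0: float, h1: float, ratio: float) -> np.ndarray:
    """Monotone point set on [0, length]: spacing h0 growing to h1."""
    pts = [0.0]
    h = h0
    while pts[-1] + 1.5 * h < length:
        pts.append(pts[-1] + h)
        h = min(h * ratio, h1)
    pts.append(length)
    return np.asarray(pts)


def _nseg(arc: float, h: float, nmin: int = 2) -> int:
    return max(nmin, int(math.ceil(arc / h)))


# ---------------------------------------------------------------------------
# section blocks (2-D cross section; also the generator for the revolve)
# ---------------------------------------------------------------------------

def _ring_phis(g: OcularGeometry, d: MeshDensity, half: bool) -> np.ndarray:
    """Arc-node angles of the scleral ring, from the nasal canal rim."""
    R = g.R
    a1, a2, a3, a4, ap = (g.alpha_canal, g.alpha_on, g.alpha_sheath_in,
                          g.alpha_sheath_out, g.alpha_peri)
    segs = [
        (a1, a2, _nseg(R * (a2 - a1), d.fine)),
        (a2, a3, _nseg(R * (a3 - a2), d.fine)),
        (a3, a4, _nseg(R * (a4 - a3), d.fine)),
        (a4, ap, _nseg(R * (ap - a4), d.fine)),
    ]
    end = math.pi if half else 2.0 * math.pi - ap
    segs.append((ap, end, _nseg(R * (end - ap), d.coarse, nmin=8)))
    if not half:
        segs += [(end, 2 * math.pi - a4, _nseg(R * (ap - a4), d.fine)),
                 (2 * math.pi - a4, 2 * math.pi - a3,
                  _nseg(R * (a4 - a3), d.fine)),
                 (2 * math.pi - a3, 2 * math.pi - a2,
                  _nseg(R * (a3 - a2), d.fine)),
                 (2 * math.pi - a2, 2 * math.pi - a1,
                  _nseg(R * (a2 - a1), d.fine))]
    phis = [segs[0][0]]
    for p0, p1, n in segs:
        phis.extend(np.linspace(p0, p1, n + 1)[1:])
    return np.asarray(phis)


def _ring_block(g: OcularGeometry, d: MeshDensity, half: bool):
    # 2-D keeps the tilted-pole (nasal/temporal-asymmetric) thickness; the
    # revolved 3-D surrogate uses the axisymmetric profile
    phis = _ring_phis(g, d, half)
    nr = d.radial_layers
    dirs = np.stack([np.sin(phis), np.zeros_like(phis), np.cos(phis)], axis=1)
    t = g.shell_thickness(dirs, tilted_pole=not half)
    fr = np.arange(nr + 1) / nr
    r = g.R - t[:, None] * (1.0 - fr[None, :])          # (nphi, nr+1)
    verts = np.stack([r * np.sin(phis)[:, None],
                      r * np.cos(phis)[:, None]], axis=-1).reshape(-1, 2)
    ni, nk = len(phis), nr + 1
    idx = np.arange(ni * nk).reshape(ni, nk)
    quads = np.stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(),
                      idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()], axis=1)
    mid_phi = 0.5 * (phis[:-1] + phis[1:])
    mdirs = np.stack([np.sin(mid_phi), np.zeros_like(mid_phi),
                      np.cos(mid_phi)], axis=1)
    zones = np.atleast_1d(g.scleral_zone(mdirs))
    labels = np.repeat(zones, nr)  # quads are (i-major, k-minor) ordered
    return verts, quads, labels, phis


def _lc_levels(g: OcularGeometry, d: MeshDensity):
    c = g.config
    nr = d.radial_layers
    t_can = c.scleral_thickness_canal
    levels = g.R - t_can * (1.0 - np.arange(nr + 1) / nr)
    n_lc = int(round(nr * c.lc_thickness / t_can))
    return levels, n_lc


def _cap_blocks(g: OcularGeometry, d: MeshDensity, half: bool):
    """LC cap and the retro-LC ON band inside the canal."""
    a1 = g.alpha_canal
    arc = g.R * a1 * (1.0 if half else 2.0)
    m1 = _nseg(arc, d.fine, nmin=2 if half else 4)
    phis = np.linspace(0.0 if half else -a1, a1, m1 + 1)
    levels, n_lc = _lc_levels(g, d)

    def grid(rlev):
        v = np.stack([rlev[None, :] * np.sin(phis)[:, None],
                      rlev[None, :] * np.cos(phis)[:, None]], axis=-1)
        ni, nk = v.shape[:2]
        idx = np.arange(ni * nk).reshape(ni, nk)
        quads = np.stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(),
                          idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()], axis=1)
        return v.reshape(-1, 2), quads, ni - 1, nk - 1

    lc_v, lc_q, _, _ = grid(levels[: n_lc + 1])
    band_v, band_q, na, nkb = grid(levels[n_lc:])
    # arc-column index of each band quad (i-major ordering)
    band_cols = np.repeat(np.arange(na), nkb)
    return (lc_v, lc_q), (band_v, band_q, band_cols), phis, m1


def _on_block(g: OcularGeometry, d: MeshDensity, half: bool, cap_phis):
    """Tapered ON wall between the posterior globe and the apex plane."""
    a1, a2 = g.alpha_canal, g.alpha_on
    n_att = _nseg(g.R * (a2 - a1), d.fine)
    att = np.linspace(a1, a2, n_att + 1)
    if half:
        phi_a = np.concatenate([cap_phis, att[1:]])
    else:
        phi_a = np.concatenate([-att[::-1], cap_phis[1:], att[1:]])
    s_a = np.sin(phi_a) / math.sin(a2)
    P0 = g.R * np.stack([np.sin(phi_a), np.cos(phi_a)], axis=1)
    P1 = np.stack([g.w_posterior * s_a,
                   np.full_like(s_a, g.apex_z)], axis=1)
    length = float(np.linalg.norm(P1[0] - P0[0]))
    vrows = _graded(length, d.fine, d.axial_max, d.growth) / length
    verts = ((1.0 - vrows[None, :, None]) * P0[:, None, :]
             + vrows[None, :, None] * P1[:, None, :])
    ni, nj = verts.shape[:2]
    idx = np.arange(ni * nj).reshape(ni, nj)
    quads = np.stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(),
                      idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()], axis=1)
    cols = np.repeat(np.arange(ni - 1), nj - 1)
    return verts.reshape(-1, 2), quads, cols, phi_a


def _sheath_block(g: OcularGeometry, d: MeshDensity, mirror: bool):
    c = g.config
    a3, a4 = g.alpha_sheath_in, g.alpha_sheath_out
    n_t = _nseg(g.R * (a4 - a3), d.fine)
    phis = np.linspace(a3, a4, n_t + 1)
    s = (phis - a3) / (a4 - a3)
    Q0 = g.R * np.stack([np.sin(phis), np.cos(phis)], axis=1)
    Q1 = np.stack([g.w_posterior + c.csf_thickness + c.sheath_thickness * s,
                   np.full_like(s, g.apex_z)], axis=1)
    length = float(np.linalg.norm(Q1[0] - Q0[0]))
    vrows = _graded(length, d.fine, d.axial_max, d.growth) / length
    verts = ((1.0 - vrows[None, :, None]) * Q0[:, None, :]
             + vrows[None, :, None] * Q1[:, None, :])
    if mirror:
        verts = verts.copy()
        verts[..., 0] *= -1.0
    ni, nj = verts.shape[:2]
    idx = np.arange(ni * nj).reshape(ni, nj)
    quads = np.stack([idx[:-1, :-1].ravel(), idx[1:, :-1].ravel(),
                      idx[1:, 1:].ravel(), idx[:-1, 1:].ravel()], axis=1)
    return verts.reshape(-1, 2), quads


# ---------------------------------------------------------------------------
# facet and node sets
# ---------------------------------------------------------------------------

def _assign_sets(mesh: RegionTaggedMesh, g: OcularGeometry):
    """Named facet sets and node sets on an eye mesh (either mode)."""
    c = g.config
    dim = mesh.dim
    facets, parents = boundary_facets(mesh.elements, dim)
    mid = mesh.nodes[facets].mean(axis=1)
    if dim == 2:
        x, z = mid[:, 0], mid[:, 1]
        y = np.zeros_like(x)
    else:
        x, y, z = mid[:, 0], mid[:, 1], mid[:, 2]
    rho = np.abs(x) if dim == 2 else np.hypot(x, y)
    r = np.hypot(rho, z)
    off_sym = np.abs(y) > 1e-9 if dim == 3 else np.ones_like(r, dtype=bool)
    preg = np.asarray([mesh.region_name(e) for e in parents])
    on_like = np.isin(preg, ("on_homogenized", "on_connective", "on_neural"))
    sclera = np.char.endswith(preg.astype(str), "sclera")
    zlim = g.apex_z - 1e-6
    wtol = 0.12

    inner = off_sym & (r < g.R - 0.5 * c.scleral_thickness_canal)
    on_wall = (off_sym & on_like & (z < zlim) & (r > g.R - 0.05)
               & (np.abs(rho - g.on_half_width(np.maximum(z, g.z_on_edge)))
                  < wtol))
    sh_wall = (off_sym & (preg == "on_sheath") & (z < zlim)
               & (np.abs(rho - g.sheath_inner_radius(np.maximum(z, g.z_sheath_in)))
                  < wtol))
    ang = np.arccos(np.clip(z / np.maximum(r, 1e-12), -1, 1))
    cap = (off_sym & sclera & (np.abs(r - g.R) < 0.02)
           & (ang > g.alpha_on - 1e-3) & (ang < g.alpha_sheath_in + 1e-3))

    mesh.facet_sets["inner_scleral_surface"] = facets[inner]
    mesh.facet_sets["csf_inner_surface"] = facets[on_wall]
    mesh.facet_sets["csf_outer_surface"] = facets[sh_wall]
    mesh.facet_sets["csf_scleral_cap"] = facets[cap]

    X = mesh.nodes
    zs = X[:, 1] if dim == 2 else X[:, 2]
    mesh.node_sets["apex_fixed_set"] = np.flatnonzero(zs > g.apex_z - 1e-6)
    ant = mesh.elements_in_region("anterior_sclera")
    mesh.node_sets["anterior_rotation_set"] = np.unique(
        mesh.elements[ant].ravel())
    if dim == 2:
        mesh.node_sets["symmetry_plane"] = np.arange(mesh.n_nodes)
    else:
        mesh.node_sets["symmetry_plane"] = np.flatnonzero(
            np.abs(X[:, 1]) < 1e-9)
    for name in ("inner_scleral_surface", "csf_inner_surface",
                 "csf_outer_surface", "csf_scleral_cap"):
        if len(mesh.facet_sets[name]) == 0:
            raise MeshError(f"facet set {name!r} came out empty")
    return mesh


# ---------------------------------------------------------------------------
# honeycomb partition (3-D)
# ---------------------------------------------------------------------------

def _honeycomb_select(col_weights: np.ndarray, n_sectors: int,
                      neural_fraction: float) -> np.ndarray:
    """Deterministic neural/connective split of prismatic ON columns.

    ``col_weights[a]`` is the cross-sectional weight of section column
    ``a``; each column appears once per revolve sector with equal weight.
    Columns are visited in golden-ratio (low-discrepancy) order so neural
    channels are intermixed through the cross section; cells are marked
    neural until the target area fraction is reached.  Returns a boolean
    (n_cols, n_sectors) mask.
    """
    ncol = len(col_weights)
    ids = np.arange(ncol * n_sectors)
    order = np.argsort((_GOLDEN * (ids + 1)) % 1.0, kind="stable")
    w = np.repeat(col_weights / n_sectors, n_sectors)
    target = neural_fraction * w.sum()
    mask = np.zeros(ncol * n_sectors, dtype=bool)
    acc = 0.0
    for i in order:
        # bounded greedy: take the cell only if that lands closer to the
        # target fraction than skipping it
        if abs(acc + w[i] - target) <= abs(acc - target):
            mask[i] = True
            acc += w[i]
    return mask.reshape(ncol, n_sectors)


# ---------------------------------------------------------------------------
# public entry point
# ---------------------------------------------------------------------------

def generate_mesh(geometry: OcularGeometry = None, density=None,
                  mode: str = "2d") -> RegionTaggedMesh:
    """Build the region-tagged quadratic mesh of the eye-ON complex."""
    g = geometry or build_geometry()
    d = _as_density(density).validate(g)
    if mode not in ("2d", "3d"):
        raise MeshError(f"mode must be '2d' or '3d', got {mode!r}")
    mesh = _generate_2d(g, d) if mode == "2d" else _generate_3d(g, d)
    return _assign_sets(mesh, g).validate()


def _generate_2d(g: OcularGeometry, d: MeshDensity) -> RegionTaggedMesh:
    ring_v, ring_q, ring_lab, _ = _ring_block(g, d, half=False)
    (lc_v, lc_q), (band_v, band_q, _), cap_phis, _ = _cap_blocks(
        g, d, half=False)
    on_v, on_q, _, _ = _on_block(g, d, half=False, cap_phis=cap_phis)
    shn_v, shn_q = _sheath_block(g, d, mirror=False)
    sht_v, sht_q = _sheath_block(g, d, mirror=True)
    blocks = [
        (ring_v, ring_q, ring_lab),
        (lc_v, lc_q, "lamina_cribrosa"),
        (band_v, band_q, "on_homogenized"),
        (on_v, on_q, "on_homogenized"),
        (shn_v, shn_q, "on_sheath"),
        (sht_v, sht_q, "on_sheath"),
    ]
    nodes, tris, rid, names = build_linear_blocks(blocks, dim=2)
    nodes, conn = elevate_to_quadratic(nodes, tris, 2)
    return RegionTaggedMesh(dim=2, nodes=nodes, elements=conn,
                            region_ids=rid, region_names=names)


def _generate_3d(g: OcularGeometry, d: MeshDensity) -> RegionTaggedMesh:
    c = g.config
    ring_v, ring_q, _, _ = _ring_block(g, d, half=True)
    (lc_v, lc_q), (band_v, band_q, band_cols), cap_phis, m1 = _cap_blocks(
        g, d, half=True)
    on_v, on_q, on_cols, _ = _on_block(g, d, half=True, cap_phis=cap_phis)
    sh_v, sh_q = _sheath_block(g, d, mirror=False)

    # concatenate section blocks with metadata
    sec_v, sec_q = [], []
    kinds, cols = [], []
    offset = 0
    for verts, quads, kind, col in (
            (ring_v, ring_q, "ring", None),
            (lc_v, lc_q, "lc", None),
            (band_v, band_q, "on", band_cols),
            (on_v, on_q, "on", on_cols),
            (sh_v, sh_q, "sheath", None)):
        sec_v.append(verts)
        sec_q.append(np.asarray(quads) + offset)
        kinds.extend([kind] * len(quads))
        cols.extend(list(col) if col is not None
                    else [-1] * len(quads))
        offset += len(verts)
    sec_v = np.concatenate(sec_v, axis=0)
    sec_q = np.concatenate(sec_q, axis=0)
    kinds = np.asarray(kinds)
    cols = np.asarray(cols)

    # revolve the half section (x >= 0) about the ON axis through y >= 0
    nsec = d.revolve_sectors
    phr = np.linspace(0.0, math.pi, nsec + 1)
    nv = len(sec_v)
    xs, zs = sec_v[:, 0], sec_v[:, 1]
    nodes = np.concatenate([
        np.stack([xs * math.cos(p), xs * math.sin(p), zs], axis=1)
        for p in phr], axis=0)
    hexes = []
    hex_kind, hex_col, hex_sec = [], [], []
    for k in range(nsec):
        o0, o1 = k * nv, (k + 1) * nv
        h = np.concatenate([sec_q + o0, sec_q + o1], axis=1)
        hexes.append(h)
        hex_kind.append(kinds)
        hex_col.append(cols)
        hex_sec.append(np.full(len(sec_q), k))
    hexes = np.concatenate(hexes, axis=0)
    hex_kind = np.concatenate(hex_kind)
    hex_col = np.concatenate(hex_col)
    hex_sec = np.concatenate(hex_sec)

    nodes, hexes = merge_duplicate_nodes(nodes, hexes, tol=1e-6)

    # per-hex region labels
    labels = np.empty(len(hexes), dtype=object)
    labels[hex_kind == "lc"] = "lamina_cribrosa"
    labels[hex_kind == "sheath"] = "on_sheath"
    ring_sel = hex_kind == "ring"
    if ring_sel.any():
        cen = nodes[hexes[ring_sel]].mean(axis=1)
        labels[ring_sel] = np.atleast_1d(g.scleral_zone(cen))
    on_sel = hex_kind == "on"
    ncol = int(hex_col[on_sel].max()) + 1
    # section-column cross-sectional weights (revolved volume per Pappus)
    weights = np.zeros(ncol)
    v = sec_v[sec_q]

    def cross2(a, b):
        return a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]

    area = 0.5 * np.abs(
        cross2(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        + cross2(v[:, 2] - v[:, 0], v[:, 3] - v[:, 0]))
    xbar = v[..., 0].mean(axis=1)
    for q in np.flatnonzero(kinds == "on"):
        weights[cols[q]] += area[q] * max(xbar[q], 1e-6)
    neural = _honeycomb_select(weights, nsec,
                               1.0 - c.connective_fraction)
    sel_idx = np.flatnonzero(on_sel)
    labels[sel_idx] = np.where(
        neural[hex_col[sel_idx], hex_sec[sel_idx]],
        "on_neural", "on_connective")

    nodes, tets, parent = hexes_to_tets(nodes, hexes, tol=1e-6)
    tet_labels = labels[parent]
    names = tuple(dict.fromkeys(tet_labels))
    name_to_id = {n: i for i, n in enumerate(names)}
    rid = np.array([name_to_id[n] for n in tet_labels], dtype=np.int64)
    nodes, conn = elevate_to_quadratic(nodes, tets, 3)
    return RegionTaggedMesh(dim=3, nodes=nodes, elements=conn,
                            region_ids=rid, region_names=names)
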