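"""Scalar fields, landmark summaries, and lamina-cribrosa displacement.

Reporting conventions: stresses are von Mises equivalents of the Cauchy
stress converted to kPa; strains are the largest eigenvalue of the
logarithmic strain tensor in percent; lamina cribrosa (LC) edge
displacements are in micrometres with +nasal = +x and +posterior = +z.

Local values are quantified the way the study reports them: the mean over
a small patch (12-16 face-contiguous elements, default 14) of the region of
interest nearest a named landmark, each element carrying its
quadrature-point average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PostprocessError
from .fem.bcs import adduction_rotation_matrix
from .meshing import element_adjacency, element_centroids
from .units import FRACTION_TO_PERCENT, MM_TO_UM, MPA_TO_KPA

__all__ = [
    "von_mises",
    "principal_values",
    "max_principal_strain",
    "RegionSummaryRule",
    "region_summary",
    "element_von_mises",
    "element_max_principal_strain",
    "LCDisplacement",
    "lc_edge_displacement",
    "convergence_study",
]

_EYE3 = np.eye(3)


def _check_symmetric(t: np.ndarray):
    t = np.asarray(t, dtype=float)
    if t.shape[-2:] != (3, 3):
        raise PostprocessError(f"expected (..., 3, 3) tensor, got {t.shape}")
    scale = np.abs(t).max() + 1.0
    if np.abs(t - np.swapaxes(t, -1, -2)).max() > 1e-8 * scale:
        raise PostprocessError("tensor is not symmetric")
    return t


def von_mises(stress) -> np.ndarray:
    """Von Mises equivalent sqrt(3/2 dev(s):dev(s)), same units as input."""
    s = _check_symmetric(stress)
    dev = s - (np.trace(s, axis1=-2, axis2=-1) / 3.0)[..., None, None] * _EYE3
    vm = np.sqrt(1.5 * np.einsum("...ij,...ij", dev, dev))
    return vm if vm.ndim else float(vm)


def principal_values(tensor) -> np.ndarray:
    """Eigenvalues of a symmetric tensor in non-increasing order."""
    t = _check_symmetric(tensor)
    w = np.linalg.eigvalsh(t)
    return w[..., ::-1]


def max_principal_strain(strain) -> np.ndarray:
    """Largest eigenvalue of the (logarithmic) strain tensor."""
    out = principal_values(strain)[..., 0]
    return out if out.ndim else float(out)


def element_von_mises(solution) -> np.ndarray:
    """Per-element von Mises Cauchy stress (MPa), quadrature averaged."""
    return von_mises(solution.cauchy_stress_qp()).mean(axis=1)


def element_max_principal_strain(solution) -> np.ndarray:
    """Per-element max principal logarithmic strain, quadrature averaged."""
    return max_principal_strain(solution.log_strain_qp()).mean(axis=1)


# ---------------------------------------------------------------------------
# landmark region summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionSummaryRule:
    """Mean over k face-contiguous elements of a region near a landmark."""

    regions: tuple
    element_count: int = 14
    aggregation: str = "mean"

    def __post_init__(self):
        if not 12 <= self.element_count <= 16:
            raise PostprocessError(
                f"element_count must be 12..16, got {self.element_count}")
        if self.aggregation != "mean":
            raise PostprocessError("only mean aggregation is defined")


def select_patch(mesh, regions, landmark, k: int,
                 adjacency=None) -> np.ndarray:
    """Deterministic contiguous patch of k elements nearest a landmark.

    Grows from the nearest element of the allowed regions by face
    adjacency, always taking the adjacent candidate closest to the landmark
    (ties broken by element index).
    """
    allowed = mesh.elements_in_region(*regions)
    if len(allowed) < k:
        raise PostprocessError(
            f"region(s) {regions} have only {len(allowed)} elements; "
            f"{k} requested -- refine the mesh")
    lm = np.asarray(landmark, dtype=float)
    cen = element_centroids(mesh.nodes, mesh.elements)
    dist = np.linalg.norm(cen - lm, axis=1)
    if adjacency is None:
        adjacency = element_adjacency(mesh.elements, mesh.dim)
    allowed_set = set(allowed.tolist())
    start = allowed[np.lexsort((allowed, dist[allowed]))[0]]
    patch = [int(start)]
    in_patch = {int(start)}
    frontier = {e for e in adjacency[start] if e in allowed_set}
    while len(patch) < k:
        if not frontier:
            raise PostprocessError(
                f"contiguous patch near {lm.tolist()} exhausted at "
                f"{len(patch)} elements; refine the mesh")
        nxt = min(frontier, key=lambda e: (dist[e], e))
        frontier.discard(nxt)
        patch.append(nxt)
        in_patch.add(nxt)
        frontier |= {e for e in adjacency[nxt]
                     if e in allowed_set and e not in in_patch}
    return np.asarray(patch, dtype=np.int64)


def region_summary(mesh, element_values, rule: RegionSummaryRule, landmark,
                   adjacency=None) -> float:
    """Mean of a per-element scalar over the landmark patch."""
    vals = np.asarray(element_values, dtype=float)
    if len(vals) != mesh.n_elements:
        raise PostprocessError("one value per element required")
    patch = select_patch(mesh, rule.regions, landmark, rule.element_count,
                         adjacency)
    return float(vals[patch].mean())


# ---------------------------------------------------------------------------
# lamina cribrosa displacement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LCDisplacement:
    """Temporal LC edge displacement (um): +nasal and +posterior."""

    nasal_um: float
    posterior_um: float

    def as_tuple(self):
        return (self.nasal_um, self.posterior_um)


def lc_edge_displacement(solution, mesh, landmark,
                         rotation_compensation_rad: float = 0.0,
                         rotation_center=None) -> LCDisplacement:
    """Displacement of the LC-edge landmark node (Lagrangian tracking).

    By default the displacement is reported in the laboratory frame.  With
    ``rotation_compensation_rad`` set to the applied adduction angle, the
    deformed position is rotated back by that angle first, giving the
    globe-fixed (co-rotating) displacement -- the tether-induced shift of
    the LC relative to the rigidly rotating eye, which is the quantity the
    cross-section overlays and clinical imaging report.
    """
    lm = np.asarray(landmark, dtype=float)
    nid = int(np.argmin(np.linalg.norm(mesh.nodes - lm, axis=1)))
    X = mesh.nodes[nid]
    x = X + solution.displacements[nid]
    if rotation_compensation_rad:
        R = adduction_rotation_matrix(-rotation_compensation_rad, mesh.dim)
        c = (np.zeros(mesh.dim) if rotation_center is None
             else np.asarray(rotation_center, float))
        x = (x - c) @ R.T + c
    u = x - X
    nasal = float(u[0])
    posterior = float(u[-1])
    return LCDisplacement(nasal_um=nasal * MM_TO_UM,
                          posterior_um=posterior * MM_TO_UM)


# ---------------------------------------------------------------------------
# mesh-convergence study
# ---------------------------------------------------------------------------

def convergence_study(case, densities, config=None, library=None,
                      mode: str = "2d", schedule=None):
    """Solve one load case at several mesh densities.

    Returns a pandas DataFrame with one row per density: element count,
    mean and max von Mises stress (kPa) over all elements, and the relative
    change of each against the next-finer level.  The two finest levels are
    expected to agree within a few percent.
    """
    import pandas as pd

    from .scenarios import run_case  # deferred: avoids a module cycle

    seen = set()
    for d in densities:
        key = repr(d)
        if key in seen:
            raise PostprocessError(f"duplicate density {d!r}")
        seen.add(key)
    if len(densities) < 2:
        raise PostprocessError("need at least two densities")

    from .meshing import element_volumes

    rows = []
    for d in densities:
        try:
            bundle = run_case(case, config=config, library=library,
                              density=d, mode=mode, schedule=schedule,
                              keep_solution=True)
            vm = bundle.element_stress_kpa
            vol = element_volumes(bundle.mesh.nodes, bundle.mesh.elements,
                                  bundle.mesh.dim)
            # volume-weighted mean: independent of how elements subdivide
            rows.append({"density": repr(d),
                         "n_elements": int(len(vm)),
                         "mean_von_mises_kpa": float(np.average(vm,
                                                                weights=vol)),
                         "max_von_mises_kpa": float(np.max(vm)),
                         "error": ""})
        except Exception as exc:  # per-row failure reporting
            rows.append({"density": repr(d), "n_elements": 0,
                         "mean_von_mises_kpa": np.nan,
                         "max_von_mises_kpa": np.nan,
                         "error": str(exc)})
    df = pd.DataFrame(rows).sort_values("n_elements").reset_index(drop=True)
    for col in ("mean_von_mises_kpa", "max_von_mises_kpa"):
        ref = df[col].shift(-1)
        df[f"rel_change_{col[:4]}"] = np.abs(df[col] - ref) / np.abs(ref)
    return df
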