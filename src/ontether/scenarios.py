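"""The experiment grid: average case, sensitivity matrix, pressure and
ON-stiffness scenarios.

Each scenario solves the 6 deg incremental-adduction problem (beyond the
26 deg tethering threshold taken as the stress-free reference) under the
case's regional stiffness levels and pressures, and reduces the fields to
the reported quantities: von Mises stress (kPa) and maximum principal
logarithmic strain (%) at the temporal optic-disc / ON junction, temporal
peripapillary sclera, sheath-sclera junction, retrolaminar ON, and mid
sheath, plus the temporal LC edge displacement (um, globe-fixed frame).

All runs of one grid share a single mesh; only material cards and loads
differ, so comparisons across cases are controlled.  The pipeline is
deterministic: rerunning a grid reproduces summaries bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cases import CaseSpec, SENSITIVITY_CASES, make_case_materials
from .constitutive import MaterialLibrary, load_material_library
from .errors import OntetherError, SolverError
from .eyemesh import generate_mesh
from .fem import BoundaryConditionSet, FemModel, SolveSchedule, solve
from .geometry import OcularGeometry, OcularGeometryConfig, build_geometry
from .meshing import element_adjacency
from .postprocess import (
    LCDisplacement,
    RegionSummaryRule,
    element_max_principal_strain,
    element_von_mises,
    lc_edge_displacement,
    region_summary,
)
from .units import FRACTION_TO_PERCENT, MPA_TO_KPA

__all__ = ["LoadCase", "ResultsBundle", "run_case", "run_matrix",
           "run_pressure_scenarios", "run_on_stiffness_variants",
           "results_table", "SUMMARY_SPECS", "DEFAULT_MATRIX_LABELS",
           "EXTREME_IOP_MMHG", "EXTREME_ICP_MMHG"]

#: normal and extreme (high-IOP / low-ICP) pressure conditions, mmHg
NORMAL_IOP_MMHG = 15.0
NORMAL_ICP_MMHG = 10.0
EXTREME_IOP_MMHG = 40.0
EXTREME_ICP_MMHG = 4.0

DEFAULT_MATRIX_LABELS = ("average",) + tuple(SENSITIVITY_CASES)

_ON_REGIONS = ("on_homogenized", "on_connective", "on_neural")

#: summary name -> (allowed regions, geometry landmark key)
SUMMARY_SPECS = {
    "on_junction_temporal": (("lamina_cribrosa",) + _ON_REGIONS,
                             "on_junction_temporal"),
    "on_junction_nasal": (("lamina_cribrosa",) + _ON_REGIONS,
                          "on_junction_nasal"),
    "peripapillary_temporal": (("peripapillary_sclera",),
                               "peripapillary_temporal"),
    "sheath_sclera_junction": (("on_sheath",), "sheath_junction_temporal"),
    "retrolaminar_neural": (_ON_REGIONS, "retrolaminar_on"),
    "on_sheath": (("on_sheath",), "mid_sheath_temporal"),
}


@dataclass(frozen=True)
class LoadCase:
    """A complete scenario: stiffness case, pressures, adduction."""

    case: CaseSpec = field(default_factory=CaseSpec)
    iop_mmhg: float = NORMAL_IOP_MMHG
    icp_mmhg: float = NORMAL_ICP_MMHG
    adduction_deg: float = 6.0
    tethering: bool = True

    def __post_init__(self):
        if self.iop_mmhg < 0 or self.icp_mmhg < 0:
            raise OntetherError("pressures must be non-negative")
        if self.adduction_deg < 0:
            raise OntetherError("adduction increment must be non-negative")

    @property
    def label(self) -> str:
        tag = self.case.label
        if not self.tethering:
            tag += "-no_tether"
        if (self.iop_mmhg, self.icp_mmhg) != (NORMAL_IOP_MMHG,
                                              NORMAL_ICP_MMHG):
            tag += f"-iop{self.iop_mmhg:g}-icp{self.icp_mmhg:g}"
        return tag

    @classmethod
    def from_label(cls, label: str, **kw) -> "LoadCase":
        return cls(case=CaseSpec.from_label(label), **kw)


@dataclass
class ResultsBundle:
    """Reduced results of one scenario run."""

    case_label: str
    stress_kpa: dict               # summary name -> von Mises (kPa)
    strain_pct: dict               # summary name -> principal strain (%)
    lc_displacement: LCDisplacement  # globe-fixed frame (tether-induced)
    lc_displacement_lab: LCDisplacement
    element_stress_kpa: np.ndarray
    element_strain_pct: np.ndarray
    solution: object = None
    mesh: object = None

    def to_row(self) -> dict:
        row = {"case_label": self.case_label}
        for name, v in self.stress_kpa.items():
            row[f"stress_kpa[{name}]"] = v
        for name, v in self.strain_pct.items():
            row[f"strain_pct[{name}]"] = v
        row["lc_nasal_um"] = self.lc_displacement.nasal_um
        row["lc_posterior_um"] = self.lc_displacement.posterior_um
        return row


def _default_schedule() -> SolveSchedule:
    return SolveSchedule()


@dataclass
class _Workbench:
    """Shared geometry/mesh/adjacency for a grid of runs."""

    geometry: OcularGeometry
    mesh: object
    mode: str
    library: MaterialLibrary
    adjacency: list

    @classmethod
    def build(cls, config=None, library=None, mesh=None, density=None,
              mode="2d"):
        if isinstance(config, OcularGeometryConfig) or config is None:
            geometry = build_geometry(config)
        elif isinstance(config, OcularGeometry):
            geometry = config
        else:
            raise OntetherError(f"cannot interpret config {config!r}")
        if mesh is None:
            mesh = generate_mesh(geometry, density=density, mode=mode)
        library = library or load_material_library()
        return cls(geometry=geometry, mesh=mesh, mode=mode, library=library,
                   adjacency=element_adjacency(mesh.elements, mesh.dim))


#: Membrane-equivalence factor for cavity pressures in the plane-strain
#: cross-section mode.  A ring of radius R and thickness t under pressure p
#: carries hoop stress pR/t, twice the pR/(2t) of the sphere it represents;
#: halving the section pressure reproduces the spherical membrane stress
#: state (at which the published percentile cards were operating).
PLANE_STRAIN_PRESSURE_FACTOR = 0.5


def _boundary_conditions(bench: _Workbench, load: LoadCase):
    g = bench.geometry
    adduction = math.radians(load.adduction_deg) if load.tethering else 0.0
    fac = PLANE_STRAIN_PRESSURE_FACTOR if bench.mode == "2d" else 1.0
    pressures = {
        "inner_scleral_surface": fac * load.iop_mmhg,
        "csf_inner_surface": fac * load.icp_mmhg,
        "csf_scleral_cap": fac * load.icp_mmhg,
    }
    # The sheath wall carries its CSF pressure by hoop stress in the real
    # tube; a plane-strain strip has no hoop path and would balloon, so the
    # sheath-side wall load is applied only in 3-D mode.
    if bench.mode == "3d":
        pressures["csf_outer_surface"] = load.icp_mmhg
    return BoundaryConditionSet(
        fixed_sets=("apex_fixed_set",),
        rotation_set="anterior_rotation_set",
        adduction_rad=adduction,
        pressures_mmhg=pressures,
        predictor_axial_range=(g.z_on_edge, g.apex_z),
    )


def _reduce(bench: _Workbench, load: LoadCase, solution,
            keep_solution: bool) -> ResultsBundle:
    g, mesh = bench.geometry, bench.mesh
    landmarks = g.landmarks()
    vm_kpa = element_von_mises(solution) * MPA_TO_KPA
    eps_pct = element_max_principal_strain(solution) * FRACTION_TO_PERCENT
    stress, strain = {}, {}
    for name, (regions, lm_key) in SUMMARY_SPECS.items():
        rule = RegionSummaryRule(regions=regions)
        lm = landmarks[lm_key]
        if mesh.dim == 3:
            lm = np.array([lm[0], 0.0, lm[1]])
        stress[name] = region_summary(mesh, vm_kpa, rule, lm, bench.adjacency)
        strain[name] = region_summary(mesh, eps_pct, rule, lm,
                                      bench.adjacency)
    lm = landmarks["lc_temporal_edge"]
    if mesh.dim == 3:
        lm = np.array([lm[0], 0.0, lm[1]])
    ang = math.radians(load.adduction_deg) if load.tethering else 0.0
    lc_rel = lc_edge_displacement(solution, mesh, lm,
                                  rotation_compensation_rad=ang)
    lc_lab = lc_edge_displacement(solution, mesh, lm)
    return ResultsBundle(
        case_label=load.label,
        stress_kpa=stress,
        strain_pct=strain,
        lc_displacement=lc_rel,
        lc_displacement_lab=lc_lab,
        element_stress_kpa=vm_kpa,
        element_strain_pct=eps_pct,
        solution=solution if keep_solution else None,
        mesh=mesh if keep_solution else None,
    )


def run_case(load: LoadCase, config=None, library=None, mesh=None,
             density=None, mode: str = "2d", schedule: SolveSchedule = None,
             keep_solution: bool = False,
             _bench: "_Workbench" = None) -> ResultsBundle:
    """Solve one scenario and reduce it to the reported summaries."""
    if isinstance(load, CaseSpec):
        load = LoadCase(case=load)
    bench = _bench or _Workbench.build(config, library, mesh, density, mode)
    mats = make_case_materials(load.case, bench.library, bench.mode,
                               bench.geometry.config.connective_fraction)
    model = FemModel(bench.mesh, mats)
    bcs = _boundary_conditions(bench, load)
    try:
        solution = solve(model, bcs, schedule or _default_schedule())
    except SolverError as exc:
        raise SolverError(f"case {load.label!r}: {exc}",
                          convergence_log=exc.convergence_log) from exc
    return _reduce(bench, load, solution, keep_solution)


def run_matrix(cases=None, config=None, library=None, density=None,
               mode: str = "2d", schedule: SolveSchedule = None,
               iop_mmhg: float = NORMAL_IOP_MMHG,
               icp_mmhg: float = NORMAL_ICP_MMHG) -> dict:
    """Run a list of case labels / LoadCases on one shared mesh.

    Returns label -> ResultsBundle (or the exception for a failed case;
    failures do not abort the rest of the matrix).
    """
    if cases is None:
        cases = DEFAULT_MATRIX_LABELS
    loads = []
    for c in cases:
        if isinstance(c, LoadCase):
            loads.append(c)
        elif isinstance(c, CaseSpec):
            loads.append(LoadCase(case=c))
        else:
            loads.append(LoadCase.from_label(c, iop_mmhg=iop_mmhg,
                                             icp_mmhg=icp_mmhg))
    labels = [ld.label for ld in loads]
    if len(set(labels)) != len(labels):
        raise OntetherError(f"duplicate case labels in matrix: {labels}")
    bench = _Workbench.build(config, library, None, density, mode)
    out = {}
    for ld in loads:
        try:
            out[ld.label] = run_case(ld, schedule=schedule, _bench=bench)
        except OntetherError as exc:
            out[ld.label] = exc
    return out


def run_pressure_scenarios(case="average", config=None, library=None,
                           density=None, mode: str = "2d",
                           schedule: SolveSchedule = None) -> dict:
    """{no-rotation, rotation} x {normal, extreme} pressure scenarios.

    Keys: ``tether_normal``, ``tether_extreme``, ``pressure_only_normal``,
    ``pressure_only_extreme``.
    """
    spec = case if isinstance(case, CaseSpec) else CaseSpec.from_label(case)
    bench = _Workbench.build(config, library, None, density, mode)
    grid = {
        "pressure_only_normal": LoadCase(spec, NORMAL_IOP_MMHG,
                                         NORMAL_ICP_MMHG, tethering=False),
        "pressure_only_extreme": LoadCase(spec, EXTREME_IOP_MMHG,
                                          EXTREME_ICP_MMHG, tethering=False),
        "tether_normal": LoadCase(spec, NORMAL_IOP_MMHG, NORMAL_ICP_MMHG),
        "tether_extreme": LoadCase(spec, EXTREME_IOP_MMHG, EXTREME_ICP_MMHG),
    }
    return {k: run_case(ld, schedule=schedule, _bench=bench)
            for k, ld in grid.items()}


def run_on_stiffness_variants(base_case="B", config=None, library=None,
                              density=None, mode: str = "2d",
                              schedule: SolveSchedule = None,
                              include_extreme_pressure: bool = False) -> dict:
    """ON connective tissue compliant / average / stiff on the base case.

    The default base is the least favorable sensitivity combination
    (case B: stiff posterior and peripapillary sclera, compliant sheath).
    """
    spec = (base_case if isinstance(base_case, CaseSpec)
            else CaseSpec.from_label(base_case))
    bench = _Workbench.build(config, library, None, density, mode)
    out = {}
    for level in ("compliant", "average", "stiff"):
        out[level] = run_case(LoadCase(spec.with_on(level)),
                              schedule=schedule, _bench=bench)
    if include_extreme_pressure:
        out["stiff_extreme_pressure"] = run_case(
            LoadCase(spec.with_on("stiff"), EXTREME_IOP_MMHG,
                     EXTREME_ICP_MMHG),
            schedule=schedule, _bench=bench)
    return out


def results_table(bundles: dict) -> pd.DataFrame:
    """Long-form summary table (one row per case and reporting region)."""
    rows = []
    for key, b in bundles.items():
        if isinstance(b, Exception):
            rows.append({"run": key, "case_label": "", "region": "",
                         "stress_kpa": np.nan, "strain_pct": np.nan,
                         "lc_nasal_um": np.nan, "lc_posterior_um": np.nan,
                         "error": str(b)})
            continue
        for name in b.stress_kpa:
            rows.append({
                "run": key,
                "case_label": b.case_label,
                "region": name,
                "stress_kpa": b.stress_kpa[name],
                "strain_pct": b.strain_pct[name],
                "lc_nasal_um": b.lc_displacement.nasal_um,
                "lc_posterior_um": b.lc_displacement.posterior_um,
                "error": "",
            })
    return pd.DataFrame(rows)
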