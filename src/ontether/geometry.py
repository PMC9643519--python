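"""Parametric geometry of the adducted eye / optic-nerve complex.

The reference (stress-free) configuration is the 26 deg-adducted pose in
which the optic nerve (ON) has just straightened: the ON runs along the +z
axis from the posterior globe to the orbital apex.  Coordinate frame:
origin at the globe centre, +z posterior (toward the apex), +x nasal,
+y superior (the hemi-symmetry normal).  All lengths in mm, angles stored
in degrees and used in radians internally.

Solids: spherical scleral shell (thickness graded from the equator to the
posterior pole and thinned around the scleral canal), lamina cribrosa (LC)
as a spherical cap plugging the canal, tapered ON, ON sheath tube anchored
to the peripapillary sclera, and the cerebrospinal-fluid (CSF) gap between
ON and sheath, which is represented by its two wetted surfaces rather than
meshed (it only transmits the intracranial pressure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np
import yaml

from .errors import ClassificationError, GeometryError

__all__ = ["OcularGeometryConfig", "OcularGeometry", "build_geometry",
           "classify_region"]


@dataclass
class OcularGeometryConfig:
    """Printed anatomical dimensions of the average adducted eye (mm, deg)."""

    globe_diameter: float = 24.0
    scleral_thickness_equator: float = 0.4
    scleral_thickness_posterior_pole: float = 1.0
    #: thinned shell thickness at the scleral-canal rim (profile is not
    #: printed; exposed here) and the width of the thinning annulus.
    scleral_thickness_canal: float = 0.5
    canal_taper_width: float = 1.0
    peripapillary_radius: float = 4.0
    lc_diameter: float = 1.8
    lc_thickness: float = 0.3
    on_diameter_anterior: float = 4.0
    on_diameter_posterior: float = 3.5
    sheath_thickness: float = 0.74
    csf_thickness: float = 0.59
    apex_distance: float = 41.0
    apex_axis_to_medial_wall_angle: float = 22.0
    angle_kappa: float = 5.0
    fovea_disc_angle: float = 17.0
    initial_adduction: float = 26.0
    #: connective : neural cross-sectional ratio of the ON interior.
    on_connective_neural_ratio: tuple = (9, 16)
    #: polar-angle bounds (deg, from the corneal pole) of the anterior and
    #: equatorial scleral zones; the paper names the zones without bounds.
    anterior_zone_angle: float = 60.0
    equatorial_zone_angle: float = 120.0

    # ------------------------------------------------------------------
    @property
    def globe_radius(self) -> float:
        return self.globe_diameter / 2.0

    @property
    def connective_fraction(self) -> float:
        a, b = self.on_connective_neural_ratio
        return a / (a + b)

    def validate(self) -> "OcularGeometryConfig":
        for name in ("globe_diameter", "scleral_thickness_equator",
                     "scleral_thickness_posterior_pole",
                     "scleral_thickness_canal", "canal_taper_width",
                     "peripapillary_radius", "lc_diameter", "lc_thickness",
                     "on_diameter_anterior", "on_diameter_posterior",
                     "sheath_thickness", "csf_thickness", "apex_distance"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.lc_diameter >= self.on_diameter_anterior:
            raise GeometryError("lc_diameter must be smaller than the "
                                "anterior ON diameter")
        if self.lc_thickness >= self.scleral_thickness_canal:
            raise GeometryError("LC thicker than the scleral canal shell")
        if self.apex_distance <= self.globe_radius + 2.0:
            raise GeometryError("apex too close to the globe for a "
                                "straight, slack-free ON path")
        if self.on_diameter_posterior > self.on_diameter_anterior:
            raise GeometryError("ON must taper from the globe to the apex")
        return self

    # -- YAML round trip ------------------------------------------------
    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["on_connective_neural_ratio"] = list(self.on_connective_neural_ratio)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "OcularGeometryConfig":
        if isinstance(source, str) and "\n" in source:
            data = yaml.safe_load(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        if "on_connective_neural_ratio" in data:
            data["on_connective_neural_ratio"] = tuple(
                data["on_connective_neural_ratio"])
        return cls(**data).validate()


class OcularGeometry:
    """Derived geometric quantities and region predicates.

    Built by :func:`build_geometry`; consumed by the mesh generators, the
    region classifier, and the post-processing landmarks.
    """

    def __init__(self, config: OcularGeometryConfig):
        self.config = config.validate()
        c = self.config
        R = c.globe_radius
        self.R = R
        self.apex_z = c.apex_distance
        self.w_anterior = c.on_diameter_anterior / 2.0
        self.w_posterior = c.on_diameter_posterior / 2.0

        # polar half-angles (from the +z disc axis) of the canal, the ON
        # edge, and the sheath attachment band on the scleral surface
        self.alpha_canal = math.asin(c.lc_diameter / 2.0 / R)
        self.alpha_on = math.asin(self.w_anterior / R)
        self.alpha_sheath_in = math.asin((self.w_anterior + c.csf_thickness) / R)
        self.alpha_sheath_out = math.asin(
            (self.w_anterior + c.csf_thickness + c.sheath_thickness) / R)
        self.alpha_peri = c.peripapillary_radius / R  # geodesic
        if self.alpha_sheath_out >= self.alpha_peri:
            raise GeometryError(
                "sheath attachment band extends beyond the peripapillary "
                "annulus; enlarge peripapillary_radius or shrink the sheath")

        # z of the anterior attachment circles on the sphere
        self.z_on_edge = R * math.cos(self.alpha_on)
        self.z_sheath_in = R * math.cos(self.alpha_sheath_in)
        self.z_sheath_out = R * math.cos(self.alpha_sheath_out)

        # LC radial band: inner surface flush with the thinned canal shell
        self.r_lc_inner = R - c.scleral_thickness_canal
        self.r_lc_outer = self.r_lc_inner + c.lc_thickness

        # corneal (geometric) pole: tilted temporally from the -z axis by
        # (fovea-disc angle - angle kappa) so the disc sits nasal to the
        # posterior pole
        delta = math.radians(c.fovea_disc_angle - c.angle_kappa)
        self.pole_tilt = delta
        self.corneal_pole = np.array(
            [math.sin(delta), 0.0, -math.cos(delta)])

    # -- scalar profile functions ---------------------------------------
    def on_half_width(self, z) -> np.ndarray:
        """ON half-width (mm) at axial position z, linear taper."""
        z = np.asarray(z, dtype=float)
        s = (z - self.z_on_edge) / (self.apex_z - self.z_on_edge)
        return self.w_anterior + (self.w_posterior - self.w_anterior) * s

    def sheath_inner_radius(self, z) -> np.ndarray:
        c = self.config
        z = np.asarray(z, dtype=float)
        s = (z - self.z_sheath_in) / (self.apex_z - self.z_sheath_in)
        r0 = self.w_anterior + c.csf_thickness
        r1 = self.w_posterior + c.csf_thickness
        return r0 + (r1 - r0) * s

    def sheath_outer_radius(self, z) -> np.ndarray:
        c = self.config
        z = np.asarray(z, dtype=float)
        s = (z - self.z_sheath_out) / (self.apex_z - self.z_sheath_out)
        r0 = self.w_anterior + c.csf_thickness + c.sheath_thickness
        r1 = self.w_posterior + c.csf_thickness + c.sheath_thickness
        return r0 + (r1 - r0) * s

    def polar_angle_from_pole(self, direction: np.ndarray,
                              tilted: bool = True) -> np.ndarray:
        """Angle (rad) between surface directions and the corneal pole."""
        d = np.asarray(direction, dtype=float)
        d = d / np.maximum(np.linalg.norm(d, axis=-1, keepdims=True), 1e-300)
        pole = self.corneal_pole if tilted else np.array([0.0, 0.0, -1.0])
        return np.arccos(np.clip(d @ pole, -1.0, 1.0))

    def shell_thickness(self, direction: np.ndarray,
                        tilted_pole: bool = True) -> np.ndarray:
        """Scleral thickness along a surface direction (3-vector(s))."""
        c = self.config
        psi = self.polar_angle_from_pole(direction, tilted_pole)
        t_eq, t_pole = c.scleral_thickness_equator, c.scleral_thickness_posterior_pole
        base = np.where(
            psi <= math.pi / 2.0, t_eq,
            t_eq + (t_pole - t_eq) * (psi - math.pi / 2.0) / (math.pi / 2.0))
        # thinning toward the canal over a geodesic annulus
        d = np.asarray(direction, dtype=float)
        d = d / np.maximum(np.linalg.norm(d, axis=-1, keepdims=True), 1e-300)
        ang_disc = np.arccos(np.clip(d[..., 2], -1.0, 1.0))
        dgeo = self.R * ang_disc
        d0 = self.R * self.alpha_canal
        w = c.canal_taper_width
        frac = np.clip((dgeo - d0) / w, 0.0, 1.0)
        t_canal = c.scleral_thickness_canal
        return np.where(dgeo < d0 + w,
                        t_canal + (base - t_canal) * frac, base)

    # -- zone classification --------------------------------------------
    def scleral_zone(self, direction: np.ndarray) -> np.ndarray:
        """anterior / equatorial / posterior / peripapillary by direction."""
        d = np.atleast_2d(np.asarray(direction, dtype=float))
        d = d / np.maximum(np.linalg.norm(d, axis=-1, keepdims=True), 1e-300)
        psi = np.degrees(self.polar_angle_from_pole(d))
        ang_disc = np.arccos(np.clip(d[..., 2], -1.0, 1.0))
        out = np.where(
            self.R * ang_disc < self.config.peripapillary_radius,
            "peripapillary_sclera",
            np.where(psi < self.config.anterior_zone_angle, "anterior_sclera",
                     np.where(psi < self.config.equatorial_zone_angle,
                              "equatorial_sclera", "posterior_sclera")))
        return out if out.shape != (1,) else out[0]

    # -- landmarks on the symmetry plane ---------------------------------
    def landmarks(self) -> dict:
        """Reference positions (x, z) of the reporting landmarks.

        Temporal is -x; all landmarks lie on the horizontal symmetry plane
        as in the figures: the LC temporal edge, the temporal and nasal
        optic-disc / ON junction, the temporal peripapillary sclera, the
        sheath-sclera junction, the retrolaminar ON, and the mid sheath.
        """
        r_lc = 0.5 * (self.r_lc_inner + self.r_lc_outer)
        a1 = self.alpha_canal
        sj = 0.5 * (self.alpha_sheath_in + self.alpha_sheath_out)
        peri = 0.5 * (self.alpha_sheath_out + self.alpha_peri)
        z_mid_sheath = 0.5 * (self.z_sheath_in + self.apex_z)
        return {
            "lc_temporal_edge": np.array([-r_lc * math.sin(a1),
                                          r_lc * math.cos(a1)]),
            "lc_nasal_edge": np.array([r_lc * math.sin(a1),
                                       r_lc * math.cos(a1)]),
            "on_junction_temporal": np.array([-self.r_lc_outer * math.sin(a1),
                                              self.r_lc_outer * math.cos(a1)]),
            "on_junction_nasal": np.array([self.r_lc_outer * math.sin(a1),
                                           self.r_lc_outer * math.cos(a1)]),
            "peripapillary_temporal": np.array([-self.R * math.sin(peri),
                                                self.R * math.cos(peri)]),
            "sheath_junction_temporal": np.array([-self.R * math.sin(sj),
                                                  self.R * math.cos(sj)]),
            "retrolaminar_on": np.array([0.0, self.r_lc_outer + 1.0]),
            "mid_sheath_temporal": np.array(
                [-float(self.sheath_inner_radius(z_mid_sheath))
                 - 0.5 * self.config.sheath_thickness, z_mid_sheath]),
        }


def build_geometry(config: OcularGeometryConfig = None) -> OcularGeometry:
    """Construct the parametric geometry (region predicates + dimensions)."""
    return OcularGeometry(config or OcularGeometryConfig())


# ---------------------------------------------------------------------------
# point classification
# ---------------------------------------------------------------------------

def _embed3(point) -> np.ndarray:
    p = np.asarray(point, dtype=float)
    if p.shape == (2,):
        return np.array([p[0], 0.0, p[1]])
    if p.shape == (3,):
        return p
    raise ClassificationError(f"point must be 2- or 3-vector, got {p.shape}")


def classify_region(point, geometry: OcularGeometry, tol: float = 1e-9) -> str:
    """Deterministic tissue-region label of a point inside the solid.

    2-D points are (x, z) on the symmetry plane.  The ON interior is
    reported as ``on_interior`` (the honeycomb split into connective and
    neural channels is a mesh-level assignment, not a point property).
    """
    g = geometry
    c = g.config
    p = _embed3(point)
    r = float(np.linalg.norm(p))
    z = p[2]
    rho = math.hypot(p[0], p[1])
    ang_disc = math.acos(max(-1.0, min(1.0, z / r))) if r > 0 else math.pi

    # sheath tube (including its spherical-cap anterior attachment zone)
    if g.z_sheath_out - tol <= z <= g.apex_z + tol and r >= g.R - tol:
        ri = float(g.sheath_inner_radius(z))
        ro = float(g.sheath_outer_radius(z))
        if ri - tol <= rho <= ro + tol and r >= g.R - tol:
            return "on_sheath"

    # ON (behind the globe surface, inside the tapered cylinder) and the
    # retro-LC tissue inside the scleral canal
    if z >= g.r_lc_outer - tol and rho <= float(g.on_half_width(max(z, g.z_on_edge))) + tol:
        if r >= g.R - tol and z <= g.apex_z + tol:
            return "on_interior"
        if ang_disc <= g.alpha_canal + tol and g.r_lc_outer - tol <= r <= g.R + tol:
            return "on_interior"

    # lamina cribrosa: spherical cap plugging the canal
    if ang_disc <= g.alpha_canal + tol and \
            g.r_lc_inner - tol <= r <= g.r_lc_outer + tol:
        return "lamina_cribrosa"

    # scleral shell
    if ang_disc >= g.alpha_canal - tol:
        t = float(g.shell_thickness(p / max(r, 1e-12)))
        if g.R - t - tol <= r <= g.R + tol:
            return str(g.scleral_zone(p / r))

    raise ClassificationError(
        f"point {np.asarray(point).tolist()} is outside the meshed solid")
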