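"""Regional hyperelastic constitutive models for ocular tissues.

The tissues of the posterior eye (sclera, lamina cribrosa, optic-nerve
connective tissue and sheath) are modelled with the isotropic
reduced-polynomial strain-energy family

    U = sum_i  C_i0 (I1bar - 3)^i  +  sum_i (1/D_i) (J - 1)^(2i),

where ``I1bar = J^(-2/3) tr(F^T F)`` is the first deviatoric invariant and
``J = det F`` the volume ratio.  The ``N = 1`` member is neo-Hookean with
shear modulus ``mu = 2 C10`` and bulk modulus ``kappa = 2 / D1``.  ON neural
tissue is linear elastic (published brain properties) and is also evaluated
through an equivalent neo-Hookean card so that every region shares one
finite-strain code path.

Cards for each region at the published compliant (5th percentile), average,
and stiff (95th percentile) levels are shipped with the package
(``data/material_cards.csv``) and loaded with :func:`load_material_library`.

Stress measures: second Piola-Kirchhoff stress ``S = 2 dU/dC`` with the
consistent material tangent ``CC = 2 dS/dC`` (minor symmetric), and the
Cauchy stress by push-forward ``sigma = F S F^T / J``.  Tissues whose card
has no volumetric coefficient are treated as nearly incompressible with a
penalty bulk modulus ``kappa = 1000 mu``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import (
    InvalidDeformationError,
    MaterialLookupError,
    MaterialParameterError,
    MixtureError,
)

__all__ = [
    "ReducedPolynomialParams",
    "LinearElasticParams",
    "DeformationState",
    "MixtureSpec",
    "MaterialLibrary",
    "strain_energy_density",
    "uniaxial_nominal_stress",
    "uniaxial_tangent_modulus",
    "pk2_stress",
    "cauchy_stress",
    "material_tangent",
    "connective_modulus_from_mixture",
    "homogenize_on_interior",
    "load_material_library",
    "REGIONS",
    "CONNECTIVE_NEURAL_AREA_FRACTION",
]

MAX_ORDER = 6

#: Tissue regions of the model, in library order.
REGIONS = (
    "anterior_sclera",
    "equatorial_sclera",
    "posterior_sclera",
    "peripapillary_sclera",
    "on_sheath",
    "lamina_cribrosa",
    "on_connective",
    "on_neural",
)

#: Connective-tissue area fraction of the ON interior, f = 9 / (9 + 16),
#: from the histologically observed 9:16 connective:neural area ratio.
CONNECTIVE_NEURAL_AREA_FRACTION = 9.0 / 25.0

#: Penalty bulk / shear ratio for cards without a volumetric coefficient.
PENALTY_KAPPA_OVER_MU = 1000.0


@dataclass(frozen=True)
class ReducedPolynomialParams:
    """One tissue's reduced-polynomial hyperelastic card.

    Parameters
    ----------
    deviatoric_coeffs :
        ``C_i0`` in MPa, ``i = 1..N`` with ``1 <= N <= 6``; ``C10 > 0``.
    volumetric_coeffs :
        ``D_i`` in 1/MPa; a zero entry means that volumetric term is absent.
        If every ``D_i`` is zero the material is treated as nearly
        incompressible with penalty bulk modulus ``1000 * mu``.
    label :
        Free-form region / stiffness tag used in error messages.
    """

    deviatoric_coeffs: tuple
    volumetric_coeffs: tuple
    label: str = ""
    #: optional monotonicity safeguard for use outside the fitted strain
    #: range: the deviatoric hardening dW/dI1bar is smoothly floored at
    #: ``hardening_floor * C10``.  Percentile polynomial fits can turn
    #: non-monotone when extrapolated beyond the tested strains (soft
    #: tissue itself stiffens monotonically); the floor leaves the response
    #: untouched wherever the polynomial hardening exceeds it.  0 disables.
    hardening_floor: float = 0.0

    def __post_init__(self):
        c = tuple(float(x) for x in self.deviatoric_coeffs)
        d = tuple(float(x) for x in self.volumetric_coeffs)
        if not 1 <= len(c) <= MAX_ORDER:
            raise MaterialParameterError(
                f"{self.label or 'card'}: order N={len(c)} outside 1..{MAX_ORDER}"
            )
        if len(d) != len(c):
            raise MaterialParameterError(
                f"{self.label or 'card'}: need one D_i per deviatoric term"
            )
        if c[0] <= 0.0:
            raise MaterialParameterError(
                f"{self.label or 'card'}: C10={c[0]} must be positive"
            )
        if any(x < 0.0 for x in d):
            raise MaterialParameterError(
                f"{self.label or 'card'}: D_i must be non-negative"
            )
        object.__setattr__(self, "deviatoric_coeffs", c)
        object.__setattr__(self, "volumetric_coeffs", d)

    @property
    def order(self) -> int:
        return len(self.deviatoric_coeffs)

    @property
    def c10(self) -> float:
        return self.deviatoric_coeffs[0]

    @property
    def shear_modulus(self) -> float:
        """Small-strain shear modulus mu = 2 C10 (MPa)."""
        return 2.0 * self.c10

    @property
    def bulk_modulus(self) -> float:
        """Small-strain bulk modulus: 2/D1 if given, else the penalty value."""
        d1 = self.volumetric_coeffs[0]
        if d1 > 0.0:
            return 2.0 / d1
        return PENALTY_KAPPA_OVER_MU * self.shear_modulus

    @property
    def youngs_modulus(self) -> float:
        """Small-strain Young's modulus from (mu, kappa)."""
        mu, k = self.shear_modulus, self.bulk_modulus
        return 9.0 * k * mu / (3.0 * k + mu)

    def with_hardening_floor(self, fraction: float) -> "ReducedPolynomialParams":
        """Copy of this card with the monotonicity safeguard enabled."""
        return ReducedPolynomialParams(
            self.deviatoric_coeffs, self.volumetric_coeffs, self.label,
            hardening_floor=float(fraction))


@dataclass(frozen=True)
class LinearElasticParams:
    """Linear-elastic card (ON neural tissue)."""

    youngs_modulus: float
    poisson_ratio: float
    label: str = ""

    def __post_init__(self):
        if self.youngs_modulus <= 0.0:
            raise MaterialParameterError(f"{self.label}: E must be positive")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise MaterialParameterError(f"{self.label}: need 0 <= nu < 0.5")

    @property
    def shear_modulus(self) -> float:
        return self.youngs_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def bulk_modulus(self) -> float:
        return self.youngs_modulus / (3.0 * (1.0 - 2.0 * self.poisson_ratio))

    def to_reduced_polynomial(self) -> ReducedPolynomialParams:
        """Equivalent neo-Hookean card: C10 = mu/2, D1 = 2/kappa."""
        return ReducedPolynomialParams(
            (self.shear_modulus / 2.0,),
            (2.0 / self.bulk_modulus,),
            label=self.label or "linear-elastic",
        )


def as_reduced_polynomial(params) -> ReducedPolynomialParams:
    """Coerce either card type to a reduced-polynomial card."""
    if isinstance(params, ReducedPolynomialParams):
        return params
    if isinstance(params, LinearElasticParams):
        return params.to_reduced_polynomial()
    raise MaterialParameterError(f"not a material card: {params!r}")


@dataclass(frozen=True)
class DeformationState:
    """A local deformation, characterised by the gradient F (3x3)."""

    deformation_gradient: np.ndarray

    def __post_init__(self):
        F = np.asarray(self.deformation_gradient, dtype=float)
        if F.shape != (3, 3):
            raise InvalidDeformationError(f"F must be 3x3, got {F.shape}")
        object.__setattr__(self, "deformation_gradient", F)
        if self.volume_ratio <= 0.0:
            raise InvalidDeformationError(
                f"non-positive volume ratio J={self.volume_ratio}"
            )

    @property
    def F(self) -> np.ndarray:
        return self.deformation_gradient

    @property
    def volume_ratio(self) -> float:
        """J = det F."""
        return float(np.linalg.det(self.deformation_gradient))

    @property
    def elastic_volume_ratio(self) -> float:
        """J^el; equal to J (no thermal or growth split in this model)."""
        return self.volume_ratio

    @property
    def deviatoric_first_invariant(self) -> float:
        """I1bar = J^(-2/3) tr(F^T F); >= 3, equal iff isochoric rigid."""
        F = self.deformation_gradient
        return float(self.volume_ratio ** (-2.0 / 3.0) * np.einsum("ij,ij", F, F))

    @classmethod
    def from_stretches(cls, l1: float, l2: float, l3: float) -> "DeformationState":
        return cls(np.diag([float(l1), float(l2), float(l3)]))

    @classmethod
    def uniaxial_incompressible(cls, stretch: float) -> "DeformationState":
        """Isochoric uniaxial stretch: F = diag(l, 1/sqrt(l), 1/sqrt(l))."""
        if stretch <= 0.0:
            raise InvalidDeformationError(f"stretch must be positive, got {stretch}")
        s = 1.0 / np.sqrt(stretch)
        return cls.from_stretches(stretch, s, s)


@dataclass(frozen=True)
class MixtureSpec:
    """Rule-of-mixtures description of the ON composite.

    ``f`` is the connective-tissue volume fraction
    ``V_connective / (V_connective + V_neural)``; the whole-ON tensile
    modulus ``E_ON`` and the neural modulus ``E_neural`` are in MPa.
    """

    whole_on_modulus: float
    neural_modulus: float
    connective_fraction: float = CONNECTIVE_NEURAL_AREA_FRACTION

    def __post_init__(self):
        if not 0.0 < self.connective_fraction <= 1.0:
            raise MixtureError(
                f"connective fraction f={self.connective_fraction} outside (0, 1]"
            )
        if self.whole_on_modulus <= 0.0 or self.neural_modulus <= 0.0:
            raise MixtureError("moduli must be positive")


# ---------------------------------------------------------------------------
# Batched kernel: second Piola-Kirchhoff stress and material tangent
# ---------------------------------------------------------------------------

_I3 = np.eye(3)


def _poly_coeffs(params: ReducedPolynomialParams):
    c = np.asarray(params.deviatoric_coeffs, dtype=float)
    d = np.asarray(params.volumetric_coeffs, dtype=float)
    penalty = None
    if not np.any(d > 0.0):
        penalty = PENALTY_KAPPA_OVER_MU * params.shear_modulus
    return c, d, penalty


def _volumetric(params: ReducedPolynomialParams, J: np.ndarray):
    """Volumetric energy and its first two J-derivatives (elementwise)."""
    c, d, penalty = _poly_coeffs(params)
    J = np.asarray(J, dtype=float)
    U = np.zeros_like(J)
    dU = np.zeros_like(J)
    d2U = np.zeros_like(J)
    if penalty is not None:
        # kappa/2 (J-1)^2 with kappa = 1000 mu
        U = 0.5 * penalty * (J - 1.0) ** 2
        dU = penalty * (J - 1.0)
        d2U = np.full_like(J, penalty)
        return U, dU, d2U
    x = J - 1.0
    for i, di in enumerate(d, start=1):
        if di <= 0.0:
            continue  # "-" entry: term absent
        U = U + x ** (2 * i) / di
        dU = dU + 2 * i * x ** (2 * i - 1) / di
        d2U = d2U + 2 * i * (2 * i - 1) * x ** (2 * i - 2) / di
    return U, dU, d2U


def _deviatoric_psi(params: ReducedPolynomialParams, x: np.ndarray):
    """W(x), W'(x), W''(x) for W = sum C_i0 x^i with x = I1bar - 3.

    With a positive ``hardening_floor`` the first derivative is replaced by
    a smooth maximum of the polynomial value and ``floor * C10`` (and W''
    by its consistent derivative); the energy itself is reported from the
    raw polynomial, which equilibrium never uses.
    """
    c, _, _ = _poly_coeffs(params)
    x = np.asarray(x, dtype=float)
    W = np.zeros_like(x)
    W1 = np.zeros_like(x)
    W2 = np.zeros_like(x)
    for i, ci in enumerate(c, start=1):
        W = W + ci * x**i
        W1 = W1 + i * ci * x ** (i - 1)
        if i >= 2:
            W2 = W2 + i * (i - 1) * ci * x ** (i - 2)
    if params.hardening_floor > 0.0:
        f = params.hardening_floor * c[0]
        eps = 0.05 * c[0]
        s = np.sqrt((W1 - f) ** 2 + eps**2)
        W2 = 0.5 * W2 * (1.0 + (W1 - f) / s)
        W1 = 0.5 * (W1 + f + s)
    return W, W1, W2


def _check_jacobians(J: np.ndarray, label: str):
    if np.any(J <= 0.0):
        raise InvalidDeformationError(
            f"{label or 'material'}: non-positive J encountered "
            f"(min J = {float(np.min(J)):.3e})"
        )


def pk2_stress_batch(params: ReducedPolynomialParams, F: np.ndarray) -> np.ndarray:
    """Second Piola-Kirchhoff stress for a batch of gradients F (..., 3, 3)."""
    S, _ = _stress_tangent_batch(params, F, need_tangent=False)
    return S


def _stress_tangent_batch(params: ReducedPolynomialParams, F: np.ndarray,
                          need_tangent: bool = True):
    F = np.asarray(F, dtype=float)
    C = np.einsum("...ki,...kj->...ij", F, F)
    J2 = np.linalg.det(C)
    _check_jacobians(J2, params.label)
    J = np.sqrt(J2)
    Cinv = np.linalg.inv(C)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    J23 = J ** (-2.0 / 3.0)
    I1b = J23 * I1
    x = I1b - 3.0

    _, W1, W2 = _deviatoric_psi(params, x)
    _, dU, d2U = _volumetric(params, J)

    # G = d I1bar / d C
    G = (J23[..., None, None] * _I3 - (I1b / 3.0)[..., None, None] * Cinv)
    S = 2.0 * W1[..., None, None] * G + (dU * J)[..., None, None] * Cinv

    if not need_tangent:
        return S, None

    IxCi = np.einsum("ij,...kl->...ijkl", _I3, Cinv)
    CixI = np.einsum("...ij,kl->...ijkl", Cinv, _I3)
    CixCi = np.einsum("...ij,...kl->...ijkl", Cinv, Cinv)
    CioCi = (np.einsum("...ik,...jl->...ijkl", Cinv, Cinv)
             + np.einsum("...il,...jk->...ijkl", Cinv, Cinv))
    GxG = np.einsum("...ij,...kl->...ijkl", G, G)

    w1 = W1[..., None, None, None, None]
    w2 = W2[..., None, None, None, None]
    j23 = J23[..., None, None, None, None]
    i1b = I1b[..., None, None, None, None]
    CC = (4.0 * w2 * GxG
          + 4.0 * w1 * (-(j23 / 3.0) * (IxCi + CixI)
                        + (i1b / 9.0) * CixCi
                        + (i1b / 6.0) * CioCi))
    du = (dU * J)[..., None, None, None, None]
    d2u = ((d2U * J + dU) * J)[..., None, None, None, None]
    CC = CC + d2u * CixCi - du * CioCi
    return S, CC


# ---------------------------------------------------------------------------
# Scalar (single-state) operations
# ---------------------------------------------------------------------------

def strain_energy_density(params, state: DeformationState) -> float:
    """Strain energy per unit reference volume U (MPa)."""
    p = as_reduced_polynomial(params)
    F = state.F
    J = state.volume_ratio
    x = state.deviatoric_first_invariant - 3.0
    W, _, _ = _deviatoric_psi(p, np.asarray(x))
    Uv, _, _ = _volumetric(p, np.asarray(J))
    return float(W + Uv)


def pk2_stress(params, state: DeformationState) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dU/dC (MPa, symmetric 3x3)."""
    p = as_reduced_polynomial(params)
    S, _ = _stress_tangent_batch(p, state.F[None], need_tangent=False)
    return S[0]


def cauchy_stress(params, state: DeformationState) -> np.ndarray:
    """Cauchy stress sigma = F S F^T / J (MPa, symmetric 3x3)."""
    p = as_reduced_polynomial(params)
    F = state.F
    S = pk2_stress(p, state)
    return F @ S @ F.T / state.volume_ratio


def material_tangent(params, state: DeformationState) -> np.ndarray:
    """Material tangent CC = 2 dS/dC (MPa, 3x3x3x3, minor symmetric).

    Relates increments of Green-Lagrange strain to increments of second
    Piola-Kirchhoff stress: dS = CC : dE.
    """
    p = as_reduced_polynomial(params)
    _, CC = _stress_tangent_batch(p, state.F[None], need_tangent=True)
    return CC[0]


def uniaxial_nominal_stress(params, stretch: float) -> float:
    """Nominal (first Piola-Kirchhoff) uniaxial stress on the incompressible
    path, P(l) = 2 (l - l^-2) dW/dI1bar with I1bar = l^2 + 2/l (MPa)."""
    p = as_reduced_polynomial(params)
    lam = float(stretch)
    if lam <= 0.0:
        raise InvalidDeformationError(f"stretch must be positive, got {lam}")
    x = lam**2 + 2.0 / lam - 3.0
    _, W1, _ = _deviatoric_psi(p, np.asarray(x))
    return float(2.0 * (lam - lam**-2) * W1)


def uniaxial_tangent_modulus(params, stretch: float, h: float = 1e-6) -> float:
    """dP/dl by central difference; at l = 1 this is the incompressible
    small-strain Young's modulus E = 6 C10 for a single-term card."""
    return (uniaxial_nominal_stress(params, stretch + h)
            - uniaxial_nominal_stress(params, stretch - h)) / (2.0 * h)


# ---------------------------------------------------------------------------
# Rule of mixtures and ON homogenization
# ---------------------------------------------------------------------------

def connective_modulus_from_mixture(spec: MixtureSpec) -> float:
    """Connective-tissue modulus from the general rule of mixtures.

    Inverts ``E_ON = f E_connective + (1 - f) E_neural`` for E_connective.
    """
    f = spec.connective_fraction
    e = (spec.whole_on_modulus - (1.0 - f) * spec.neural_modulus) / f
    if e <= 0.0:
        raise MixtureError(
            f"inconsistent mixture: E_connective={e:.4g} MPa not positive "
            f"(E_ON={spec.whole_on_modulus}, E_neural={spec.neural_modulus}, f={f})"
        )
    return e


def homogenize_on_interior(connective: ReducedPolynomialParams,
                           neural: LinearElasticParams,
                           connective_fraction: float = CONNECTIVE_NEURAL_AREA_FRACTION,
                           ) -> ReducedPolynomialParams:
    """Voigt (rule-of-mixtures) homogenization of the ON interior.

    Used by the 2-D cross-section model, where the honeycomb of connective
    matrix and neural channels is replaced by a single material with energy
    ``U = f U_connective + (1 - f) U_neural``; at small strain this
    reproduces the forward rule of mixtures for the moduli.
    """
    f = float(connective_fraction)
    if not 0.0 < f <= 1.0:
        raise MixtureError(f"connective fraction f={f} outside (0, 1]")
    nh = neural.to_reduced_polynomial()
    n = max(connective.order, 1)
    c = [f * ci for ci in connective.deviatoric_coeffs]
    c[0] += (1.0 - f) * nh.c10
    kappa = f * connective.bulk_modulus + (1.0 - f) * neural.bulk_modulus
    d = [0.0] * n
    d[0] = 2.0 / kappa
    return ReducedPolynomialParams(
        tuple(c), tuple(d),
        label=f"on_homogenized[{connective.label or 'connective'}]",
    )


# ---------------------------------------------------------------------------
# Material library
# ---------------------------------------------------------------------------

#: Stiffness levels published per region.
_EXPECTED_LEVELS = {
    "anterior_sclera": ("average",),
    "equatorial_sclera": ("average",),
    "posterior_sclera": ("average", "stiff", "compliant"),
    "peripapillary_sclera": ("average", "stiff", "compliant"),
    "on_sheath": ("average", "stiff", "compliant"),
    "lamina_cribrosa": ("average",),
    "on_connective": ("average", "stiff", "compliant"),
    "on_neural": ("average",),
}

#: Printed C30..C60 columns carry a x1e3 display scaling.
_SCALED_COLUMNS = ("C30", "C40", "C50", "C60")


@dataclass
class MaterialLibrary:
    """Mapping region -> stiffness level -> material card."""

    cards: dict = field(default_factory=dict)

    def get(self, region: str, level: str = "average"):
        try:
            by_level = self.cards[region]
        except KeyError:
            raise MaterialLookupError(
                f"unknown region {region!r}; known: {sorted(self.cards)}"
            ) from None
        try:
            return by_level[level]
        except KeyError:
            raise MaterialLookupError(
                f"region {region!r} has no {level!r} card; published levels: "
                f"{sorted(by_level)}"
            ) from None

    def levels(self, region: str):
        if region not in self.cards:
            raise MaterialLookupError(f"unknown region {region!r}")
        return tuple(sorted(self.cards[region]))

    @property
    def regions(self):
        return tuple(self.cards)

    def validate(self):
        for region, levels in _EXPECTED_LEVELS.items():
            for level in levels:
                card = self.get(region, level)
                if region == "on_neural":
                    if not isinstance(card, LinearElasticParams):
                        raise MaterialParameterError(
                            "on_neural must be linear elastic"
                        )
                elif not isinstance(card, ReducedPolynomialParams):
                    raise MaterialParameterError(
                        f"{region}/{level} must be reduced polynomial"
                    )
        return self


def _parse_float(cell: str):
    cell = (cell or "").strip()
    if cell in ("", "-", "--"):
        return None
    return float(cell)


def load_material_library(card_source=None) -> MaterialLibrary:
    """Load the regional material cards (packaged CSV by default).

    The ``C30..C60`` columns are stored with the printed x1e3 scaling and are
    rescaled to MPa here.  Dash / empty cells become absent terms.
    """
    if card_source is None:
        ref = resources.files("ontether").joinpath("data/material_cards.csv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(card_source).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    reader = csv.DictReader(lines)
    lib = MaterialLibrary()
    for row in reader:
        region = row["region"].strip()
        level = row["stiffness"].strip()
        model = row["model"].strip()
        label = f"{region}/{level}"
        if model == "linear_elastic":
            card = LinearElasticParams(
                youngs_modulus=_parse_float(row["E"]),
                poisson_ratio=_parse_float(row["nu"]),
                label=label,
            )
        elif model == "reduced_polynomial":
            c, d = [], []
            for i, col in enumerate(("C10", "C20", "C30", "C40", "C50", "C60")):
                v = _parse_float(row.get(col))
                if v is None:
                    continue
                if col in _SCALED_COLUMNS:
                    v *= 1e-3
                # keep trailing placement: pad skipped interior columns with 0
                while len(c) < i:
                    c.append(0.0)
                    d.append(0.0)
                c.append(v)
                d.append(0.0)
            d1 = _parse_float(row.get("D1"))
            if d1 is not None and d1 > 0.0:
                d[0] = d1
            card = ReducedPolynomialParams(tuple(c), tuple(d), label=label)
        else:
            raise MaterialParameterError(f"{label}: unknown model {model!r}")
        lib.cards.setdefault(region, {})[level] = card
    return lib.validate()
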