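"""Reduced-polynomial hyperelasticity: energies, stresses, tangents,
the rule of mixtures, and the packaged material library."""

import numpy as np
import pytest

from ontether.constitutive import (
    CONNECTIVE_NEURAL_AREA_FRACTION,
    DeformationState,
    LinearElasticParams,
    MixtureSpec,
    ReducedPolynomialParams,
    cauchy_stress,
    connective_modulus_from_mixture,
    homogenize_on_interior,
    load_material_library,
    material_tangent,
    pk2_stress,
    strain_energy_density,
    uniaxial_nominal_stress,
    uniaxial_tangent_modulus,
)
from ontether.errors import (
    InvalidDeformationError,
    MaterialLookupError,
    MaterialParameterError,
    MixtureError,
)

from conftest import all_polynomial_cards

NEO = ReducedPolynomialParams((0.5,), (0.0,), "neo-hookean")


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def random_state(rng, scale=0.05):
    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    return DeformationState(F)


class TestStrainEnergy:
    def test_zero_at_identity_for_every_card(self, library):
        st = DeformationState(np.eye(3))
        for card in all_polynomial_cards(library):
            assert strain_energy_density(card, st) == 0.0

    def test_single_term_uniaxial_hand_value(self):
        # C10 = 0.5 MPa, isochoric lam = 2: I1bar = 4 + 2/2 = 5, U = 0.5*2
        st = DeformationState.uniaxial_incompressible(2.0)
        assert strain_energy_density(NEO, st) == pytest.approx(1.0, rel=1e-12)

    def test_posterior_sclera_average_high_precision_oracle(self, library):
        # frozen value from an exact-rational polynomial evaluation of the
        # posterior-sclera average card on the isochoric uniaxial path
        card = library.get("posterior_sclera", "average")
        st = DeformationState.uniaxial_incompressible(1.05)
        assert strain_energy_density(card, st) == pytest.approx(
            0.0121906613248364100856, rel=1e-12)

    def test_invalid_deformation_rejected(self):
        with pytest.raises(InvalidDeformationError):
            DeformationState(np.diag([1.0, 1.0, -1.0]))

    def test_order_bounds_enforced(self):
        with pytest.raises(MaterialParameterError):
            ReducedPolynomialParams((0.1,) * 7, (0.0,) * 7)
        with pytest.raises(MaterialParameterError):
            ReducedPolynomialParams((-0.1,), (0.0,))
        with pytest.raises(MaterialParameterError):
            ReducedPolynomialParams((0.1,), (-1.0,))


class TestUniaxialStress:
    def test_stress_free_reference(self, library):
        for card in all_polynomial_cards(library):
            assert uniaxial_nominal_stress(card, 1.0) == 0.0

    def test_posterior_average_frozen_value(self, library):
        card = library.get("posterior_sclera", "average")
        assert uniaxial_nominal_stress(card, 1.05) == pytest.approx(
            0.77902573215103856, rel=1e-12)

    def test_matches_energy_derivative_every_card(self, library):
        # dU/dlam along the isochoric path, central difference
        h = 1e-6
        for card in all_polynomial_cards(library):
            for lam in (1.03, 1.10):
                up = strain_energy_density(
                    card, DeformationState.uniaxial_incompressible(lam + h))
                um = strain_energy_density(
                    card, DeformationState.uniaxial_incompressible(lam - h))
                assert uniaxial_nominal_stress(card, lam) == pytest.approx(
                    (up - um) / (2 * h), rel=1e-6)

    def test_small_strain_modulus_is_6_c10(self, library):
        for card in all_polynomial_cards(library):
            assert uniaxial_tangent_modulus(card, 1.0) == pytest.approx(
                6.0 * card.c10, rel=1e-6)

    def test_stiff_curve_above_compliant_in_fitted_range(self, library):
        for region in ("posterior_sclera", "peripapillary_sclera",
                       "on_sheath", "on_connective"):
            stiff = library.get(region, "stiff")
            soft = library.get(region, "compliant")
            for lam in np.linspace(1.02, 1.08, 13):
                assert uniaxial_nominal_stress(stiff, lam) > \
                    uniaxial_nominal_stress(soft, lam), (region, lam)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(InvalidDeformationError):
            uniaxial_nominal_stress(NEO, -1.0)


class TestStressAndTangent:
    def test_zero_stress_at_identity_and_under_rotation(self, library, rng):
        for card in all_polynomial_cards(library):
            s0 = cauchy_stress(card, DeformationState(np.eye(3)))
            assert np.abs(s0).max() == 0.0
            R = random_rotation(rng)
            sR = cauchy_stress(card, DeformationState(R))
            assert np.abs(sR).max() < 1e-12 * max(card.bulk_modulus, 1.0)

    def test_objectivity_of_energy(self, library, rng):
        st = random_state(rng)
        for card in all_polynomial_cards(library):
            u0 = strain_energy_density(card, st)
            for _ in range(3):
                R = random_rotation(rng)
                uR = strain_energy_density(
                    card, DeformationState(R @ st.F))
                assert uR == pytest.approx(u0, rel=1e-10, abs=1e-14)

    def test_stress_is_energy_gradient(self, library, rng):
        # first Piola from finite differences of U vs F S (rel tol 1e-5)
        h = 1e-6
        for card in all_polynomial_cards(library):
            st = random_state(rng, 0.03)
            S = pk2_stress(card, st)
            P = st.F @ S
            Pfd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = st.F.copy(), st.F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    Pfd[i, j] = (strain_energy_density(card, DeformationState(Fp))
                                 - strain_energy_density(card, DeformationState(Fm))
                                 ) / (2 * h)
            assert np.abs(P - Pfd).max() < 1e-5 * np.abs(P).max()

    def test_tangent_matches_stress_differences(self, library, rng):
        for card in all_polynomial_cards(library):
            st = random_state(rng, 0.03)
            CC = material_tangent(card, st)
            dF = 1e-6 * rng.standard_normal((3, 3))
            S0 = pk2_stress(card, st)
            S1 = pk2_stress(card, DeformationState(st.F + dF))
            dE = 0.5 * ((st.F + dF).T @ (st.F + dF) - st.F.T @ st.F)
            dS = np.einsum("ijkl,kl->ij", CC, dE)
            assert np.abs(S1 - S0 - dS).max() < 1e-4 * np.abs(dS).max()

    def test_tangent_minor_symmetries(self, library, rng):
        st = random_state(rng, 0.05)
        for card in all_polynomial_cards(library)[:4]:
            CC = material_tangent(card, st)
            assert np.abs(CC - CC.transpose(1, 0, 2, 3)).max() < 1e-12
            assert np.abs(CC - CC.transpose(0, 1, 3, 2)).max() < 1e-12

    def test_small_strain_limit_is_isotropic_elasticity(self, library):
        I = np.eye(3)
        Isym = 0.5 * (np.einsum("ik,jl->ijkl", I, I)
                      + np.einsum("il,jk->ijkl", I, I))
        IxI = np.einsum("ij,kl->ijkl", I, I)
        for card in all_polynomial_cards(library):
            CC = material_tangent(card, DeformationState(np.eye(3)))
            mu, k = card.shear_modulus, card.bulk_modulus
            expected = k * IxI + 2.0 * mu * (Isym - IxI / 3.0)
            assert np.abs(CC - expected).max() < 1e-9 * k


class TestHardeningFloor:
    def test_inactive_inside_fitted_range(self, library):
        card = library.get("posterior_sclera", "average")
        floored = card.with_hardening_floor(0.2)
        for lam in (1.02, 1.05, 1.08):
            assert uniaxial_nominal_stress(floored, lam) == pytest.approx(
                uniaxial_nominal_stress(card, lam), rel=1e-3)

    def test_keeps_soft_percentile_card_tensile(self, library):
        # the raw 5th-percentile extrapolation turns down and even goes
        # compressive at tensile stretches; the floor keeps the response
        # tensile with a much smaller dip
        card = library.get("peripapillary_sclera", "compliant")
        floored = card.with_hardening_floor(0.2)
        lams = np.linspace(1.01, 1.45, 80)
        raw = np.array([uniaxial_nominal_stress(card, l) for l in lams])
        reg = np.array([uniaxial_nominal_stress(floored, l) for l in lams])
        assert raw.min() < 0.0
        assert reg.min() > 0.0
        assert np.diff(reg).min() > 0.5 * np.diff(raw).min()


class TestMixture:
    def test_pure_connective_identity(self):
        spec = MixtureSpec(whole_on_modulus=0.3, neural_modulus=0.001,
                           connective_fraction=1.0)
        assert connective_modulus_from_mixture(spec) == pytest.approx(0.3)

    def test_default_fraction_is_9_over_25(self):
        assert CONNECTIVE_NEURAL_AREA_FRACTION == pytest.approx(9.0 / 25.0)
        spec = MixtureSpec(whole_on_modulus=0.3, neural_modulus=0.001)
        assert spec.connective_fraction == pytest.approx(0.36)

    def test_algebraic_round_trip(self):
        spec = MixtureSpec(whole_on_modulus=0.21, neural_modulus=0.001195)
        ec = connective_modulus_from_mixture(spec)
        f = spec.connective_fraction
        back = f * ec + (1 - f) * spec.neural_modulus
        assert back == pytest.approx(spec.whole_on_modulus, rel=1e-15)

    def test_inconsistent_mixture_rejected(self):
        with pytest.raises(MixtureError):
            connective_modulus_from_mixture(
                MixtureSpec(whole_on_modulus=0.0005, neural_modulus=0.001195))
        with pytest.raises(MixtureError):
            MixtureSpec(whole_on_modulus=0.2, neural_modulus=0.001,
                        connective_fraction=0.0)

    def test_homogenized_on_small_strain_modulus(self, library):
        conn = library.get("on_connective", "average")
        neural = library.get("on_neural", "average")
        hom = homogenize_on_interior(conn, neural)
        f = CONNECTIVE_NEURAL_AREA_FRACTION
        # Voigt blend of shear and bulk moduli
        assert hom.shear_modulus == pytest.approx(
            f * conn.shear_modulus + (1 - f) * neural.shear_modulus, rel=1e-12)
        assert hom.bulk_modulus == pytest.approx(
            f * conn.bulk_modulus + (1 - f) * neural.bulk_modulus, rel=1e-12)


class TestMaterialLibrary:
    def test_expected_rows_and_levels(self, library):
        assert set(library.regions) == {
            "anterior_sclera", "equatorial_sclera", "posterior_sclera",
            "peripapillary_sclera", "on_sheath", "lamina_cribrosa",
            "on_connective", "on_neural"}
        for region in ("posterior_sclera", "peripapillary_sclera",
                       "on_sheath", "on_connective"):
            assert library.levels(region) == ("average", "compliant", "stiff")
        for region in ("anterior_sclera", "equatorial_sclera",
                       "lamina_cribrosa", "on_neural"):
            assert library.levels(region) == ("average",)

    def test_posterior_average_is_six_term_card(self, library):
        card = library.get("posterior_sclera", "average")
        assert card.order == 6
        assert card.deviatoric_coeffs[0] == pytest.approx(0.633)
        assert card.deviatoric_coeffs[1] == pytest.approx(144.0)
        # printed x1e3 columns are rescaled on load
        assert card.deviatoric_coeffs[2] == pytest.approx(-6.08e-3)
        assert card.deviatoric_coeffs[5] == pytest.approx(9.55)
        assert card.volumetric_coeffs[0] == pytest.approx(0.064)

    def test_unpublished_level_raises(self, library):
        with pytest.raises(MaterialLookupError):
            library.get("anterior_sclera", "stiff")
        with pytest.raises(MaterialLookupError):
            library.get("vitreous", "average")

    def test_neural_tissue_is_linear_elastic(self, library):
        card = library.get("on_neural", "average")
        assert isinstance(card, LinearElasticParams)
        assert card.poisson_ratio == pytest.approx(0.48)
        assert card.youngs_modulus == pytest.approx(0.001195)

    def test_incompressible_cards_use_penalty_bulk(self, library):
        card = library.get("on_connective", "stiff")
        assert card.volumetric_coeffs[0] == 0.0
        assert card.bulk_modulus == pytest.approx(
            1000.0 * card.shear_modulus)
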