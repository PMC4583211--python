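"""Powder C-term intensities, VTVH curves and polarization fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vtvhmcd import (
    OrientationGrid,
    TransitionMoments,
    fractional_polarizations,
    moments_from_polarizations,
    nesting_spread,
    powder_cterm_intensity,
    s_half_closed_form,
    vtvh_curves,
)
from vtvhmcd.constants import BOHR_MAGNETON_CM1_PER_T, BOLTZMANN_CM1_PER_K
from vtvhmcd.cterm import UndefinedPolarizationError, orientation_coefficients

# gamma=-3, single M_xy=1: the powder average equals tanh(g beta B/2kT) exactly
TANH_MOMENTS = TransitionMoments(M_xy=1.0, M_xz=0.0, M_yz=0.0, gamma=-3.0)


class TestPowderIntensity:
    def test_spin_half_matches_tanh_oracle(self, spin_half):
        """S=1/2 isotropic powder curve equals the closed form to 1e-4."""
        for x_target in np.linspace(0.1, 3.0, 8):
            T = 4.0
            B = x_target * BOLTZMANN_CM1_PER_K * T / BOHR_MAGNETON_CM1_PER_T
            got = powder_cterm_intensity(spin_half, TANH_MOMENTS, B, T)
            assert abs(got - s_half_closed_form(2.0, B, T)) < 1e-4

    def test_zero_field_zero_intensity(self, spin_half, mono_system):
        assert powder_cterm_intensity(spin_half, TANH_MOMENTS, 0.0, 2.0) == 0.0
        assert powder_cterm_intensity(mono_system, TANH_MOMENTS, 0.0, 2.0) == 0.0

    def test_intensity_odd_in_field(self, mono_system, coarse_grid):
        m = TransitionMoments(M_xy=0.4, M_xz=-0.8, M_yz=0.3)
        for B, T in [(2.0, 2.0), (5.0, 10.0)]:
            plus = powder_cterm_intensity(mono_system, m, B, T, grid=coarse_grid)
            minus = powder_cterm_intensity(mono_system, m, -B, T, grid=coarse_grid)
            assert abs(plus + minus) < 1e-12 * max(1.0, abs(plus))

    def test_curie_limit_linear_in_b_over_t(self, spin_half, mono_system, coarse_grid):
        """High T, low B: intensity is linear in B/T (Curie behavior)."""
        T, eps = 300.0, 0.02
        # doubling B doubles the intensity for both systems
        for sys_ in (spin_half, mono_system):
            i1 = powder_cterm_intensity(sys_, TANH_MOMENTS, eps, T, grid=coarse_grid)
            i2 = powder_cterm_intensity(sys_, TANH_MOMENTS, 2 * eps, T, grid=coarse_grid)
            assert abs(i2 / i1 - 2.0) < 1e-3
        # S=1/2: halving T doubles the intensity with the tanh slope g*beta/2k
        i1 = powder_cterm_intensity(spin_half, TANH_MOMENTS, eps, T, grid=coarse_grid)
        i4 = powder_cterm_intensity(spin_half, TANH_MOMENTS, eps, T / 2, grid=coarse_grid)
        assert abs(i4 / i1 - 2.0) < 1e-6
        slope = i1 / (eps / T)
        analytic = 2.0 * BOHR_MAGNETON_CM1_PER_T / (2.0 * BOLTZMANN_CM1_PER_K)
        assert abs(slope - analytic) / analytic < 1e-6

    def test_all_zero_moments_rejected(self, spin_half):
        with pytest.raises(ValueError):
            powder_cterm_intensity(
                spin_half, TransitionMoments(M_xy=0.0, M_xz=0.0, M_yz=0.0), 1.0, 2.0
            )
        with pytest.raises(ValueError):
            powder_cterm_intensity(spin_half, TANH_MOMENTS, 1.0, -2.0)

    def test_quadrature_convergence_on_doubling(self, mono_system):
        """Doubling the default grid changes every curve point by < 1e-6 rel."""
        m = TransitionMoments(M_xy=0.5, M_xz=0.7, M_yz=-0.5)
        B = np.array([1.0, 4.0, 7.0])
        T = np.array([2.0, 10.0])
        a1 = orientation_coefficients(mono_system, B, T, OrientationGrid.gauss_legendre(32, 64))
        a2 = orientation_coefficients(mono_system, B, T, OrientationGrid.gauss_legendre(64, 128))
        c = m.as_coefficients()
        i1 = np.einsum("u,ubt->bt", c, a1)
        i2 = np.einsum("u,ubt->bt", c, a2)
        assert np.max(np.abs(i1 - i2) / np.abs(i2)) < 1e-6


class TestNesting:
    def test_spin_half_isotherms_overlay(self, spin_half, medium_grid):
        """S=1/2 isotherms lie on one master curve versus beta*B/kT.

        Each temperature is sampled at fields giving the same beta*B/kT
        nodes, so the comparison is interpolation-free.
        """
        x_nodes = np.linspace(0.2, 1.2, 6)
        curves = []
        for T in [2.0, 5.0, 10.0, 20.0]:
            B = x_nodes * BOLTZMANN_CM1_PER_K * T / BOHR_MAGNETON_CM1_PER_T
            curves += vtvh_curves(spin_half, TANH_MOMENTS, B, [T],
                                  grid=medium_grid, normalization="raw")
        assert nesting_spread(curves) < 1e-6

    def test_s1_with_zfs_isotherms_nest(self, mono_system, medium_grid):
        """D=28 cm^-1 S=1 curves at 2-20 K show pronounced nesting."""
        curves = vtvh_curves(
            mono_system, TransitionMoments(M_xy=1.0, M_xz=1.0, M_yz=1.0),
            np.linspace(0.5, 7, 8), [2.0, 5.0, 10.0, 20.0],
            grid=medium_grid, normalization="raw",
        )
        assert nesting_spread(curves) > 0.1

    def test_curve_metadata(self, spin_half, coarse_grid):
        curves = vtvh_curves(spin_half, TANH_MOMENTS, [1.0, 2.0], [2.0], grid=coarse_grid)
        assert len(curves) == 1 and curves[0].normalization == "raw"
        np.testing.assert_allclose(
            curves[0].x_axis,
            BOHR_MAGNETON_CM1_PER_T * np.array([1.0, 2.0]) / (BOLTZMANN_CM1_PER_K * 2.0),
        )
        with pytest.raises(ValueError):
            vtvh_curves(spin_half, TANH_MOMENTS, [], [2.0], grid=coarse_grid)


class TestPolarizationFractions:
    @pytest.mark.parametrize(
        "products,expected",
        [
            ((0.0, 1.0, 1.0), (0.0, 0.0, 100.0)),  # pure z
            ((1.0, 1.0, 0.0), (100.0, 0.0, 0.0)),  # pure x
            ((1.0, 1.0, 1.0), (100 / 3, 100 / 3, 100 / 3)),
        ],
    )
    def test_reference_patterns(self, products, expected):
        m = TransitionMoments(M_xy=products[0], M_xz=products[1], M_yz=products[2])
        np.testing.assert_allclose(
            fractional_polarizations(m).as_array(), expected, atol=1e-12
        )

    @given(
        mxy=st.floats(0.05, 5.0),
        mxz=st.floats(0.05, 5.0),
        myz=st.floats(0.05, 5.0),
        scale=st.floats(0.1, 10.0),
        signs=st.tuples(st.sampled_from([-1, 1]), st.sampled_from([-1, 1]), st.sampled_from([-1, 1])),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_sum_and_scale_invariance(self, mxy, mxz, myz, scale, signs):
        """Fractions sum to 100, lie in [0,100] and ignore common rescaling/signs."""
        m1 = TransitionMoments(M_xy=signs[0] * mxy, M_xz=signs[1] * mxz, M_yz=signs[2] * myz)
        m2 = TransitionMoments(
            M_xy=scale * signs[0] * mxy, M_xz=scale * signs[1] * mxz, M_yz=scale * signs[2] * myz
        )
        f1 = fractional_polarizations(m1).as_array()
        f2 = fractional_polarizations(m2).as_array()
        assert abs(f1.sum() - 100.0) < 1e-9
        assert np.all((f1 >= 0) & (f1 <= 100))
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_undefined_for_single_product(self):
        with pytest.raises(UndefinedPolarizationError):
            fractional_polarizations(TransitionMoments(M_xy=1.0, M_xz=0.0, M_yz=0.0))

    def test_inverse_round_trip(self):
        """moments_from_polarizations reproduces the requested pattern."""
        for target in [(10.0, 82.0, 8.0), (1.0, 6.0, 93.0), (55.0, 45.0, 0.0)]:
            m = moments_from_polarizations(*target)
            got = fractional_polarizations(m).as_array()
            np.testing.assert_allclose(got, np.array(target) / sum(target) * 100, atol=1.0)
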