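"""Spin-matrix algebra, ZFS tensors, Hamiltonian construction and sublevels."""

import numpy as np
import pytest

from vtvhmcd import (
    ExchangeCoupling,
    FieldVector,
    SpinSite,
    SpinSystem,
    ZFSParameters,
    build_hamiltonian,
    convert_exchange_convention,
    rotate_tensor,
    spin_matrices,
    thermal_sublevels,
)
from vtvhmcd.constants import BOHR_MAGNETON_CM1_PER_T
from vtvhmcd.spin import hamiltonian_components, rotation_matrix

from conftest import random_spin_system


@pytest.mark.parametrize("S", [0.5, 1.0, 1.5, 2.0, 2.5])
def test_spin_matrices_algebra(S):
    """[S_x, S_y] = i S_z and S^2 = S(S+1) 1 for half-integer spins."""
    sx, sy, sz = spin_matrices(S)
    dim = int(2 * S + 1)
    np.testing.assert_allclose(sx @ sy - sy @ sx, 1j * sz, atol=1e-12)
    np.testing.assert_allclose(
        sx @ sx + sy @ sy + sz @ sz, S * (S + 1) * np.eye(dim), atol=1e-12
    )


def test_spin_matrices_basis_conventions():
    """S=1 gives S_z = diag(1, 0, -1); S=1/2 gives half the Pauli matrices."""
    _, _, sz = spin_matrices(1.0)
    np.testing.assert_allclose(sz, np.diag([1.0, 0.0, -1.0]))
    sx, sy, sz = spin_matrices(0.5)
    np.testing.assert_allclose(sx, 0.5 * np.array([[0, 1], [1, 0]]), atol=1e-15)
    np.testing.assert_allclose(sy, 0.5 * np.array([[0, -1j], [1j, 0]]), atol=1e-15)
    np.testing.assert_allclose(sz, 0.5 * np.diag([1.0, -1.0]), atol=1e-15)


@pytest.mark.parametrize("bad", [-1.0, 0.3, 1.2])
def test_spin_matrices_reject_non_half_integer(bad):
    with pytest.raises(ValueError):
        spin_matrices(bad)


class TestZFSTensor:
    def test_principal_form(self):
        """Unrotated axial tensor is diag(-D/3, -D/3, 2D/3)."""
        t = rotate_tensor(ZFSParameters(D=28.0, E_over_D=0.0))
        np.testing.assert_allclose(t, np.diag([-28 / 3, -28 / 3, 56 / 3]), atol=1e-12)

    def test_traceless_symmetric_any_angles(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            zfs = ZFSParameters(
                D=float(rng.uniform(-40, 40)),
                E_over_D=float(rng.uniform(0, 1 / 3)),
                euler_angles=tuple(rng.uniform(-180, 360, 3)),
            )
            t = rotate_tensor(zfs)
            assert abs(np.trace(t)) < 1e-12
            np.testing.assert_allclose(t, t.T, atol=1e-12)

    def test_ninety_degree_x_rotation_permutes_axes(self):
        """Rx(90): principal values preserved, y and z principal axes swap."""
        zfs0 = ZFSParameters(D=5.3, E_over_D=0.30)
        zfs_rot = ZFSParameters(D=5.3, E_over_D=0.30, euler_angles=(-90.0, 90.0, 90.0))
        rx90 = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
        np.testing.assert_allclose(rotation_matrix(-90, 90, 90), rx90, atol=1e-12)
        ev0 = np.sort(np.linalg.eigvalsh(rotate_tensor(zfs0)))
        ev1 = np.sort(np.linalg.eigvalsh(rotate_tensor(zfs_rot)))
        np.testing.assert_allclose(ev0, ev1, atol=1e-12)
        t0 = rotate_tensor(zfs0)
        np.testing.assert_allclose(
            rotate_tensor(zfs_rot), np.diag([t0[0, 0], t0[2, 2], t0[1, 1]]), atol=1e-12
        )

    def test_rhombicity_bounds(self):
        with pytest.raises(ValueError):
            ZFSParameters(D=10.0, E_over_D=0.4)


class TestHamiltonian:
    def test_zero_field_gap_is_d(self, mono_system):
        """Axial S=1: the M_s=+-1 doublet lies D above M_s=0."""
        e = np.linalg.eigvalsh(build_hamiltonian(mono_system, FieldVector.along_z(0.0)))
        gaps = e - e[0]
        np.testing.assert_allclose(gaps, [0.0, 28.0, 28.0], atol=1e-10)

    def test_pure_zeeman_spacing(self):
        """D=E=0, B || z: equally spaced levels separated by g beta B."""
        sys_ = SpinSystem(sites=(SpinSite(S=1.0, zfs=ZFSParameters(D=0.0)),))
        e = np.sort(np.linalg.eigvalsh(build_hamiltonian(sys_, FieldVector.along_z(10.0))))
        spacing = 2.0 * BOHR_MAGNETON_CM1_PER_T * 10.0
        np.testing.assert_allclose(np.diff(e), [spacing, spacing], atol=1e-10)

    def test_exchange_multiplets(self):
        """Pure ferromagnetic exchange: multiplets at -J[S(S+1)-4], S=2,1,0."""
        sys_ = SpinSystem(
            sites=(
                SpinSite(S=1.0, zfs=ZFSParameters(D=0.0)),
                SpinSite(S=1.0, zfs=ZFSParameters(D=0.0)),
            ),
            exchange=ExchangeCoupling(J=35.0, convention="minus2J"),
        )
        e = np.sort(np.linalg.eigvalsh(build_hamiltonian(sys_, FieldVector.along_z(0.0))))
        expected = sorted([-70.0] * 5 + [70.0] * 3 + [140.0])
        np.testing.assert_allclose(e, expected, atol=1e-10)

    def test_hermitian_real_eigenvalues_random_systems(self):
        rng = np.random.default_rng(17)
        for _ in range(15):
            sys_ = random_spin_system(rng, two_sites=bool(rng.integers(2)))
            fv = FieldVector(float(rng.uniform(0, 10)), float(rng.uniform(0, np.pi)),
                             float(rng.uniform(0, 2 * np.pi)))
            h = build_hamiltonian(sys_, fv)
            np.testing.assert_allclose(h, h.conj().T, atol=1e-12)
            assert np.all(np.isfinite(np.linalg.eigvalsh(h)))

    def test_dimer_matches_brute_force_kronecker(self):
        """Independent ground-up Kronecker construction agrees on random draws."""
        rng = np.random.default_rng(23)
        for _ in range(8):
            sys_ = random_spin_system(rng, two_sites=True)
            fv = FieldVector(float(rng.uniform(0, 10)), float(rng.uniform(0, np.pi)),
                             float(rng.uniform(0, 2 * np.pi)))
            # oracle: assemble everything from scratch with explicit kron
            mats = [spin_matrices(s.S) for s in sys_.sites]
            da, db = sys_.sites[0].dim, sys_.sites[1].dim
            ops = [
                [np.kron(m, np.eye(db)) for m in mats[0]],
                [np.kron(np.eye(da), m) for m in mats[1]],
            ]
            h_ref = np.zeros((da * db, da * db), dtype=complex)
            bvec = fv.magnitude * fv.direction
            for i, site in enumerate(sys_.sites):
                dt = site.zfs.tensor()
                gt = site.g_tensor()
                for u in range(3):
                    for v in range(3):
                        h_ref += dt[u, v] * ops[i][u] @ ops[i][v]
                        h_ref += BOHR_MAGNETON_CM1_PER_T * bvec[u] * gt[u, v] * ops[i][v]
            c = -2.0 * sys_.exchange.J if sys_.exchange.convention == "minus2J" else sys_.exchange.J
            for u in range(3):
                h_ref += c * ops[0][u] @ ops[1][u]
            np.testing.assert_allclose(build_hamiltonian(sys_, fv), h_ref, atol=1e-10)

    def test_strong_exchange_limit_matches_projected_block(self):
        """For J >> |D_i| the lowest 5 dimer levels equal the ZFS Hamiltonian
        projected onto the numerically determined S=2 subspace."""
        big_j = 5000.0
        sys_ = SpinSystem(
            sites=(
                SpinSite(S=1.0, zfs=ZFSParameters(D=28.0)),
                SpinSite(S=1.0, zfs=ZFSParameters(D=5.3, E_over_D=0.30,
                                                  euler_angles=(-90.0, 90.0, 90.0))),
            ),
            exchange=ExchangeCoupling(J=big_j, convention="minus2J"),
        )
        h_full = build_hamiltonian(sys_, FieldVector.along_z(0.0))
        e_full = np.linalg.eigvalsh(h_full)[:5]
        # exchange-only eigenbasis defines the S=2 subspace numerically
        h_ex = -2.0 * big_j * sum(
            np.kron(a, b) for a, b in zip(spin_matrices(1.0), spin_matrices(1.0))
        )
        e_ex, v_ex = np.linalg.eigh(h_ex)
        p = v_ex[:, :5]  # ground multiplet projector columns
        h_zfs = h_full - h_ex
        block = p.conj().T @ h_zfs @ p
        e_block = np.linalg.eigvalsh(block) + e_ex[0]
        # first-order degenerate perturbation theory: O(D^2/J) corrections
        np.testing.assert_allclose(e_full, np.sort(e_block), atol=10 * 28.0**2 / big_j)


class TestExchangeConvention:
    def test_algebraic_conversion_and_involution(self):
        ex = ExchangeCoupling(J=35.0, convention="minus2J")
        conv = convert_exchange_convention(ex, "plusJ")
        assert conv.J == -70.0 and conv.convention == "plusJ"
        back = convert_exchange_convention(conv, "minus2J")
        assert back.J == 35.0 and back.convention == "minus2J"

    def test_spectra_identical_under_conversion(self):
        site = SpinSite(S=1.0, zfs=ZFSParameters(D=12.0, E_over_D=0.1))
        for target in ("plusJ", "minus2J"):
            ex = ExchangeCoupling(J=-21.0, convention="plusJ")
            s1 = SpinSystem(sites=(site, site), exchange=ex)
            s2 = SpinSystem(sites=(site, site), exchange=convert_exchange_convention(ex, target))
            fv = FieldVector(5.0, 0.7, 1.1)
            e1 = np.linalg.eigvalsh(build_hamiltonian(s1, fv))
            e2 = np.linalg.eigvalsh(build_hamiltonian(s2, fv))
            np.testing.assert_allclose(e1, e2, atol=1e-10)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            convert_exchange_convention(ExchangeCoupling(J=1.0), "minusJ")


class TestThermalSublevels:
    def test_ms_minus_one_expectations(self, mono_system):
        """At 10 T along z the M_s=-1 eigenstate has <S_z>=-1, <S_x>=<S_y>=0."""
        sl = thermal_sublevels(mono_system, FieldVector.along_z(10.0), 2.0)
        idx = int(np.argmin(np.abs(sl.spin_expectations[:, 2] + 1.0)))
        np.testing.assert_allclose(sl.spin_expectations[idx], [0.0, 0.0, -1.0], atol=1e-10)

    def test_ground_level_dominates_at_2k(self, mono_system):
        """D=28 cm^-1 vs kT(2 K)=1.39 cm^-1: M_s=0 population exceeds 0.999."""
        sl = thermal_sublevels(mono_system, FieldVector.along_z(0.0), 2.0)
        assert sl.populations[0] > 0.999

    def test_populations_normalize_and_high_t_uniform(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            sys_ = random_spin_system(rng, two_sites=bool(rng.integers(2)))
            fv = FieldVector(float(rng.uniform(0, 10)), float(rng.uniform(0, np.pi)), 0.3)
            sl = thermal_sublevels(sys_, fv, float(rng.uniform(1.5, 50)))
            assert abs(sl.populations.sum() - 1.0) < 1e-12
            assert np.all(sl.populations >= 0)
        sl = thermal_sublevels(sys_, fv, 1e7)
        np.testing.assert_allclose(sl.populations, np.full(sys_.dim, 1.0 / sys_.dim), atol=1e-6)

    def test_time_reversal_zero_field_magnetization(self):
        """At B=0 the thermally weighted <S_u> vanishes for u = x, y, z."""
        rng = np.random.default_rng(41)
        for _ in range(10):
            sys_ = random_spin_system(rng, two_sites=bool(rng.integers(2)))
            sl = thermal_sublevels(sys_, FieldVector.along_z(0.0), 4.0)
            m = sl.populations @ sl.spin_expectations
            np.testing.assert_allclose(m, 0.0, atol=1e-10)

    def test_invalid_inputs(self, mono_system, dimer_system):
        with pytest.raises(ValueError):
            thermal_sublevels(mono_system, FieldVector.along_z(1.0), -2.0)
        with pytest.raises(ValueError):
            thermal_sublevels(mono_system, FieldVector.along_z(1.0), 2.0, "site_A")
        # valid for dimers
        thermal_sublevels(dimer_system, FieldVector.along_z(1.0), 2.0, "site_B")


class TestSerialization:
    def test_yaml_round_trip(self, dimer_system):
        restored = type(dimer_system).from_yaml(dimer_system.to_yaml())
        assert restored == dimer_system

    def test_unknown_keys_rejected(self, mono_system):
        d = mono_system.to_dict()
        d["hyperfine"] = 1.0
        with pytest.raises(ValueError):
            type(mono_system).from_dict(d)


def test_system_validation():
    site = SpinSite(S=1.0, zfs=ZFSParameters(D=1.0))
    with pytest.raises(ValueError):
        SpinSystem(sites=(site, site))  # missing exchange
    with pytest.raises(ValueError):
        SpinSite(S=1.0, zfs=ZFSParameters(D=1.0), g=(2.0, -2.0, 2.0))
    with pytest.raises(ValueError):
        FieldVector(-1.0)
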