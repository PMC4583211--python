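"""Spin Hamiltonians for mononuclear and exchange-coupled dinuclear systems.

The model is the standard S >= 1/2 spin Hamiltonian

    H = sum_i [ S_i . D_i . S_i  +  beta B . g_i . S_i ]  +  H_ex

with a symmetric traceless zero-field-splitting (ZFS) tensor ``D_i`` per
site (parametrized by the axial parameter D, the rhombicity E/D and three
Euler angles orienting the tensor in the molecular frame), a g tensor
diagonal in the same local frame, and, for two-site systems, an isotropic
Heisenberg exchange term.  Two exchange conventions are supported:

* ``minus2J``:  H_ex = -2 J S_A . S_B   (J > 0 ferromagnetic)
* ``plusJ``:    H_ex = +J S_A . S_B     (J < 0 ferromagnetic)

Everything is built on the Zeeman product basis |M_A, M_B> and diagonalized
exactly; no perturbative step is involved anywhere.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import yaml

from .constants import BOHR_MAGNETON_CM1_PER_T, BOLTZMANN_CM1_PER_K

__all__ = [
    "ZFSParameters",
    "SpinSite",
    "ExchangeCoupling",
    "SpinSystem",
    "FieldVector",
    "SublevelSet",
    "spin_matrices",
    "rotation_matrix",
    "rotate_tensor",
    "build_hamiltonian",
    "hamiltonian_components",
    "thermal_sublevels",
    "convert_exchange_convention",
    "spin_operators",
]

ExchangeConvention = Literal["minus2J", "plusJ"]
SpinOperatorMode = Literal["total", "site_A", "site_B"]

_DEGENERACY_TOL = 1e-9


def spin_matrices(S: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return the spin matrices (S_x, S_y, S_z) for spin quantum number S.

    The basis is |S, M> with M = S, S-1, ..., -S (descending), so that
    S_z = diag(S, ..., -S).  Matrices are complex and satisfy
    [S_x, S_y] = i S_z and S_x^2 + S_y^2 + S_z^2 = S(S+1) 1.
    """
    two_s = 2.0 * S
    if S < 0 or abs(two_s - round(two_s)) > 1e-12:
        raise ValueError(f"S must be a non-negative half-integer, got {S}")
    m = np.arange(S, -S - 1.0, -1.0)
    dim = len(m)
    sz = np.diag(m).astype(complex)
    # <m+1| S_+ |m> = sqrt(S(S+1) - m(m+1)); m descending puts S_+ above diag
    ladder = np.sqrt(S * (S + 1.0) - m[1:] * (m[1:] + 1.0))
    sp = np.zeros((dim, dim), dtype=complex)
    sp[np.arange(dim - 1), np.arange(1, dim)] = ladder
    sm = sp.conj().T
    sx = 0.5 * (sp + sm)
    sy = -0.5j * (sp - sm)
    return sx, sy, sz


def rotation_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Active Z-Y-Z Euler rotation matrix, angles in degrees.

    R = Rz(alpha) @ Ry(beta) @ Rz(gamma); a vector expressed in the tensor
    principal frame transforms to the molecular frame as v_mol = R v_pf.
    """
    a, b, g = np.deg2rad([alpha, beta, gamma])

    def rz(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(a) @ ry(b) @ rz(g)


@dataclass(frozen=True)
class ZFSParameters:
    """Zero-field splitting parameters.

    D is the axial parameter in cm^-1; E_over_D the rhombicity (0 to 1/3);
    euler_angles (Z-Y-Z, active, degrees) orient the tensor principal axes
    in the molecular frame.
    """

    D: float
    E_over_D: float = 0.0
    euler_angles: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.E_over_D <= 1.0 / 3.0 + 1e-12):
            raise ValueError(f"E/D must lie in [0, 1/3], got {self.E_over_D}")
        if len(self.euler_angles) != 3:
            raise ValueError("euler_angles must have three components")

    @property
    def E(self) -> float:
        return self.D * self.E_over_D

    def principal_tensor(self) -> np.ndarray:
        """diag(-D/3 + E, -D/3 - E, 2D/3): the traceless principal form."""
        D, E = self.D, self.E
        return np.diag([-D / 3.0 + E, -D / 3.0 - E, 2.0 * D / 3.0])

    def tensor(self) -> np.ndarray:
        """ZFS tensor rotated into the molecular frame (symmetric, traceless)."""
        R = rotation_matrix(*self.euler_angles)
        return R @ self.principal_tensor() @ R.T


def rotate_tensor(zfs: ZFSParameters) -> np.ndarray:
    """Molecular-frame 3x3 ZFS tensor for the given parameters."""
    return zfs.tensor()


@dataclass(frozen=True)
class SpinSite:
    """One paramagnetic site: spin quantum number, ZFS and principal g-values.

    The g tensor is diagonal in the site's ZFS principal frame and co-rotates
    with it.
    """

    S: float
    zfs: ZFSParameters
    g: tuple[float, float, float] = (2.0, 2.0, 2.0)

    def __post_init__(self) -> None:
        two_s = 2.0 * self.S
        if self.S < 0.5 or abs(two_s - round(two_s)) > 1e-12:
            raise ValueError(f"S must be a half-integer >= 1/2, got {self.S}")
        if any(gv <= 0 for gv in self.g):
            raise ValueError("g components must be positive")

    @property
    def dim(self) -> int:
        return int(round(2.0 * self.S + 1.0))

    def g_tensor(self) -> np.ndarray:
        R = rotation_matrix(*self.zfs.euler_angles)
        return R @ np.diag(self.g) @ R.T


@dataclass(frozen=True)
class ExchangeCoupling:
    """Isotropic bilinear exchange; J in cm^-1 under the stated convention."""

    J: float
    convention: ExchangeConvention = "minus2J"

    def __post_init__(self) -> None:
        if self.convention not in ("minus2J", "plusJ"):
            raise ValueError(f"unknown exchange convention {self.convention!r}")

    def prefactor(self) -> float:
        """Coefficient c in H_ex = c * S_A . S_B."""
        return -2.0 * self.J if self.convention == "minus2J" else self.J


def convert_exchange_convention(
    coupling: ExchangeCoupling, target: ExchangeConvention
) -> ExchangeCoupling:
    """Re-express J under another convention; the Hamiltonian is unchanged."""
    if target not in ("minus2J", "plusJ"):
        raise ValueError(f"unknown exchange convention {target!r}")
    if target == coupling.convention:
        return coupling
    if coupling.convention == "minus2J":  # -2J = J'
        return ExchangeCoupling(J=-2.0 * coupling.J, convention=target)
    return ExchangeCoupling(J=-0.5 * coupling.J, convention=target)


@dataclass(frozen=True)
class SpinSystem:
    """One or two spin sites, optionally exchange coupled."""

    sites: tuple[SpinSite, ...]
    exchange: ExchangeCoupling | None = None

    def __post_init__(self) -> None:
        if len(self.sites) not in (1, 2):
            raise ValueError("SpinSystem supports one or two sites")
        if len(self.sites) == 2 and self.exchange is None:
            raise ValueError("a two-site system requires an exchange coupling")
        if len(self.sites) == 1 and self.exchange is not None:
            raise ValueError("exchange given but only one site present")

    @property
    def dim(self) -> int:
        d = 1
        for s in self.sites:
            d *= s.dim
        return d

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def total_spin(self) -> float:
        """Maximum total spin, the ground multiplet for ferromagnetic coupling."""
        return sum(s.S for s in self.sites)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "sites": [
                {
                    "S": s.S,
                    "D": s.zfs.D,
                    "E_over_D": s.zfs.E_over_D,
                    "euler_angles": list(s.zfs.euler_angles),
                    "g": list(s.g),
                }
                for s in self.sites
            ]
        }
        if self.exchange is not None:
            d["exchange"] = {"J": self.exchange.J, "convention": self.exchange.convention}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SpinSystem":
        known = {"sites", "exchange"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown keys in spin system config: {sorted(unknown)}")
        sites = []
        for sd in d["sites"]:
            site_known = {"S", "D", "E_over_D", "euler_angles", "g"}
            extra = set(sd) - site_known
            if extra:
                raise ValueError(f"unknown keys in site config: {sorted(extra)}")
            sites.append(
                SpinSite(
                    S=float(sd["S"]),
                    zfs=ZFSParameters(
                        D=float(sd["D"]),
                        E_over_D=float(sd.get("E_over_D", 0.0)),
                        euler_angles=tuple(sd.get("euler_angles", (0.0, 0.0, 0.0))),
                    ),
                    g=tuple(sd.get("g", (2.0, 2.0, 2.0))),
                )
            )
        ex = d.get("exchange")
        exchange = (
            ExchangeCoupling(J=float(ex["J"]), convention=ex.get("convention", "minus2J"))
            if ex is not None
            else None
        )
        return cls(sites=tuple(sites), exchange=exchange)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SpinSystem":
        return cls.from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class FieldVector:
    """Applied magnetic field: magnitude (Tesla) and polar angles (radians)."""

    magnitude: float
    theta: float = 0.0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError("field magnitude must be non-negative")

    @classmethod
    def along_z(cls, B: float) -> "FieldVector":
        return cls(magnitude=B, theta=0.0, phi=0.0)

    @property
    def direction(self) -> np.ndarray:
        """Direction cosines (l_x, l_y, l_z); unit norm."""
        st, ct = np.sin(self.theta), np.cos(self.theta)
        return np.array([st * np.cos(self.phi), st * np.sin(self.phi), ct])

    @property
    def vector(self) -> np.ndarray:
        return self.magnitude * self.direction


def _embed(op: np.ndarray, index: int, dims: Sequence[int]) -> np.ndarray:
    """Kronecker-embed a single-site operator into the product space."""
    mats = [np.eye(d, dtype=complex) for d in dims]
    mats[index] = op
    out = mats[0]
    for m in mats[1:]:
        out = np.kron(out, m)
    return out


def site_spin_operators(system: SpinSystem) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-site (S_x, S_y, S_z) embedded in the product basis."""
    dims = [s.dim for s in system.sites]
    out = []
    for i, site in enumerate(system.sites):
        ops = spin_matrices(site.S)
        out.append(tuple(_embed(o, i, dims) for o in ops))
    return out


def spin_operators(system: SpinSystem, mode: str = "total") -> tuple[np.ndarray, ...]:
    """Spin operators (S_x, S_y, S_z) for the requested expectation-value set.

    ``total`` sums over sites; ``site_A``/``site_B`` select a single site's
    local spin (dimer only).
    """
    mode = mode.replace("-", "_")
    ops = site_spin_operators(system)
    if mode == "total":
        return tuple(sum(o[u] for o in ops) for u in range(3))
    if mode in ("site_A", "site_B"):
        if system.n_sites == 1:
            raise ValueError("site-resolved spin operators require a two-site system")
        return ops[0] if mode == "site_A" else ops[1]
    raise ValueError(f"unknown spin operator mode {mode!r}")


def hamiltonian_components(
    system: SpinSystem,
) -> tuple[np.ndarray, np.ndarray]:
    """Field-independent part H0 (cm^-1) and Zeeman operators Z (3, d, d).

    The full Hamiltonian at field B (Tesla) along unit vector l is
    H = H0 + B * sum_u l_u Z_u, with Z_u = beta * sum_sites sum_v g_uv S_v.
    """
    dims = [s.dim for s in system.sites]
    d = system.dim
    h0 = np.zeros((d, d), dtype=complex)
    z = np.zeros((3, d, d), dtype=complex)
    site_ops = site_spin_operators(system)
    for i, site in enumerate(system.sites):
        ops = site_ops[i]
        dten = site.zfs.tensor()
        for u in range(3):
            for v in range(3):
                if dten[u, v] != 0.0:
                    h0 += dten[u, v] * (ops[u] @ ops[v])
        gten = site.g_tensor()
        for u in range(3):
            for v in range(3):
                if gten[u, v] != 0.0:
                    z[u] += BOHR_MAGNETON_CM1_PER_T * gten[u, v] * ops[v]
    if system.exchange is not None:
        a_ops, b_ops = site_ops
        c = system.exchange.prefactor()
        h0 += c * sum(a_ops[u] @ b_ops[u] for u in range(3))
    return h0, z


def build_hamiltonian(system: SpinSystem, field: FieldVector) -> np.ndarray:
    """Full spin Hamiltonian (Hermitian, cm^-1) at the given field."""
    h0, z = hamiltonian_components(system)
    l = field.direction
    return h0 + field.magnitude * np.einsum("u,uij->ij", l, z)


@dataclass
class SublevelSet:
    """Eigen-decomposition plus thermal populations and spin expectations.

    energies are sorted ascending (cm^-1, relative to the ground level);
    states[:, i] is the i-th eigenvector in the product basis; populations
    are Boltzmann factors at the stored temperature; spin_expectations[i]
    holds (<S_x>_i, <S_y>_i, <S_z>_i) for the selected spin-operator set,
    with degenerate subspaces averaged so that time-reversal partners cancel.
    """

    energies: np.ndarray
    states: np.ndarray
    populations: np.ndarray
    spin_expectations: np.ndarray
    temperature: float
    mode: str = "total"


def _degenerate_groups(energies: np.ndarray, tol: float = _DEGENERACY_TOL) -> list[np.ndarray]:
    groups: list[list[int]] = [[0]]
    for i in range(1, len(energies)):
        if energies[i] - energies[groups[-1][0]] <= tol * max(1.0, abs(energies[i])):
            groups[-1].append(i)
        else:
            groups.append([i])
    return [np.array(g) for g in groups]


def thermal_sublevels(
    system: SpinSystem,
    field: FieldVector,
    T: float,
    spin_operator_mode: str = "total",
) -> SublevelSet:
    """Diagonalize, populate and evaluate spin expectations at (B, T).

    Within degenerate eigenvalue groups the expectations are replaced by the
    subspace average (trace over the group), which removes the arbitrary
    mixing a numerical eigensolver introduces and makes time-reversal pairs
    cancel exactly at zero field.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    h = build_hamiltonian(system, field)
    energies, states = np.linalg.eigh(h)
    energies = energies - energies[0]
    beta_t = 1.0 / (BOLTZMANN_CM1_PER_K * T)
    w = np.exp(-energies * beta_t)
    populations = w / w.sum()
    ops = spin_operators(system, spin_operator_mode)
    exp = np.empty((len(energies), 3))
    for u, op in enumerate(ops):
        exp[:, u] = np.real(np.einsum("ki,kl,li->i", states.conj(), op, states))
    for group in _degenerate_groups(energies):
        if len(group) > 1:
            exp[group] = exp[group].mean(axis=0)
    return SublevelSet(
        energies=energies,
        states=states,
        populations=populations,
        spin_expectations=exp,
        temperature=T,
        mode=spin_operator_mode,
    )
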