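"""MCD C-term and pseudo-A-term sign prediction for d-d transitions.

For one-electron ligand-field excitations dominated by a single orbital
replacement, the sign of a C-term in the saturation limit follows from
three ingredients: the one-electron orbital angular momentum matrix element
coupling the two excited states (spin-orbit, J-K coupling), the directions
of the two electric transition dipole moments, and the energy ordering of
the pair.  Writing J for the observed transition and K for its partner,

    sign(C_J) = sign[ (1/Delta_KJ) * sum_t Im<K| l_t |J> (D_J x D_K)_t ],
    Delta_KJ = E_K - E_J,

with the matrix element reduced to the donating/accepting orbitals via the
Slater-Condon rules.  Equivalently (the graphical rule): when the two
transition dipoles and the spin-orbit vector form a left-handed system the
lower-energy transition absorbs right circularly polarized light and its
C-term is negative.  The two members of a pseudo-A pair always carry
opposite signs, and the pseudo-A sign (that of the higher-energy member)
does not depend on which member lies lower.

Real d orbitals are expanded in the complex |l=2, m> basis with
Condon-Shortley phases; every reported sign is relative to this convention.
Transition-dipole directions are inputs (they encode transition-density
information outside the scope of a ligand-field sign rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "D_ORBITALS",
    "RealOrbital",
    "OneElectronTransition",
    "ExcitedStatePair",
    "d_orbital_angmom",
    "soc_vector",
    "cterm_sign_saturation",
    "cterm_sign_handedness",
    "pseudo_a_sign",
]

# Real d orbitals over |2, m>, m = -2..+2 (columns ordered m = -2, -1, 0, 1, 2),
# Condon-Shortley phases.
_SQ2 = np.sqrt(0.5)
D_ORBITALS: dict[str, np.ndarray] = {
    "d_z2": np.array([0, 0, 1, 0, 0], dtype=complex),
    "d_xz": np.array([0, _SQ2, 0, -_SQ2, 0], dtype=complex),
    "d_yz": np.array([0, 1j * _SQ2, 0, 1j * _SQ2, 0], dtype=complex),
    "d_xy": np.array([1j * _SQ2, 0, 0, 0, -1j * _SQ2], dtype=complex),
    "d_x2-y2": np.array([_SQ2, 0, 0, 0, _SQ2], dtype=complex),
}

_M = np.arange(-2, 3, dtype=float)
_LZ = np.diag(_M).astype(complex)
_LP = np.zeros((5, 5), dtype=complex)
for _i, _m in enumerate(_M[:-1]):
    _LP[_i + 1, _i] = np.sqrt(6.0 - _m * (_m + 1.0))  # <m+1| l+ |m>
_LM = _LP.conj().T
_LX = 0.5 * (_LP + _LM)
_LY = -0.5j * (_LP - _LM)
_L_OPS = {"x": _LX, "y": _LY, "z": _LZ}

_AXES = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}


@dataclass(frozen=True)
class RealOrbital:
    """One of the five real d orbitals, identified by label."""

    label: str

    def __post_init__(self) -> None:
        if self.label not in D_ORBITALS:
            raise ValueError(
                f"unknown orbital {self.label!r}; expected one of {sorted(D_ORBITALS)}"
            )

    @property
    def vector(self) -> np.ndarray:
        return D_ORBITALS[self.label]


def d_orbital_angmom(orb1: RealOrbital | str, orb2: RealOrbital | str, component: str) -> float:
    """Signed imaginary part of <orb1| l_component |orb2> in units of hbar.

    The element itself is purely imaginary between real orbitals; it is
    antisymmetric under orbital exchange and vanishes on the diagonal.
    """
    if component not in _L_OPS:
        raise ValueError(f"unknown component {component!r}; expected x, y or z")
    o1 = orb1 if isinstance(orb1, RealOrbital) else RealOrbital(orb1)
    o2 = orb2 if isinstance(orb2, RealOrbital) else RealOrbital(orb2)
    elem = o1.vector.conj() @ _L_OPS[component] @ o2.vector
    return float(elem.imag)


def _parse_direction(direction) -> np.ndarray:
    """Accept '-x', '+y', 'z' or a 3-vector; return a unit vector."""
    if isinstance(direction, str):
        d = direction.strip()
        sign = -1.0 if d.startswith("-") else 1.0
        axis = d.lstrip("+-")
        if axis not in _AXES:
            raise ValueError(f"unknown dipole direction {direction!r}")
        return sign * _AXES[axis]
    v = np.asarray(direction, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("dipole direction must be nonzero")
    return v / n


@dataclass(frozen=True)
class OneElectronTransition:
    """A single-excitation d-d transition: EDO -> EAO with a dipole direction.

    Only the relative energy ordering of paired transitions matters.
    """

    edo: RealOrbital
    eao: RealOrbital
    dipole_direction: tuple[float, float, float]
    energy: float

    def __post_init__(self) -> None:
        if self.edo.label == self.eao.label:
            raise ValueError("donating and accepting orbitals must differ")
        v = _parse_direction(self.dipole_direction)
        object.__setattr__(self, "dipole_direction", tuple(float(x) for x in v))

    @classmethod
    def make(cls, edo: str, eao: str, dipole, energy: float) -> "OneElectronTransition":
        return cls(
            edo=RealOrbital(edo),
            eao=RealOrbital(eao),
            dipole_direction=_parse_direction(dipole),
            energy=energy,
        )

    @property
    def dipole(self) -> np.ndarray:
        return np.asarray(self.dipole_direction)


def _state_angmom(bra: OneElectronTransition, ket: OneElectronTransition, component: str) -> float:
    """Im <bra_state| l_component |ket_state> via the Slater-Condon rules.

    Shared EAO: the states differ in which orbital hosts the hole, and the
    element reduces to <edo_ket's replacement...>; concretely moving the
    electron from bra.edo (occupied in ket) into ket.edo gives
    <ket.edo| l |bra.edo>... expressed from the orbital pair that differs.
    Shared EDO: reduces to <eao_bra| l |eao_ket>.  States differing in both
    orbitals are not spin-orbit coupled at the one-electron level.
    """
    if bra.eao.label == ket.eao.label and bra.edo.label != ket.edo.label:
        # bra has bra.edo hole; ket -> bra by moving electron from bra.edo to ket.edo
        return d_orbital_angmom(ket.edo, bra.edo, component)
    if bra.edo.label == ket.edo.label and bra.eao.label != ket.eao.label:
        return d_orbital_angmom(bra.eao, ket.eao, component)
    return 0.0


@dataclass(frozen=True)
class ExcitedStatePair:
    """Two spin-orbit-coupled single excitations forming a pseudo-A pair."""

    first: OneElectronTransition
    second: OneElectronTransition

    def __post_init__(self) -> None:
        if self.first.energy == self.second.energy:
            raise ValueError("the pair must be split in energy (Delta != 0)")

    @property
    def lower(self) -> OneElectronTransition:
        return self.first if self.first.energy < self.second.energy else self.second

    @property
    def upper(self) -> OneElectronTransition:
        return self.second if self.first.energy < self.second.energy else self.first

    def soc_vector(self, observed: OneElectronTransition) -> np.ndarray:
        """L vector with components Im<partner| l_t |observed>."""
        partner = self.second if observed is self.first else self.first
        return np.array([_state_angmom(partner, observed, t) for t in "xyz"])


def soc_vector(pair: ExcitedStatePair, observed: OneElectronTransition) -> np.ndarray:
    return pair.soc_vector(observed)


def _select(pair: ExcitedStatePair, which: str) -> OneElectronTransition:
    if which == "lower":
        return pair.lower
    if which == "upper":
        return pair.upper
    raise ValueError("which must be 'lower' or 'upper'")


def cterm_sign_saturation(pair: ExcitedStatePair, which: str = "lower") -> int:
    """Saturation-limit C-term sign (+1 or -1) of one member of the pair."""
    observed = _select(pair, which)
    partner = pair.upper if observed is pair.lower else pair.lower
    delta = partner.energy - observed.energy
    l_vec = pair.soc_vector(observed)
    cross = np.cross(observed.dipole, partner.dipole)
    if np.linalg.norm(cross) < 1e-12:
        raise ValueError("transition dipoles are zero or parallel; no J-K C-term")
    value = (l_vec @ cross) / delta
    if value == 0.0:
        raise ValueError("the orbital pair carries no spin-orbit coupling along the dipole normal")
    return 1 if value > 0 else -1


def cterm_sign_handedness(pair: ExcitedStatePair, which: str = "lower") -> int:
    """Graphical handedness rule, evaluated independently of the formula.

    Build the triad (D_observed, D_partner, L): a left-handed triad
    (negative determinant) with the partner above the observed transition
    means absorption of right circularly polarized light, i.e. a negative
    C-term; each inversion (handedness or energy ordering) flips the sign.
    """
    observed = _select(pair, which)
    partner = pair.upper if observed is pair.lower else pair.lower
    l_vec = pair.soc_vector(observed)
    if np.linalg.norm(l_vec) == 0:
        raise ValueError("no spin-orbit coupling between the pair")
    triad = np.linalg.det(np.stack([observed.dipole, partner.dipole, l_vec]))
    if abs(triad) < 1e-12:
        raise ValueError("degenerate dipole/spin-orbit geometry")
    ordering = 1.0 if partner.energy > observed.energy else -1.0
    return 1 if triad * ordering > 0 else -1


def pseudo_a_sign(pair: ExcitedStatePair) -> int:
    """Sign of the pseudo-A feature: that of its higher-energy C-term."""
    return cterm_sign_saturation(pair, which="upper")
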