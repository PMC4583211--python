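"""Orientation-averaged MCD C-term intensities and VTVH magnetization curves.

The C-term intensity of a band at field B and temperature T is the powder
average

    I(B, T) = gamma / (4 pi S) * Int dOmega  sum_i N_i *
              ( l_x <s_x>_i M_yz + l_y <s_y>_i M_xz + l_z <s_z>_i M_xy )

where N_i and <s_u>_i are the Boltzmann populations and spin expectation
values of the magnetic sublevels obtained by exact diagonalization of the
spin Hamiltonian at every orientation (no linear-response shortcut), the
l_u are the direction cosines of the field in the molecular frame and the
M_vw are signed effective transition dipole moment products.  For S = 1/2
with isotropic g this reduces to the hyperbolic tangent of beta*B/2kT and
all isotherms overlay; for S > 1/2 with zero-field splitting the isotherms
nest.

The intensity is *linear* in the three products (at fixed spin system),
which the fitting module exploits: `orientation_coefficients` returns the
three orientation-averaged sums multiplying (M_yz, M_xz, M_xy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOHR_MAGNETON_CM1_PER_T, BOLTZMANN_CM1_PER_K
from .spin import SpinSystem, hamiltonian_components, spin_operators

__all__ = [
    "TransitionMoments",
    "OrientationGrid",
    "VTVHCurve",
    "PolarizationFractions",
    "orientation_coefficients",
    "powder_cterm_intensity",
    "vtvh_curves",
    "s_half_closed_form",
    "fractional_polarizations",
    "moments_from_polarizations",
    "nesting_spread",
]


@dataclass(frozen=True)
class TransitionMoments:
    """Signed effective transition dipole moment products for one band.

    M_vw multiplies l_u <s_u> for the axis u complementary to (v, w); gamma
    is an arbitrary overall scale (absolute Delta-epsilon units are not
    modeled).  Predictions depend only on the products gamma*M_vw, so
    (gamma, M) -> (gamma/c, c M) leaves every curve unchanged.  site_tag
    selects which site's local spin expectations the band senses (dimers);
    'total' uses the total spin.
    """

    M_xy: float
    M_xz: float
    M_yz: float
    gamma: float = 1.0
    site_tag: str = "total"

    def as_coefficients(self) -> np.ndarray:
        """(c_x, c_y, c_z) = gamma * (M_yz, M_xz, M_xy), the linear weights."""
        return self.gamma * np.array([self.M_yz, self.M_xz, self.M_xy])


@dataclass(frozen=True)
class OrientationGrid:
    """Quadrature nodes over the unit sphere for powder averaging.

    Gauss-Legendre in cos(theta) crossed with a uniform midpoint rule in
    phi; weights sum to 4 pi.
    """

    theta: np.ndarray
    phi: np.ndarray
    weights: np.ndarray

    @classmethod
    def gauss_legendre(cls, n_theta: int = 32, n_phi: int = 64) -> "OrientationGrid":
        if n_theta < 1 or n_phi < 1:
            raise ValueError("grid sizes must be positive")
        x, wx = np.polynomial.legendre.leggauss(n_theta)
        theta = np.arccos(x)
        phi = (np.arange(n_phi) + 0.5) * (2.0 * np.pi / n_phi)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        ww = np.repeat(wx, n_phi) * (2.0 * np.pi / n_phi)
        return cls(theta=tt.ravel(), phi=pp.ravel(), weights=ww)

    @property
    def directions(self) -> np.ndarray:
        """(N, 3) array of direction cosines."""
        st = np.sin(self.theta)
        return np.column_stack(
            [st * np.cos(self.phi), st * np.sin(self.phi), np.cos(self.theta)]
        )

    @property
    def n_nodes(self) -> int:
        return len(self.weights)


_DEFAULT_GRID: dict[tuple[int, int], OrientationGrid] = {}


def default_grid(n_theta: int = 32, n_phi: int = 64) -> OrientationGrid:
    key = (n_theta, n_phi)
    if key not in _DEFAULT_GRID:
        _DEFAULT_GRID[key] = OrientationGrid.gauss_legendre(*key)
    return _DEFAULT_GRID[key]


def orientation_coefficients(
    system: SpinSystem,
    B_values: np.ndarray,
    T_values: np.ndarray,
    grid: OrientationGrid | None = None,
    mode: str = "total",
) -> np.ndarray:
    """Orientation-averaged population-weighted spin sums.

    Returns a (3, nB, nT) array ``a`` with

        a_u(B, T) = 1/(4 pi S) * sum_nodes w l_u sum_i N_i <s_u>_i

    so that the band intensity is gamma*(a_x M_yz + a_y M_xz + a_z M_xy).
    B may be signed; a is odd in B and exactly zero at B = 0.
    """
    if grid is None:
        grid = default_grid()
    B_values = np.atleast_1d(np.asarray(B_values, dtype=float))
    T_values = np.atleast_1d(np.asarray(T_values, dtype=float))
    if np.any(T_values <= 0):
        raise ValueError("temperatures must be positive")
    h0, z = hamiltonian_components(system)
    su = np.stack(spin_operators(system, mode))
    l = grid.directions
    w = grid.weights
    s_total = system.total_spin
    out = np.zeros((3, len(B_values), len(T_values)))
    zl = np.einsum("nu,uij->nij", l, z)  # (N, d, d)
    for ib, b in enumerate(B_values):
        if b == 0.0:
            continue  # C-term intensity is odd in B and vanishes at B = 0
        h = h0[None, :, :] + b * zl
        energies, states = np.linalg.eigh(h)
        energies = energies - energies[:, :1]
        # <s_u>_i per orientation: diag of V^dag S_u V
        exp_u = np.einsum("nki,ukl,nli->uni", states.conj(), su, states).real
        for it, t in enumerate(T_values):
            boltz = np.exp(-energies / (BOLTZMANN_CM1_PER_K * t))
            boltz /= boltz.sum(axis=1, keepdims=True)
            s_avg = np.einsum("ni,uni->un", boltz, exp_u)  # (3, N)
            out[:, ib, it] = (w[None, :] * l.T * s_avg).sum(axis=1)
    return out / (4.0 * np.pi * s_total)


def powder_cterm_intensity(
    system: SpinSystem,
    moments: TransitionMoments,
    B: float,
    T: float,
    grid: OrientationGrid | None = None,
    mode: str | None = None,
) -> float:
    """Powder-averaged C-term intensity at one (B, T) point."""
    c = moments.as_coefficients()
    if not np.any(c):
        raise ValueError("all transition moment products are zero")
    a = orientation_coefficients(
        system, np.array([B]), np.array([T]), grid=grid, mode=mode or moments.site_tag
    )
    return float(c @ a[:, 0, 0])


@dataclass
class VTVHCurve:
    """One isotherm of MCD intensity versus field at fixed wavelength."""

    T: float
    B: np.ndarray
    intensity: np.ndarray
    normalization: str = "raw"

    @property
    def x_axis(self) -> np.ndarray:
        """beta*B/kT, the conventional VTVH abscissa."""
        return BOHR_MAGNETON_CM1_PER_T * self.B / (BOLTZMANN_CM1_PER_K * self.T)


def vtvh_curves(
    system: SpinSystem,
    moments: TransitionMoments,
    B_grid: np.ndarray,
    T_list: np.ndarray,
    grid: OrientationGrid | None = None,
    mode: str | None = None,
    normalization: str = "raw",
) -> list[VTVHCurve]:
    """Simulate one magnetization curve per temperature.

    ``normalization='max'`` scales each isotherm by its maximum absolute
    intensity (the form in which nesting is usually displayed); ``'raw'``
    keeps the common gamma scale.
    """
    B_grid = np.atleast_1d(np.asarray(B_grid, dtype=float))
    T_list = np.atleast_1d(np.asarray(T_list, dtype=float))
    if B_grid.size == 0 or T_list.size == 0:
        raise ValueError("field and temperature grids must be nonempty")
    if normalization not in ("raw", "max"):
        raise ValueError("normalization must be 'raw' or 'max'")
    c = moments.as_coefficients()
    if not np.any(c):
        raise ValueError("all transition moment products are zero")
    a = orientation_coefficients(
        system, B_grid, T_list, grid=grid, mode=mode or moments.site_tag
    )
    intensities = np.einsum("u,ubt->bt", c, a)
    curves = []
    for it, t in enumerate(T_list):
        y = intensities[:, it].copy()
        if normalization == "max":
            peak = np.max(np.abs(y))
            if peak > 0:
                y = y / peak
        curves.append(VTVHCurve(T=float(t), B=B_grid.copy(), intensity=y, normalization=normalization))
    return curves


def s_half_closed_form(g: float, B: float, T: float) -> float:
    """Closed-form S=1/2 isotropic saturation curve tanh(g beta B / 2kT).

    Serves as an independent oracle for the powder average; an S=1/2 system
    with isotropic g and a single product M_xy = 1, gamma = -3 reproduces it.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    return float(
        np.tanh(g * BOHR_MAGNETON_CM1_PER_T * B / (2.0 * BOLTZMANN_CM1_PER_K * T))
    )


class UndefinedPolarizationError(ValueError):
    """Fewer than two nonzero products: the polarization fractions are 0/0."""


@dataclass(frozen=True)
class PolarizationFractions:
    """Percent of band intensity polarized along x, y and z; sums to 100."""

    pct_x: float
    pct_y: float
    pct_z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.pct_x, self.pct_y, self.pct_z])


def fractional_polarizations(moments: TransitionMoments) -> PolarizationFractions:
    """Fractional polarizations from the effective moment products.

    %x = 100 (M_xy M_xz)^2 / [(M_xy M_xz)^2 + (M_xy M_yz)^2 + (M_xz M_yz)^2],
    cyclically for y and z.  Homogeneous of degree zero: any common rescaling
    of the products leaves the fractions unchanged.
    """
    nonzero = sum(1 for m in (moments.M_xy, moments.M_xz, moments.M_yz) if m != 0.0)
    if nonzero < 2:
        raise UndefinedPolarizationError(
            "fractional polarizations need at least two nonzero moment products"
        )
    nx = (moments.M_xy * moments.M_xz) ** 2
    ny = (moments.M_yz * moments.M_xy) ** 2
    nz = (moments.M_xz * moments.M_yz) ** 2
    total = nx + ny + nz
    return PolarizationFractions(
        pct_x=100.0 * nx / total, pct_y=100.0 * ny / total, pct_z=100.0 * nz / total
    )


def moments_from_polarizations(
    pct_x: float, pct_y: float, pct_z: float, floor: float = 0.5
) -> TransitionMoments:
    """Invert the polarization formula to a representative product triple.

    Fractions below ``floor`` percent are lifted to it (exact zeros are not
    jointly realizable with two nonzero partners); the result is normalized
    to unit largest product.  Used to construct synthetic bands that show a
    prescribed polarization pattern.
    """
    f = np.array([pct_x, pct_y, pct_z], dtype=float)
    if np.any(f < 0):
        raise ValueError("fractions must be non-negative")
    f = np.maximum(f, floor)
    f = f / f.sum()
    fx, fy, fz = f
    # (M_xy M_xz)^2 : (M_xy M_yz)^2 : (M_xz M_yz)^2 = fx : fy : fz
    m_xy = (fx * fy / fz) ** 0.25
    m_xz = (fx * fz / fy) ** 0.25
    m_yz = (fy * fz / fx) ** 0.25
    peak = max(m_xy, m_xz, m_yz)
    return TransitionMoments(M_xy=m_xy / peak, M_xz=m_xz / peak, M_yz=m_yz / peak)


def nesting_spread(curves: list[VTVHCurve], n_interp: int = 101) -> float:
    """Maximum spread between isotherms plotted against beta*B/kT.

    All curves are put on one common intensity scale (the global maximum of
    the set, i.e. the saturation plateau of the coldest isotherm) and
    compared on the overlapping part of the beta*B/kT axis.  Curves that lie
    on a single master curve (S=1/2 with isotropic g) give zero to
    quadrature accuracy; zero-field splitting nests them and gives a
    strictly positive spread.  Curves must share the raw gamma scale, so
    pass ``normalization='raw'`` simulations.
    """
    if len(curves) < 2:
        raise ValueError("nesting needs at least two isotherms")
    if any(c.normalization != "raw" for c in curves):
        raise ValueError("nesting_spread needs raw (un-normalized) isotherms")
    global_peak = max(np.max(np.abs(c.intensity)) for c in curves)
    if global_peak == 0:
        raise ValueError("cannot compare identically zero isotherms")
    xmaxs = []
    norm = []
    for c in curves:
        x = np.abs(c.x_axis)
        y = np.abs(c.intensity) / global_peak
        order = np.argsort(x)
        x, y = x[order], y[order]
        if x[0] > 0:  # the C-term vanishes at zero field: anchor the origin
            x = np.concatenate([[0.0], x])
            y = np.concatenate([[0.0], y])
        norm.append((x, y))
        xmaxs.append(x.max())
    xi = np.linspace(0.0, min(xmaxs), n_interp)
    interped = np.stack([np.interp(xi, x, y) for x, y in norm])
    return float(np.max(interped.max(axis=0) - interped.min(axis=0)))
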