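"""Simultaneous Gaussian deconvolution of paired ABS and MCD spectra.

Both spectra are fit jointly with a common set of Gaussian bands whose
transition energies are shared between the two data sets up to a small
fractional shift (3% by default, implemented as a hard box constraint).
Absorption amplitudes are constrained non-negative; MCD amplitudes are
signed.  For each band the ratio of the MCD C-term zeroth moment to the
dipole strength,

    C0/D0 = (kT / beta B) * Int(DeltaEps/E) dE / Int(Eps/E) dE,

is evaluated over the fitted Gaussian profiles; metal-centered (d-d)
transitions show |C0/D0| above ~0.17 while charge-transfer bands fall
below (intensity gained through large transition dipoles rather than
spin-orbit coupling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import BOHR_MAGNETON_CM1_PER_T, BOLTZMANN_CM1_PER_K

__all__ = [
    "Spectrum",
    "GaussianBand",
    "DeconvolutionResult",
    "gaussian_profile",
    "simultaneous_deconvolve",
    "c0_over_d0",
    "classify_band",
]

#: |C0/D0| above this marks a d-d band (strict inequality).
DD_THRESHOLD = 0.17

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Spectrum:
    """A single ABS or MCD spectrum on a strictly increasing cm^-1 grid."""

    energies: np.ndarray
    intensities: np.ndarray
    kind: str = "abs"
    temperature_K: float | None = None
    field_T: float | None = None

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.kind not in ("abs", "mcd"):
            raise ValueError("spectrum kind must be 'abs' or 'mcd'")
        if len(self.energies) != len(self.intensities):
            raise ValueError("energy and intensity arrays differ in length")
        if len(self.energies) < 2:
            raise ValueError("a spectrum needs at least two points")
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass
class GaussianBand:
    """One Gaussian band shared between the ABS and MCD spectra.

    center/fwhm in cm^-1; mcd_center_shift is the fractional offset of the
    MCD band center from the ABS center (|shift| <= 3%); c0_over_d0 is
    filled in after fitting when the MCD measurement conditions are known.
    """

    center: float
    fwhm: float
    abs_amplitude: float
    mcd_amplitude: float
    mcd_center_shift: float = 0.0
    c0_over_d0: float | None = None

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if abs(self.mcd_center_shift) > 0.03 + 1e-12:
            raise ValueError("|mcd_center_shift| must not exceed 3%")


def gaussian_profile(x: np.ndarray, center: float, fwhm: float, amplitude: float) -> np.ndarray:
    """Peak-normalized Gaussian: amplitude * exp(-(x-c)^2 / 2 sigma^2)."""
    sigma = fwhm * _FWHM_TO_SIGMA
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


@dataclass
class DeconvolutionResult:
    """Fitted bands (sorted by center), per-spectrum residual norms and
    the d-d / CT classification."""

    bands: list[GaussianBand]
    abs_residual_norm: float
    mcd_residual_norm: float
    classifications: list[str] = field(default_factory=list)
    success: bool = True

    def reconstruct(self, energies: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        abs_y = np.zeros_like(energies, dtype=float)
        mcd_y = np.zeros_like(energies, dtype=float)
        for b in self.bands:
            abs_y += gaussian_profile(energies, b.center, b.fwhm, b.abs_amplitude)
            mcd_y += gaussian_profile(
                energies, b.center * (1.0 + b.mcd_center_shift), b.fwhm, b.mcd_amplitude
            )
        return abs_y, mcd_y


def _interp_amplitude(spec: Spectrum, center: float) -> float:
    return float(np.interp(center, spec.energies, spec.intensities))


def simultaneous_deconvolve(
    abs_spec: Spectrum,
    mcd_spec: Spectrum,
    n_bands: int,
    init_centers: np.ndarray,
    init_fwhm: float = 2500.0,
    shift_bound: float = 0.03,
    max_bands_fraction: float = 0.05,
) -> DeconvolutionResult:
    """Joint Gaussian fit of an ABS/MCD pair with shared band centers.

    Parameters per band: center, fwhm (shared by both spectra), a
    non-negative ABS amplitude, a signed MCD amplitude and a fractional
    MCD center shift bounded by ``shift_bound``.  Each spectrum's residual
    is scaled by its maximum absolute intensity so neither dominates the
    joint loss.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be at least 1")
    init_centers = np.asarray(init_centers, dtype=float)
    if len(init_centers) != n_bands:
        raise ValueError("one initial center per band is required")
    lo = max(abs_spec.energies.min(), mcd_spec.energies.min())
    hi = min(abs_spec.energies.max(), mcd_spec.energies.max())
    if lo >= hi:
        raise ValueError("ABS and MCD spectra do not overlap in energy")
    n_grid = len(abs_spec.energies) + len(mcd_spec.energies)
    if 5 * n_bands > max_bands_fraction * n_grid:
        raise ValueError(
            f"{n_bands} bands exceed the identifiability cap for {n_grid} spectral points"
        )

    abs_scale = np.max(np.abs(abs_spec.intensities)) or 1.0
    mcd_scale = np.max(np.abs(mcd_spec.intensities)) or 1.0

    # parameter vector: [centers | fwhms | abs_amps | mcd_amps | shifts];
    # the shift block is dropped when the bound is zero (centers exactly shared)
    fit_shifts = shift_bound > 0.0
    c0 = np.clip(init_centers, lo, hi)
    w0 = np.full(n_bands, init_fwhm)
    a0 = np.array([max(_interp_amplitude(abs_spec, c), 1e-3 * abs_scale) for c in c0])
    m0 = np.array([_interp_amplitude(mcd_spec, c) for c in c0])
    blocks0 = [c0, w0, a0, m0] + ([np.zeros(n_bands)] if fit_shifts else [])
    x0 = np.concatenate(blocks0)

    span = hi - lo
    lower = [
        np.full(n_bands, lo - 0.05 * span),
        np.full(n_bands, 50.0),
        np.zeros(n_bands),
        np.full(n_bands, -10.0 * mcd_scale),
    ]
    upper = [
        np.full(n_bands, hi + 0.05 * span),
        np.full(n_bands, span),
        np.full(n_bands, 10.0 * abs_scale),
        np.full(n_bands, 10.0 * mcd_scale),
    ]
    if fit_shifts:
        lower.append(np.full(n_bands, -shift_bound))
        upper.append(np.full(n_bands, shift_bound))
    lower, upper = np.concatenate(lower), np.concatenate(upper)

    ea, em = abs_spec.energies, mcd_spec.energies

    def unpack(x: np.ndarray):
        parts = np.split(x, 5 if fit_shifts else 4)
        if not fit_shifts:
            parts = parts + [np.zeros(n_bands)]
        return parts

    def residual(x: np.ndarray) -> np.ndarray:
        c, w, a, m, s = unpack(x)
        abs_model = np.zeros_like(ea)
        mcd_model = np.zeros_like(em)
        for k in range(n_bands):
            abs_model += gaussian_profile(ea, c[k], w[k], a[k])
            mcd_model += gaussian_profile(em, c[k] * (1.0 + s[k]), w[k], m[k])
        return np.concatenate(
            [
                (abs_model - abs_spec.intensities) / abs_scale,
                (mcd_model - mcd_spec.intensities) / mcd_scale,
            ]
        )

    sol = least_squares(residual, x0, bounds=(lower, upper), method="trf", xtol=1e-12, ftol=1e-12)
    c, w, a, m, s = unpack(sol.x)
    order = np.argsort(c)
    bands = [
        GaussianBand(
            center=float(c[k]),
            fwhm=float(w[k]),
            abs_amplitude=float(a[k]),
            mcd_amplitude=float(m[k]),
            mcd_center_shift=float(s[k]),
        )
        for k in order
    ]
    res = residual(sol.x)
    n_abs = len(ea)
    result = DeconvolutionResult(
        bands=bands,
        abs_residual_norm=float(np.linalg.norm(res[:n_abs] * abs_scale)),
        mcd_residual_norm=float(np.linalg.norm(res[n_abs:] * mcd_scale)),
        success=bool(sol.success),
    )
    if mcd_spec.temperature_K is not None and mcd_spec.field_T is not None:
        for b in result.bands:
            if b.abs_amplitude > 0:
                b.c0_over_d0 = c0_over_d0(b, mcd_spec.temperature_K, mcd_spec.field_T)
        result.classifications = [
            classify_band(b) if b.c0_over_d0 is not None else "unclassified"
            for b in result.bands
        ]
    return result


def c0_over_d0(band: GaussianBand, T: float, B: float) -> float:
    """MCD C-term zeroth moment over dipole strength for one fitted band.

    Both moments are energy-weighted integrals Int(intensity/E) dE over the
    band's Gaussian profile; the kT/(beta B) prefactor removes the trivial
    field and temperature dependence of a C-term so the ratio diagnoses the
    transition character.  The sign follows the MCD band sign.
    """
    if T <= 0 or B <= 0:
        raise ValueError("C0/D0 needs positive temperature and field")
    if band.abs_amplitude == 0:
        raise ValueError("zero absorption moment: C0/D0 undefined")
    sigma = band.fwhm * _FWHM_TO_SIGMA
    grid = np.linspace(-6.0, 6.0, 601)
    e_abs = band.center + sigma * grid
    mcd_center = band.center * (1.0 + band.mcd_center_shift)
    e_mcd = mcd_center + sigma * grid
    keep_abs = e_abs > 0
    keep_mcd = e_mcd > 0
    d0 = np.trapezoid(
        gaussian_profile(e_abs[keep_abs], band.center, band.fwhm, band.abs_amplitude)
        / e_abs[keep_abs],
        e_abs[keep_abs],
    )
    c0 = np.trapezoid(
        gaussian_profile(e_mcd[keep_mcd], mcd_center, band.fwhm, band.mcd_amplitude)
        / e_mcd[keep_mcd],
        e_mcd[keep_mcd],
    )
    prefactor = BOLTZMANN_CM1_PER_K * T / (BOHR_MAGNETON_CM1_PER_T * B)
    return float(prefactor * c0 / d0)


def classify_band(band: GaussianBand, threshold: float = DD_THRESHOLD) -> str:
    """'d-d' when |C0/D0| strictly exceeds the threshold, else 'CT'."""
    if band.c0_over_d0 is None:
        raise ValueError("compute c0_over_d0 before classifying")
    return "d-d" if abs(band.c0_over_d0) > threshold else "CT"
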