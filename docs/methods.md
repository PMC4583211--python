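# Methods

`vtvhmcd` models the low-temperature magnetic circular dichroism (MCD) of
mononuclear and exchange-coupled dinuclear iron(IV) complexes at the
spin-Hamiltonian level: exact sublevel energetics, powder-averaged C-term
saturation magnetization, least-squares recovery of zero-field-splitting
(ZFS) and transition-moment parameters, Gaussian band deconvolution with
C0/D0 classification, and one-electron C-term sign rules.  This note
records the model, its assumptions, the numerical choices, and what the
synthetic-data tests do and do not establish.

## Spin Hamiltonian

Each paramagnetic site i carries

    H_i = S_i . D_i . S_i + beta B . g_i . S_i

with the ZFS tensor parametrized by the axial parameter D (cm^-1), the
rhombicity E/D in [0, 1/3], and three Euler angles (Z-Y-Z, active,
degrees) orienting the principal axes in the molecular frame; in its
principal frame the tensor is diag(-D/3 + E, -D/3 - E, 2D/3).  The g
tensor is diagonal in the same local frame and co-rotates with it (only
isotropic g = 2.00 is used in the shipped presets).  Two-site systems add
isotropic Heisenberg exchange, supported in both common conventions:
H_ex = -2J S_A.S_B (J > 0 ferromagnetic; the convention used throughout
the presets) and H_ex = +J S_A.S_B, with J(-2J convention) = -J(+J)/2.
The dimer Hamiltonian is assembled on the Kronecker product basis
|M_A, M_B> and diagonalized exactly at every field orientation; no
perturbative or linear-response step is used anywhere, so the strong- and
weak-exchange regimes are treated on the same footing.

Constants: Bohr magneton 0.4668645 cm^-1/T, Boltzmann constant
0.6950348 cm^-1/K; energies in cm^-1, fields in Tesla, temperatures in
Kelvin.

Degenerate eigenstates (exact at B = 0) make individual spin expectation
values basis-dependent; `thermal_sublevels` therefore replaces them by the
subspace average within each degenerate group, which makes time-reversal
partners cancel exactly and removes any dependence on eigensolver
tie-breaking.  Thermal *sums* over degenerate groups are basis-invariant
anyway, so the intensity computation needs no such correction.

## C-term intensity and VTVH curves

The saturation-magnetization intensity of a band is the powder average

    I(B, T) = gamma/(4 pi S) * Int dOmega sum_i N_i
              (l_x <s_x>_i M_yz + l_y <s_y>_i M_xz + l_z <s_z>_i M_xy)

with Boltzmann populations N_i and spin expectations <s_u>_i from exact
diagonalization at each orientation, field direction cosines l_u, and
signed effective transition dipole moment products M_vw with an arbitrary
per-band scale gamma (absolute Delta-epsilon units are out of scope; only
the products gamma*M_vw are observable, and the sign gauge is fixed by
M_xz >= 0).  A- and B-terms are not modeled: the package addresses the
C-term-dominated low-temperature regime.  For S = 1/2 with isotropic g
the expression collapses to tanh(g beta B / 2kT) — the closed form
`s_half_closed_form` is kept solely as an independent oracle — and for
S > 1/2 with ZFS the isotherms nest; `nesting_spread` quantifies the
nesting as the maximum vertical spread between isotherms on a common
intensity scale versus beta*B/kT (its resolution is limited by linear
interpolation between field samples, so overlay tests sample matched
beta*B/kT nodes).

For dimer bands the spin expectations default to the *site* spin
operators of the band's site tag (a transition localized on Fe_A senses
s^A), with total-spin mode available; in the strong-exchange limit the
two differ only by the projection factor 1/2 inside the S = 2 ground
multiplet, and the choice is immaterial for sign and shape questions at
J >> kT.  Which convention the original dimer fits used is not
documented; both are provided.

Powder averaging uses Gauss-Legendre quadrature in cos(theta) crossed
with a uniform midpoint rule in phi (weights summing to 4 pi), default
32 x 64 nodes.  The integrand is smooth, so convergence is fast: doubling
the default grid changes curve points by < 1e-6 relative.  Fits use
coarser grids (12 x 24 or 8 x 16) since the quadrature error is orders of
magnitude below the 1% synthetic noise.  Intensity is exactly zero at
B = 0 (the C-term is odd in field) and this point is short-circuited.

## Fitting strategy

At fixed spin-Hamiltonian parameters the intensity is linear in
c = gamma (M_yz, M_xz, M_xy), so all per-band products are profiled out
by an exact weighted linear least-squares solve (variable projection);
the nonlinear search runs only over the named free spin-Hamiltonian
parameters (D, E/D, J, isotropic g per site) with bound-constrained
L-BFGS-B from seeded Latin-hypercube multistarts (default 32; the
analysis scripts use 4, which is already exhaustive for 1-2 free
parameters on these smooth profiles).  Weights are 1/sigma when the data
carry uncertainties and unity otherwise.  All restart endpoints are
reported, making local-minimum structure visible; fits are bitwise
reproducible given (data, spec, seed).

Uncertainty in this problem class is dominated by near-flat, strongly
correlated directions (J vs D_B), so the package deliberately provides
profile-style error-surface scans rather than covariance estimates:
`scan_error_surface` clamps one parameter on a grid, re-optimizes the
rest (multistart plus a warm start from the neighbouring grid point), and
reports the SSE profile and co-parameter trajectories.  On synthetic
dimer data generated at J = 35 cm^-1 the J profile over 20-80 cm^-1 is
flat (max/min SSE ratio ~1.2) while the compensating D_B rises
monotonically and (E/D)_B pins at the rhombic limit — the same degeneracy
structure reported for the real complex, which is why D_A and (E/D)_A are
constrained to the mononuclear values and J is fixed when quoting Fe_B
parameters.

## Band deconvolution and C0/D0

Paired absorption and MCD spectra are fit jointly by n Gaussian bands
with shared centers (MCD centers may shift by at most 3% of the band
energy, implemented as a hard box constraint; a zero bound removes the
shift parameters entirely), shared per-band widths across the two
spectra, non-negative absorption amplitudes and signed MCD amplitudes.
Residuals of each spectrum are scaled by its maximum absolute intensity
so neither data set dominates.  The per-band ratio

    C0/D0 = (kT / beta B) * Int(DeltaEps/E) dE / Int(Eps/E) dE

is evaluated over the fitted Gaussian profiles (zeroth-moment analysis;
the exact normalization used by the original deconvolution software is
not documented, so only the sign and threshold behavior of the ratio are
relied on).  |C0/D0| strictly greater than 0.17 classifies a band as
metal-centered (d-d); the boundary value itself classifies as
charge-transfer.  The threshold is configurable.

## C-term sign rules

For transitions dominated by a single orbital excitation, the C-term sign
in the saturation limit follows from the spin-orbit coupling between the
two excited states of a pseudo-A pair, their transition dipole
directions, and the energy ordering:

    sign(C_J) = sign[(1/Delta_KJ) sum_t Im<K|l_t|J> (D_J x D_K)_t],
    Delta_KJ = E_K - E_J,

with the many-electron matrix element reduced to a one-electron element
between the differing donating (or accepting) orbitals via the
Slater-Condon rules.  Real d orbitals are expanded over |l=2, m> with
Condon-Shortley phases; under this convention Im<d_xz|l_z|d_yz> = -1 and
Im<d_x2-y2|l_z|d_xy> = -2.  The orientation of the coupling element in
the formula is fixed by calibrating on the worked reference case —
E_x(d_xz -> d_x2-y2) with dipole -x below E_y(d_yz -> d_x2-y2) with
dipole -y gives a negative lower C-term — and the equivalent geometric
handedness rule (left-handed dipole/spin-orbit triad with positive
Delta means absorption of right circularly polarized light) is coded
independently and agrees exhaustively over all orbital pairs.  Dipole
*directions* are user inputs: they encode transition-density information
that no ligand-field sign rule can supply.  For the E(2e -> 2a1) pair the
relative dipole sign (+x, -y) is adopted from the published supplementary
sign analysis, whose outcome (negative pseudo-A) fixes it uniquely up to
a global flip that the bilinear rule ignores.  Out-of-state spin-orbit
distortions of band shapes and many-electron intensity borrowing are out
of scope.

## Synthetic data

The generators define the study conditions and are first-class, tested
code:

* `complex1_mono` — S = 1, D = +28 cm^-1, E/D = 0, g = 2.00; variable
  temperature at a fixed 10 T field, T = 2, 5, 10, 20, 40, 60 K; four
  bands (one z-polarized, an oppositely signed x/y pseudo-A pair, one
  mixed x,y band).
* `complex2_dimer` — two S = 1 sites, D_A = 28 / (E/D)_A = 0 and
  D_B = +5.3 / (E/D)_B = 0.30 with the B-site tensor rotated by 90
  degrees, J = 35 cm^-1 (-2J convention), g = 2.00; B = 0-7 T in 0.5 T
  steps (the standard saturation-magnetization protocol; the published
  conditions state only the 0-7 T range) at T = 2, 5, 10, 20 K; six
  wavelengths (414, 520, 592, 637, 853, 1430 nm) with per-band site tags
  and moment products chosen to reproduce the reported fractional
  polarization percentages (the true amplitudes were never published).
  The rotation axis of the B-site tensor is likewise unpublished; a 90
  degree rotation about the molecular x axis (Z-Y-Z triple (-90, 90, 90))
  is the package default, chosen because it actually tilts the unique
  axis — a 90 degree rotation about z would merely relabel x and y.
* `complex2_bands` — ten Gaussian bands at 7280, 9700, 11600, 13460,
  14970, 16850, 18450, 19880, 22600, 25380 cm^-1, FWHM 2500 cm^-1, unit
  absorption amplitudes, MCD signs following the reported signed C0/D0
  column (the lowest band, with no reported ratio, is taken positive), on
  a 5000-30000 cm^-1 grid with 25 cm^-1 spacing.

Noise is additive Gaussian with a default standard deviation of 1% of the
per-curve (or per-spectrum) maximum — no experimental noise figure was
published — and every dataset embeds its generating truth for automated
recovery scoring.  Identical seeds give identical bytes.

The generators emulate the statistical structure the analysis assumes:
exact model curves plus homoscedastic Gaussian noise.  They do not
emulate instrument baselines, glass-strain depolarization, wavelength
calibration drift, correlated noise, or band-shape asymmetry.  Passing
recovery tests therefore demonstrate that the estimators are correct and
well-conditioned under the stated conditions, not that real spectra of
these complexes would yield the same precision.  Two genuine
identifiability limits surface even on clean synthetic data and are
documented behavior, not defects: fixed-field VT data from an axial
system cannot distinguish x- from y-polarization (only the combined x,y
fraction and D are determined), and the exchange constant of the dimer is
determined only to a broad 20-80 cm^-1 band with compensating D_B.

## Problem sizes and tolerances

Recovery checks run at: mononuclear — 4 bands x 6 temperatures at 10 T,
1% noise, D free in [5, 60] cm^-1, recovered within +-3 cm^-1; dimer — 6
bands x 4 temperatures x 15 fields, 1% noise, D_B and (E/D)_B free with
J clamped at 35 cm^-1, recovered within +-1.5 cm^-1 and +-0.05; ten-band
deconvolution from centers perturbed by up to +-300 cm^-1, lowest band
recovered within +-50 cm^-1 (in practice to machine precision on
noiseless data).  Fits in tests and analysis scripts use 12 x 24 (scans:
8 x 16) orientation grids and 4 (scans: 1 + warm start) restarts; these
sizes keep every script in the seconds-to-a-minute range without
measurable loss against the defaults.  Eigenvalue degeneracy grouping
uses a 1e-9 relative tolerance; moment solves use `numpy.linalg.lstsq`
with machine rcond; the deconvolution runs trust-region reflective least
squares with xtol = ftol = 1e-12.

## Known limitations

* C-term only: no A-/B-terms, no field-induced state mixing, no absolute
  intensity units.
* Isotropic bilinear exchange only; no antisymmetric or anisotropic
  exchange, no hyperfine structure.
* Gaussian bands in the energy domain; no skewed or Voigt profiles.
* The C0/D0 magnitudes of the real complex are not reproducible without
  the original spectra; only sign/threshold behavior is asserted.
* The sign rule covers single excitations in the saturation limit with
  user-supplied dipole directions.
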