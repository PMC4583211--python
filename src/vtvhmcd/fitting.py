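"""Least-squares fitting of VTVH MCD magnetization data.

The C-term intensity of a band is linear in the three scaled products
c = gamma * (M_yz, M_xz, M_xy) once the spin system is fixed, so the fit is
organized by variable projection: for any trial set of spin-Hamiltonian
parameters the per-band products are obtained by an exact weighted linear
least-squares solve, and only the genuinely nonlinear parameters (D, E/D,
J, g) are searched numerically, with seeded Latin-hypercube multistarts.
This removes the moment directions from the nonlinear search entirely and
makes the notorious local-minimum structure of these fits a function of the
spin-Hamiltonian parameters alone.

Uncertainties for the nonlinear parameters are explored by profile-style
error-surface scans (`scan_error_surface`), not covariance estimates: the
exchange coupling in particular is known to have a nearly flat error
surface with strongly correlated zero-field-splitting compensation.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .cterm import OrientationGrid, TransitionMoments, default_grid, orientation_coefficients
from .spin import ExchangeCoupling, SpinSite, SpinSystem, ZFSParameters

__all__ = [
    "VTVHDataset",
    "FitSpec",
    "FitResult",
    "ErrorSurfaceScan",
    "fit_transition_moments",
    "fit_spin_hamiltonian",
    "scan_error_surface",
    "apply_parameters",
]

#: Free-parameter names understood by `apply_parameters`: "<field>_<site>"
#: with site letter A or B (A for a single-site system), plus "J".
_SITE_FIELDS = ("D", "E_over_D", "g_iso")


@dataclass
class VTVHDataset:
    """VTVH MCD intensities at one wavelength.

    Points are (B [Tesla], T [Kelvin], intensity, sigma); sigma defaults to
    unit weights.  site_tag records which site's spin expectations the band
    senses ('total' for a single site or total-spin fitting); truth, when
    present, stores the generating parameters of synthetic data.
    """

    wavelength_nm: float
    B: np.ndarray
    T: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    site_tag: str = "total"
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if not (len(self.B) == len(self.T) == len(self.intensity)):
            raise ValueError("B, T and intensity must have equal length")
        if np.any(self.B < 0):
            raise ValueError("fields must be non-negative")
        if np.any(self.T <= 0):
            raise ValueError("temperatures must be positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if len(self.sigma) != len(self.B):
                raise ValueError("sigma length mismatch")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive where given")

    @property
    def n_points(self) -> int:
        return len(self.B)

    def weights(self) -> np.ndarray:
        """1/sigma weights; unit weights when no sigma column is present."""
        if self.sigma is None:
            return np.ones(self.n_points)
        return 1.0 / self.sigma


@dataclass(frozen=True)
class FitSpec:
    """What is free, inside which bounds, and how hard to search.

    free: mapping name -> (lower, upper) finite bounds; fixed: mapping
    name -> value overriding the base system.  E/D bounds are clipped to
    [0, 1/3].  n_restarts Latin-hypercube starts are drawn from `seed`.
    """

    free: dict[str, tuple[float, float]] = field(default_factory=dict)
    fixed: dict[str, float] = field(default_factory=dict)
    n_restarts: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.free.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"free parameter {name!r} needs finite bounds lo < hi")
            if name.startswith("E_over_D") and (lo < 0 or hi > 1.0 / 3.0):
                raise ValueError(f"E/D bounds for {name!r} must lie in [0, 1/3]")


@dataclass
class FitResult:
    """Best parameters, per-band moments and the restart history."""

    parameters: dict[str, float]
    moments: list[TransitionMoments]
    sse: float
    restarts: list[dict]
    success: bool
    degenerate: list[bool]
    warnings: list[str] = field(default_factory=list)

    def residuals(self, datasets, system, grid=None) -> np.ndarray:
        """Recompute weighted residuals from the stored parameters."""
        sys_fit = apply_parameters(system, self.parameters)
        res = []
        for ds, mom in zip(datasets, self.moments):
            a = _dataset_coefficients(sys_fit, ds, grid)
            model = a @ mom.as_coefficients()
            res.append((ds.intensity - model) * ds.weights())
        return np.concatenate(res)


@dataclass
class ErrorSurfaceScan:
    """Profile of the re-optimized SSE along one clamped parameter."""

    parameter: str
    values: np.ndarray
    sse: np.ndarray
    co_parameters: list[dict[str, float]]

    @property
    def flatness_ratio(self) -> float:
        """max SSE / min SSE over the scan; ~1 means a flat direction."""
        return float(self.sse.max() / self.sse.min())


def apply_parameters(system: SpinSystem, params: dict[str, float]) -> SpinSystem:
    """Return a copy of `system` with named parameters replaced.

    Names: D_A, D_B, E_over_D_A, E_over_D_B, g_iso_A, g_iso_B, J.  Site A is
    the first site (and the only one for mononuclear systems).
    """
    sites = list(system.sites)
    exchange = system.exchange
    for name, value in params.items():
        if name == "J":
            if exchange is None:
                raise ValueError("cannot set J on a single-site system")
            exchange = replace(exchange, J=float(value))
            continue
        for prefix in _SITE_FIELDS:
            for letter, idx in (("A", 0), ("B", 1)):
                if name == f"{prefix}_{letter}":
                    if idx >= len(sites):
                        raise ValueError(f"parameter {name!r} refers to a missing site")
                    site = sites[idx]
                    if prefix == "D":
                        site = replace(site, zfs=replace(site.zfs, D=float(value)))
                    elif prefix == "E_over_D":
                        site = replace(site, zfs=replace(site.zfs, E_over_D=float(value)))
                    else:
                        site = replace(site, g=(float(value),) * 3)
                    sites[idx] = site
                    break
            else:
                continue
            break
        else:
            raise ValueError(f"unknown parameter name {name!r}")
    return SpinSystem(sites=tuple(sites), exchange=exchange)


def _dataset_coefficients(
    system: SpinSystem,
    dataset: VTVHDataset,
    grid: OrientationGrid | None,
    cache: dict | None = None,
) -> np.ndarray:
    """(n_points, 3) design matrix mapping c = gamma*(M_yz, M_xz, M_xy)."""
    ub = np.unique(dataset.B)
    ut = np.unique(dataset.T)
    key = (dataset.site_tag, ub.tobytes(), ut.tobytes())
    if cache is not None and key in cache:
        a = cache[key]
    else:
        a = orientation_coefficients(system, ub, ut, grid=grid, mode=dataset.site_tag)
        if cache is not None:
            cache[key] = a
    ib = np.searchsorted(ub, dataset.B)
    it = np.searchsorted(ut, dataset.T)
    return a[:, ib, it].T


def _gauge_fix(c: np.ndarray, site_tag: str) -> TransitionMoments:
    """Convert a coefficient triple to gauge-fixed TransitionMoments.

    gamma = ||c||; the sign triple is flipped so that M_xz >= 0 (only the
    relative signs of the products are observable).
    """
    gamma = float(np.linalg.norm(c))
    if gamma == 0.0:
        return TransitionMoments(M_xy=0.0, M_xz=0.0, M_yz=0.0, gamma=0.0, site_tag=site_tag)
    m_yz, m_xz, m_xy = c / gamma
    if m_xz < 0 or (m_xz == 0 and m_xy < 0):
        m_yz, m_xz, m_xy = -m_yz, -m_xz, -m_xy
    return TransitionMoments(M_xy=m_xy, M_xz=m_xz, M_yz=m_yz, gamma=gamma, site_tag=site_tag)


def _solve_moments(
    system: SpinSystem,
    datasets: list[VTVHDataset],
    grid: OrientationGrid | None,
    cache: dict | None = None,
) -> tuple[float, list[np.ndarray], list[bool]]:
    """Exact per-band linear solve; returns (weighted SSE, c per band, flags)."""
    sse = 0.0
    coeffs = []
    degenerate = []
    for ds in datasets:
        a = _dataset_coefficients(system, ds, grid, cache)
        w = ds.weights()
        aw = a * w[:, None]
        yw = ds.intensity * w
        c, *_ = np.linalg.lstsq(aw, yw, rcond=None)
        r = yw - aw @ c
        sse += float(r @ r)
        degenerate.append(bool(np.allclose(c, 0.0)))
        coeffs.append(c)
    return sse, coeffs, degenerate


def fit_transition_moments(
    datasets: list[VTVHDataset],
    system: SpinSystem,
    spec: FitSpec | None = None,
    grid: OrientationGrid | None = None,
) -> FitResult:
    """Global least-squares estimate of per-band moment products.

    With the spin system fixed the problem is exactly linear in the scaled
    products, so the optimum is found by a single weighted linear solve per
    band (every multistart of an iterative optimizer would converge to it).
    Identically zero data yields zero products flagged degenerate.
    """
    if len(datasets) == 0:
        raise ValueError("at least one dataset is required")
    if spec is not None and spec.free:
        raise ValueError("fit_transition_moments takes no free SH parameters; "
                         "use fit_spin_hamiltonian")
    fixed = dict(spec.fixed) if spec is not None else {}
    sys_fit = apply_parameters(system, fixed) if fixed else system
    sse, coeffs, degenerate = _solve_moments(sys_fit, datasets, grid, cache={})
    moments = [_gauge_fix(c, ds.site_tag) for c, ds in zip(coeffs, datasets)]
    return FitResult(
        parameters=dict(fixed),
        moments=moments,
        sse=sse,
        restarts=[{"parameters": dict(fixed), "sse": sse, "success": True}],
        success=True,
        degenerate=degenerate,
    )


def _objective_factory(base, datasets, names, grid):
    def objective(x: np.ndarray) -> float:
        params = dict(zip(names, x))
        try:
            sys_trial = apply_parameters(base, params)
        except ValueError:
            return np.inf
        sse, _, _ = _solve_moments(sys_trial, datasets, grid, cache={})
        return sse

    return objective


def fit_spin_hamiltonian(
    datasets: list[VTVHDataset],
    system: SpinSystem,
    spec: FitSpec,
    grid: OrientationGrid | None = None,
) -> FitResult:
    """Joint refinement of spin-Hamiltonian parameters and band moments.

    The moments are profiled out exactly (variable projection); the named
    free parameters are minimized with L-BFGS-B from `n_restarts` seeded
    Latin-hypercube starts inside the bounds.  All restart endpoints are
    reported so the local-minimum structure is visible.
    """
    if not spec.free:
        raise ValueError("fit_spin_hamiltonian needs at least one free SH parameter")
    if len(datasets) == 0:
        raise ValueError("at least one dataset is required")
    base = apply_parameters(system, spec.fixed) if spec.fixed else system
    names = sorted(spec.free)
    bounds = np.array([spec.free[n] for n in names])
    n_free = len(names) + 3 * len(datasets)
    n_points = sum(ds.n_points for ds in datasets)
    warns = []
    if n_free >= n_points:
        warns.append(
            f"under-determined fit: {n_free} free parameters for {n_points} points"
        )
        warnings.warn(warns[-1])
    objective = _objective_factory(base, datasets, names, grid)

    n_starts = max(1, spec.n_restarts)
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=spec.seed)
        unit = sampler.random(n_starts - 1)
        starts = np.vstack([0.5 * np.ones(len(names)), unit])
    else:
        starts = 0.5 * np.ones((1, len(names)))
    starts = bounds[:, 0] + starts * (bounds[:, 1] - bounds[:, 0])

    restarts = []
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[tuple(b) for b in bounds],
            options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-10},
        )
        entry = {
            "parameters": dict(zip(names, [float(v) for v in res.x])),
            "sse": float(res.fun),
            "success": bool(res.success),
        }
        restarts.append(entry)
        if best is None or res.fun < best.fun:
            best = res
    params = dict(zip(names, [float(v) for v in best.x]))
    sys_best = apply_parameters(base, params)
    sse, coeffs, degenerate = _solve_moments(sys_best, datasets, grid, cache={})
    moments = [_gauge_fix(c, ds.site_tag) for c, ds in zip(coeffs, datasets)]
    return FitResult(
        parameters={**spec.fixed, **params},
        moments=moments,
        sse=sse,
        restarts=restarts,
        success=bool(best.success),
        degenerate=degenerate,
        warnings=warns,
    )


def scan_error_surface(
    datasets: list[VTVHDataset],
    system: SpinSystem,
    spec: FitSpec,
    parameter: str,
    values: np.ndarray,
    grid: OrientationGrid | None = None,
) -> ErrorSurfaceScan:
    """Profile-likelihood style scan of one parameter.

    At each grid value the parameter is clamped and every other free
    parameter re-optimized (warm-started at the previous grid point's best
    fit in addition to the spec's multistarts).  Returns the SSE profile and
    the co-fitted parameter trajectories, which expose compensation effects
    such as D_B rising along a J scan.
    """
    values = np.atleast_1d(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("scan grid must be nonempty")
    others = {n: b for n, b in spec.free.items() if n != parameter}
    sse_profile = np.empty(len(values))
    co_params: list[dict[str, float]] = []
    prev_best: dict[str, float] | None = None
    for i, v in enumerate(values):
        fixed = {**spec.fixed, parameter: float(v)}
        if others:
            sub = FitSpec(free=others, fixed=fixed, n_restarts=spec.n_restarts, seed=spec.seed + i)
            result = fit_spin_hamiltonian(datasets, system, sub, grid=grid)
            best_params = {n: result.parameters[n] for n in others}
            best_sse = result.sse
            if prev_best is not None:
                # warm start from the neighbouring grid point
                base = apply_parameters(system, fixed)
                names = sorted(others)
                objective = _objective_factory(base, datasets, names, grid)
                res = minimize(
                    objective,
                    np.array([prev_best[n] for n in names]),
                    method="L-BFGS-B",
                    bounds=[others[n] for n in names],
                    options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-10},
                )
                if res.fun < best_sse:
                    best_sse = float(res.fun)
                    best_params = dict(zip(names, [float(x) for x in res.x]))
            prev_best = best_params
            sse_profile[i] = best_sse
            co_params.append(best_params)
        else:
            sys_v = apply_parameters(system, fixed)
            sse, _, _ = _solve_moments(sys_v, datasets, grid, cache={})
            sse_profile[i] = sse
            co_params.append({})
    return ErrorSurfaceScan(
        parameter=parameter, values=values, sse=sse_profile, co_parameters=co_params
    )
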