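import numpy as np
import pytest

from vtvhmcd import (
    ExchangeCoupling,
    OrientationGrid,
    SpinSite,
    SpinSystem,
    ZFSParameters,
    preset_system,
)


@pytest.fixture(scope="session")
def mono_system() -> SpinSystem:
    """The mononuclear S=1 iron(IV)-oxo system: D=+28 cm^-1, E/D=0, g=2."""
    return preset_system("complex1_mono")


@pytest.fixture(scope="session")
def dimer_system() -> SpinSystem:
    """Ferromagnetic S=1 + S=1 dimer with the published constrained tensors."""
    return preset_system("complex2_dimer")


@pytest.fixture(scope="session")
def spin_half() -> SpinSystem:
    """Isotropic S=1/2 reference (the hyperbolic-tangent limit)."""
    return SpinSystem(sites=(SpinSite(S=0.5, zfs=ZFSParameters(D=0.0)),))


@pytest.fixture(scope="session")
def coarse_grid() -> OrientationGrid:
    """Small orientation grid for fast fitting tests."""
    return OrientationGrid.gauss_legendre(10, 20)


@pytest.fixture(scope="session")
def medium_grid() -> OrientationGrid:
    return OrientationGrid.gauss_legendre(16, 32)


def random_spin_system(rng: np.random.Generator, two_sites: bool) -> SpinSystem:
    """Draw a random valid spin system for property tests."""

    def site():
        return SpinSite(
            S=float(rng.choice([0.5, 1.0, 1.5, 2.0])),
            zfs=ZFSParameters(
                D=float(rng.uniform(-30, 30)),
                E_over_D=float(rng.uniform(0, 1 / 3)),
                euler_angles=tuple(rng.uniform(0, 360, 3)),
            ),
            g=tuple(rng.uniform(1.8, 2.3, 3)),
        )

    if two_sites:
        return SpinSystem(
            sites=(site(), site()),
            exchange=ExchangeCoupling(
                J=float(rng.uniform(-60, 60)),
                convention=str(rng.choice(["minus2J", "plusJ"])),
            ),
        )
    return SpinSystem(sites=(site(),))
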