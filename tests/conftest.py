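import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hostguest import landscapes as L

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def free_amide_potential():
    """Dihedral double well of the free amide (dG 6.5, barrier 22.3)."""
    return L.make_dihedral_potential(6.5, 22.3)


@pytest.fixture(scope="session")
def analytic_profile():
    """Turn a PotentialSpec into an exact gridded FreeEnergyProfile."""
    from hostguest.thermo import FreeEnergyProfile

    def _make(pot, n=4096, temperature=300.0):
        g = pot.grid(n)
        return FreeEnergyProfile(grid=g, F=pot.energy(g),
                                 temperature=temperature,
                                 periodic=pot.periodic, basins=pot.basins)

    return _make


@pytest.fixture(scope="session")
def boltzmann_sampler():
    """Independent Boltzmann draws from an analytic landscape (inverse CDF)."""

    def _draw(pot, n, seed, temperature=300.0):
        from hostguest.constants import beta
        g = pot.grid(8192)
        w = np.exp(-beta(temperature) * pot.energy(g))
        w /= w.sum()
        rng = np.random.default_rng(seed)
        dx = g[1] - g[0]
        idx = rng.choice(len(g), size=n, p=w)
        return g[idx] + rng.uniform(-0.5 * dx, 0.5 * dx, size=n)

    return _draw
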