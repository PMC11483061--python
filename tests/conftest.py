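"""Shared fixtures: expensive synthetic datasets generated once per session."""

import pytest

from crowdtransport import synthetic


@pytest.fixture(scope="session")
def brownian_sample():
    """Brownian walkers at D=100 Å²/ns in a 200 Å box, 100 ns record."""
    return synthetic.gen_brownian(n_particles=200, D_true=100.0, L=200.0,
                                  dt=0.01, n_steps=10_000, seed=0)


@pytest.fixture(scope="session")
def ou_ensemble():
    """150 OU pressure-tensor series with analytic Green-Kubo viscosity."""
    series, gt = synthetic.gen_ou_pressure(n_traj=150, n_steps=50_000,
                                           seed=0)
    return series, gt


@pytest.fixture(scope="session")
def telegraph_timeline():
    """Default three-component telegraph contact process, 2 µs record."""
    return synthetic.gen_telegraph_contacts(seed=0)


@pytest.fixture(scope="session")
def rotational_replicas():
    """Eight independent rigid-body tumbling fixtures at Dr=0.05 ns⁻¹.

    400 ns records ≈ 120 relaxation times, the proportion the production
    trajectories give real proteins; shorter records leave the ACF tail
    noise-dominated and bias the fitted decay.
    """
    return [synthetic.gen_rotational(Dr_true=0.05, dt=0.02, n_steps=20_000,
                                     n_sites=10, seed=s)
            for s in range(8)]
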