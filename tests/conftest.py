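"""Shared fixtures: small simulated systems reused across test modules."""

import numpy as np
import pytest

import polybridge as pb
from polybridge.dynamics import confinement_radius_for_volume_fraction


@pytest.fixture(scope="session")
def small_string():
    """200-bead string, 20% red cognate beads."""
    return pb.generate_random_string(200, ["red"], 0.2, seed=5)


@pytest.fixture(scope="session")
def small_species():
    # switching off: these fixtures exercise the bridging steady state
    return [pb.FactorSpecies("red", 20, switch_off_rate=0.0, switch_on_rate=0.0)]


@pytest.fixture(scope="session")
def small_field(small_string, small_species):
    radius = confinement_radius_for_volume_fraction(small_string, small_species, 0.02)
    return pb.ForceField(confinement_radius_nm=radius)


@pytest.fixture(scope="session")
def bridging_traj(small_string, small_species, small_field):
    """An equilibrated bridging run: 200 beads + 20 factors, 400 tauB."""
    config = pb.SimulationConfig(
        n_steps=200_000, seed=7, equilibration_steps=100_000, frame_interval=2500
    )
    return pb.run_simulation(small_string, small_species, small_field, config)


@pytest.fixture(scope="session")
def polymer_only_traj():
    """Plain self-avoiding polymer, no factors: 100 beads, unconfined."""
    string = pb.generate_random_string(100, ["red"], 0.0, seed=9)
    config = pb.SimulationConfig(
        n_steps=150_000, seed=11, equilibration_steps=50_000, frame_interval=2000
    )
    return pb.run_simulation(string, [], pb.ForceField(), config)


def random_frame(n_factors, rng, box=500.0):
    """A synthetic factor-only frame with uniform random positions."""
    return pb.Frame(
        time=0.0,
        bead_positions=np.empty((0, 3)),
        factor_positions=rng.uniform(-box, box, (n_factors, 3)),
        factor_colors=["red"] * n_factors,
        binding_competent=np.ones(n_factors, dtype=bool),
    )
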