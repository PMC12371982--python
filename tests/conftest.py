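from __future__ import annotations

import numpy as np
import pytest

from knobdyn.domain_model import parse_domain_config, select_atoms
from knobdyn.synthetic_data import (
    SyntheticSpec,
    generate_hinged_trajectory,
    sinusoidal_schedule,
)


@pytest.fixture(scope="session")
def small_system():
    """A compact noiseless hinged system shared across motion tests."""
    spec = SyntheticSpec(
        n_frames=30,
        core_heavy_residues=20,
        core_light_residues=20,
        stalk_residues_per_strand=5,
        knob_residues=12,
        hinge_position=2,
        schedule_deg=sinusoidal_schedule(30, amplitude_deg=40.0, periods=1.0),
        noise_sigma=0.0,
        seed=11,
    )
    traj, truth = generate_hinged_trajectory(spec)
    partition = parse_domain_config(truth.domain_config, traj.topology)
    return {"spec": spec, "traj": traj, "truth": truth, "partition": partition}


@pytest.fixture(scope="session")
def small_selections(small_system):
    topo = small_system["traj"].topology
    part = small_system["partition"]
    return {
        name: select_atoms(topo, part, name, "backbone")
        for name in ("core", "entire", "knob", "stalk")
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
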