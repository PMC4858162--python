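"""Shared fixtures.

The long Langevin runs (equipartition, full 10-ns steering) are
session-scoped so the unit suite and the acceptance suite reuse one
trajectory each.
"""

import numpy as np
import pytest

from clampdyn.simulate import (
    LangevinParams,
    Restraint,
    build_cg,
    make_protocol,
    run_langevin,
    run_steered,
)
from clampdyn.constants import PER_DEG2_TO_PER_RAD2
from clampdyn.synthetic import RingSpec, build_ideal_ring
from clampdyn.topology import assign_domains


@pytest.fixture(scope="session")
def ideal_ring():
    """Default 6-domain planar ring + its topology and assignment."""
    s, topo = build_ideal_ring(RingSpec(seed=0))
    assignment = assign_domains(s, topo)
    return s, topo, assignment


@pytest.fixture(scope="session")
def cg_system(ideal_ring):
    s, topo, assignment = ideal_ring
    return build_cg(s, assignment, topo)


@pytest.fixture(scope="session")
def langevin_310():
    return LangevinParams(temperature=310.0, damping=5.0, timestep=0.01, seed=1)


@pytest.fixture(scope="session")
def type1_run(ideal_ring, cg_system, langevin_310):
    """Full 10-ns type-1 (interface pull) steering phase."""
    _, topo, _ = ideal_ring
    proto = make_protocol(1, topo, post_steering_ps=0.0)
    return run_steered(cg_system, proto, langevin_310, save_every=1000)


@pytest.fixture(scope="session")
def type2_run(ideal_ring, cg_system, langevin_310):
    """Full 10-ns type-2 (left-handed spiral) steering phase."""
    _, topo, _ = ideal_ring
    proto = make_protocol(2, topo, post_steering_ps=0.0)
    return run_steered(cg_system, proto, langevin_310, save_every=1000)


@pytest.fixture(scope="session")
def equipartition_run(cg_system):
    """10-ns run with one stiff static torsion restraint at 310 K."""
    sys = cg_system
    restraint = Restraint(
        kind="torsion",
        idx=(0, 1, 2, 3),
        k=50.0 * PER_DEG2_TO_PER_RAD2,
        target0=float(sys.tors_p0[0]),
        velocity=0.0,
        duration_ps=0.0,
        label="static",
    )
    params = LangevinParams(temperature=310.0, damping=5.0, timestep=0.01, seed=11)
    return run_langevin(sys, params, 1_000_000, restraints=(restraint,),
                        save_every=20), restraint
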