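"""Shared fixtures: small solvated systems prepared once per session.

Systems are built deterministically and gently relaxed; tests take fresh
copies of the stored state so mutation by one test cannot leak into
another.
"""

from __future__ import annotations

import numpy as np
import pytest

from amphimem.build import solvate
from amphimem.engine import (Frame, IntegratorConfig, System,
                             maxwell_velocities, minimize_energy, run_md)
from amphimem.synth import gen_bilayer_fixture
from amphimem.topology import BeadTopology


@pytest.fixture(scope="session")
def bilayer_state():
    """128-lipid solvated bilayer fixture, minimized and thermalized 20 ps."""
    top, frame, truth = gen_bilayer_fixture(seed=5)
    system = System(top, frame)
    minimize_energy(system, max_steps=100)
    system.frame.velocities = maxwell_velocities(top, 310.0, 11)
    run_md(system, IntegratorConfig(ensemble="NVT", seed=11), 2000, stride=2000)
    return top, system.frame.copy(), truth


@pytest.fixture()
def bilayer_system(bilayer_state):
    top, frame, _ = bilayer_state
    return System(top, frame.copy())


@pytest.fixture(scope="session")
def water_box_state():
    """~340-bead CG water box, minimized (velocities left to the tests)."""
    box = np.array([3.5, 3.5, 3.5])
    top, frame = solvate(BeadTopology(),
                         Frame(np.zeros((0, 3)), np.zeros((0, 3)), box),
                         "fill", seed=2)
    system = System(top, frame)
    minimize_energy(system, max_steps=50)
    return top, system.frame.copy()


@pytest.fixture()
def water_box(water_box_state):
    top, frame = water_box_state
    return System(top, frame.copy())
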