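"""Shared fixtures: scaled-down steady-state runs reused across test modules.

The simulation fixtures use the nx = 20 discretization (same 40 × 20 mm
blocks, coarser grid) so a full run to steady state takes tens of seconds
instead of minutes; they are session-scoped and shared by the driver,
analysis and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import occlucurve as oc

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

SCALED = {"nx": 20, "ny": 10}


def scaled_config(**overrides) -> oc.RunConfig:
    return oc.config_from_dict({**SCALED, **overrides})


@pytest.fixture(scope="session")
def run_r100() -> oc.SimulationResult:
    """Steady-state winkler run at the reference rotation radius 100 mm."""
    return oc.run_until_steady(scaled_config(c_rot_radius_mm=100))


@pytest.fixture(scope="session")
def run_r400() -> oc.SimulationResult:
    """Steady-state winkler run at the enlarged rotation radius 400 mm."""
    return oc.run_until_steady(scaled_config(c_rot_radius_mm=400))


@pytest.fixture(scope="session")
def run_r100_half_kw(run_r100) -> oc.SimulationResult:
    """Same run with the wear coefficient halved (timescale probe)."""
    cfg = scaled_config(c_rot_radius_mm=100,
                        wear_coefficient=run_r100.state.k_w / 2.0)
    return oc.run_until_steady(cfg)


@pytest.fixture(scope="session")
def run_fe_r400() -> oc.SimulationResult:
    """Steady-state run with the plane-stress FE contact engine."""
    return oc.run_until_steady(scaled_config(c_rot_radius_mm=400,
                                             engine="fe", max_cycles=4000))


@pytest.fixture()
def flat_pair():
    """Full-resolution flat block pair with 0.01 mm uniform interference."""
    mand = oc.build_block_mesh(40, 20, 40, 20, "mandibular")
    maxb = oc.build_block_mesh(40, 20, 40, 20, "maxillary", y_offset=-0.01)
    return mand, maxb


@pytest.fixture()
def identity_pose():
    return oc.RigidTransform(0.0, np.zeros(2))
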