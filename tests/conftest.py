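"""Shared fixtures: study-condition runs reused across the suite.

The full-resolution (50 x 20, 30-year) runs are expensive, so they are
computed once per session and shared between the invariant tests and the
end-to-end acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from plaquesim.config import SimulationConfig
from plaquesim.haemo_fixtures import AtheropronePatch
from plaquesim.pipeline import run_midcourse, run_single

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


def patch_config(mode: str = "combined", **kwargs) -> SimulationConfig:
    """Default study conditions with the atheroprone patch."""
    return SimulationConfig(patch=AtheropronePatch(), mode=mode, **kwargs)


@pytest.fixture(scope="session")
def healthy_run():
    """Healthy fixture: TAWSS ~3 Pa, OSI ~0 everywhere, 30 years."""
    return run_single(SimulationConfig())


@pytest.fixture(scope="session")
def midcourse_result():
    """Mid-course experiment on the combined-mode patch run (split 15 y).

    Also carries the full single-pass combined-mode run, reused by the
    end-to-end tests.
    """
    return run_midcourse(patch_config("combined"), 15.0)


@pytest.fixture(scope="session")
def patch_run_combined(midcourse_result):
    return midcourse_result.run_single_pass, midcourse_result.single_pass


@pytest.fixture(scope="session")
def patch_run_osi():
    return run_single(patch_config("osi"))


@pytest.fixture(scope="session")
def small_patch_run():
    """Scaled-down patch run (coarse mesh, 4-year horizon) for invariants."""
    from plaquesim.units import YEAR
    from dataclasses import replace

    cfg = patch_config("combined")
    cfg.geometry = replace(cfg.geometry, nx=12, nr=6)
    cfg.patient = replace(cfg.patient, horizon=4.0 * YEAR)
    return run_single(cfg)
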