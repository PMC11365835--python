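"""Shared fixtures: the default dysplastic phantom and its osteotomy plan.

Planning takes a few seconds (nested bisection over mesh measurements), so
the plan is computed once per session and shared read-only.
"""

import numpy as np
import pytest

from raoplan.geometry import build_frame
from raoplan.phantom import PhantomParams, make_hip_phantom
from raoplan.pipeline import build_planning_model
from raoplan.planner import plan_case


@pytest.fixture(scope="session")
def phantom():
    return make_hip_phantom(PhantomParams())


@pytest.fixture(scope="session")
def frame(phantom):
    return build_frame(phantom.landmarks, phantom.side)


@pytest.fixture(scope="session")
def plan(phantom):
    return plan_case(phantom)


@pytest.fixture(scope="session")
def planning_model(phantom, plan):
    return build_planning_model(phantom, plan)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
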