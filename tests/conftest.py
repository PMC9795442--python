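"""Shared fixtures: one small synthetic study bundle reused across the suite."""

import numpy as np
import pytest

from pmslt.engine import EngineConfig, MSLTModel
from pmslt.scenarios import standard_trajectories
from pmslt.synth import default_inputs

POP = 2_000_000
SEED = 7


@pytest.fixture(scope="session")
def inputs():
    return default_inputs(seed=SEED, total_population=POP)


@pytest.fixture(scope="session")
def model(inputs):
    return MSLTModel(inputs, EngineConfig())


@pytest.fixture(scope="session")
def trajectories(inputs):
    return standard_trajectories(inputs.bmi_baseline, inputs.annual_mean_delta)


@pytest.fixture(scope="session")
def runs(model, trajectories):
    out = {name: model.run(traj) for name, traj in trajectories.items()}
    out["TMREL"] = model.run("tmrel")
    out["reference"] = model.run("baseline")
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210)
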