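import numpy as np
import pytest

from pulhaplo import build_reference, make_group_references, simulate_cohort
from pulhaplo.config import PipelineConfig
from pulhaplo.groups import GroupProfile
from pulhaplo.simulate import SimulationConfig


@pytest.fixture(scope="session")
def base_ref():
    return build_reference(7)


@pytest.fixture(scope="session")
def sim_cfg():
    return SimulationConfig(seed=7, n_samples=30, prevalence=0.5,
                            seq_error_rate=0.0)


@pytest.fixture(scope="session")
def group_refs(base_ref, sim_cfg):
    return make_group_references(base_ref, sim_cfg)


@pytest.fixture(scope="session")
def profiles(group_refs):
    return {g: GroupProfile.from_reference(g, group_refs[g])
            for g in ("GI", "GII", "GIII")}


@pytest.fixture(scope="session")
def small_cohort(sim_cfg, group_refs):
    return simulate_cohort(sim_cfg, group_refs)


@pytest.fixture(scope="session")
def pipeline_cfg():
    return PipelineConfig(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
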