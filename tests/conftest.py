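import numpy as np
import pytest

import aslrepro as ar


def zero_plan() -> ar.VariancePlan:
    """Variance plan with every component switched off."""
    return ar.VariancePlan(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def default_phantom() -> ar.Phantom:
    return ar.build_phantom(ar.PhantomSpec())


@pytest.fixture(scope="session")
def small_phantom() -> ar.Phantom:
    return ar.build_phantom(ar.PhantomSpec(grid_shape=(16, 16, 8), seed=7))


@pytest.fixture(scope="session")
def study_report() -> ar.StudyReport:
    """Full default study replica (4 subjects x 3 sessions x 2 runs).

    Session-scoped: the replica takes a couple of minutes and is shared by
    the pipeline smoke tests and the planted-activation checks.
    """
    return ar.run_study(ar.StudyConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
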