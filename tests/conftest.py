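import numpy as np
import pandas as pd
import pytest

from cmsehrv import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two subjects, one hour, short segments: exercises the full tabular
    path quickly."""
    spec = synth.CohortSpec(n_subjects=2, seed=11, hours=(21,),
                            hour_duration_s=300.0)
    return synth.generate_cohort(spec), spec


@pytest.fixture(scope="session")
def linear_fm():
    """A 50x10 random design with a known linear response (no noise)."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((50, 10))
    fm = pd.DataFrame(X, columns=[f"f{i}" for i in range(10)])
    fm["lvef_pct"] = 2.0 * X[:, 3]
    return fm
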