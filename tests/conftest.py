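import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# degenerate-ROI warnings are part of several contracts under test
warnings.filterwarnings("ignore", message=".*ROI too small.*")


@pytest.fixture(scope="session")
def small_cohort():
    """Four phantom subjects (2 x grade III, 2 x grade IV) on a 32 grid."""
    from gliorad.phantom import PhantomConfig, generate_cohort

    cfg = PhantomConfig(n_grade3=2, n_grade4=2, grid_shape=(32, 32, 32), seed=5)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def one_subject(small_cohort):
    from gliorad.extract import preprocess_subject

    return preprocess_subject(small_cohort[2])  # a grade IV subject


def make_table(n0, n1, p, seed, informative=0, shift=1.5):
    """Synthetic feature table: standard-normal noise with an optional block
    of informative columns mean-shifted in the grade-IV rows."""
    from gliorad.extract import FeatureTable
    from gliorad.registry import FeatureDescriptor

    rng = np.random.default_rng(seed)
    n = n0 + n1
    X = rng.standard_normal((n, p))
    X[n0:, :informative] += shift
    grades = np.array(["III"] * n0 + ["IV"] * n1, dtype=object)
    descs = [
        FeatureDescriptor("CE-T1", "orig", None, "intensity", f"f{i}") for i in range(p)
    ]
    return FeatureTable(
        [f"s-{i:03d}" for i in range(n)], grades, ["primary"] * n, descs, X
    )
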