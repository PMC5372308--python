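import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mirmeta.datatypes import StudyMatrix
from mirmeta.simulate import SimulationSpec, simulate_meta_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_study(values, classes, study_id="s1", features=None, samples=None):
    """Build a StudyMatrix from a plain array and class tokens."""
    values = np.asarray(values, dtype=float)
    f, n = values.shape
    features = features or [f"m{i+1}" for i in range(f)]
    samples = samples or [f"{study_id}_x{j+1}" for j in range(n)]
    df = pd.DataFrame(values, index=pd.Index(features, name="feature_id"),
                      columns=samples)
    return StudyMatrix(
        study_id=study_id,
        values=df,
        sample_classes=pd.Series(list(classes), index=samples),
    )


@pytest.fixture
def toy_study():
    """4 features x 6 samples, 3 tumor + 3 normal."""
    rng = np.random.default_rng(0)
    return make_study(rng.normal(8, 1, size=(4, 6)), "TTTNNN")


@pytest.fixture
def small_meta():
    """3 synthetic studies, 40 features, 10 planted DE."""
    spec = SimulationSpec(
        n_studies=3, n_features=40, n_case=10, n_control=10, n_de=10,
        effect_g=2.0, seed=123,
    )
    return simulate_meta_dataset(spec)
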