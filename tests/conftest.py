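import numpy as np
import pytest

import rehabdss as r
from rehabdss.synthetic import GenerationSpec


@pytest.fixture(scope="session")
def session_library() -> r.CaseLibrary:
    """Small session-level library with all three modes populated."""
    return r.generate_case_library(
        GenerationSpec(
            n_patients=40, sessions_per_patient=5, samples_per_session=300, seed=7
        )
    )


@pytest.fixture(scope="session")
def feature_library() -> r.CaseLibrary:
    """Feature-level library: 2 informative + 18 noise columns, 5% label noise."""
    return r.generate_feature_library(400, mode="passive", label_noise=0.05, seed=11)


@pytest.fixture(scope="session")
def fitted_models(session_library) -> dict:
    return {m: r.fit_level_model(session_library, m) for m in r.Mode}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
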