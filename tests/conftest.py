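import numpy as np
import pytest

from qeegnfb.synthetic import SubjectParams, make_normative_reference


@pytest.fixture(scope="session")
def base_params() -> SubjectParams:
    return SubjectParams(
        subject_id="t001",
        age=30.0,
        sex="male",
        iapf_true=10.0,
        alpha_amp_ec=6.0,
        alpha_amp_eo=1.5,
    )


@pytest.fixture(scope="session")
def normative_reference():
    return make_normative_reference()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
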