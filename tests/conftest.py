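import numpy as np
import pytest

from kwgphc import GammaPrior, KumaraswamyGPHC
from kwgphc.datasets import shasta_censored, shasta_full, shasta_gphc_sample

# printed real-data reference values: (alpha, beta, reliability at t=T)
TABLE4_MLE = {
    "I": (3.258854, 2.163197, 0.341358),
    "II": (2.898993, 1.425335, 0.443953),
    "III": (3.145385, 1.706230, 0.115402),
}


@pytest.fixture(scope="session")
def shasta42():
    return shasta_full()


@pytest.fixture(scope="session")
def shasta21():
    return shasta_censored()


@pytest.fixture(scope="session")
def case_models():
    """One fitted model per illustration case of the Shasta subsample."""
    out = {}
    for case in ("I", "II", "III"):
        model = KumaraswamyGPHC(shasta_gphc_sample(case))
        out[case] = (model, model.fit())
    return out


@pytest.fixture(scope="session")
def case2_model(case_models):
    """The Case II model: the only one with a nonzero censoring term E(alpha)."""
    return case_models["II"][0]


@pytest.fixture
def noninformative():
    return GammaPrior.noninformative()


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
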