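import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from flornet.data_model import ConditionKey, ExpressionDataset
from flornet.ode_models import model_spec
from flornet.synthetic_data import GeneratorConfig, generate_mechanistic, generate_phenomenological

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

WT_SCOPE = [ConditionKey("WT", "LD"), ConditionKey("WT", "SD")]


@pytest.fixture(scope="session")
def pheno_dataset():
    return generate_phenomenological(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def mech_dataset():
    """Noise-free MC-generated wild-type data (exactly model-consistent)."""
    return generate_mechanistic(model_spec("MC"))


@pytest.fixture()
def tiny_dataset():
    """Three DET observations in one condition."""
    frame = pd.DataFrame({
        "gene": "DET", "tissue": "apex", "genotype": "WT", "photoperiod": "LD",
        "time": [7.0, 14.0, 21.0], "mean": [2.0, 4.0, 8.0], "sd": [0.2, 0.4, 0.8],
    })
    return ExpressionDataset(frame)
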