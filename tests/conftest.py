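import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from iodapport import synthgen

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def gen_config():
    return synthgen.GeneratorConfig(seed=20150)


@pytest.fixture(scope="session")
def demo_dir(tmp_path_factory, gen_config):
    """A full synthetic demo dataset written once per session."""
    out = tmp_path_factory.mktemp("demo")
    truth = synthgen.generate_dataset(gen_config, out)
    return out, truth


@pytest.fixture()
def simple_measurements():
    return pd.DataFrame({
        "sample_id": ["a", "b", "c", "d"],
        "item": ["maize grain", "maize grain", "fish", "water"],
        "group": ["grain", "grain", "fish", "water"],
        "basis": ["DW", "DW", "DW", "liquid"],
        "value": [0.004, 0.02, 0.51, np.nan],
        "below_lod": [False, False, False, True],
    })
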