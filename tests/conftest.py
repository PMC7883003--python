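import numpy as np
import pytest

from counterbart import cohort


@pytest.fixture(scope="session")
def default_study():
    """One five-experiment synthetic study at the default cohort sizes."""
    spec = cohort.GeneratorSpec()
    tables, manifest = cohort.generate_study(spec, seed=20240)
    return spec, tables, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
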