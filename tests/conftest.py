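import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from otosr.groups import qda_fit
from otosr.io import load_fish_records, load_water_baseline


@pytest.fixture(scope="session")
def baseline_sites():
    """The bundled 29-site water baseline."""
    return load_water_baseline()


@pytest.fixture(scope="session")
def fish_records():
    return load_fish_records()


@pytest.fixture(scope="session")
def baseline_qda(baseline_sites):
    """Discriminant fitted on the full 28-site training set."""
    return qda_fit(baseline_sites, include_predicted=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20150708)
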