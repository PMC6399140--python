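import numpy as np
import pytest

import msdyn as m


@pytest.fixture(scope="session")
def planted_templates():
    return m.make_templates(31, 4, seed=1)


@pytest.fixture(scope="session")
def short_subject():
    """One 60 s synthetic subject at snr=4 plus its ground truth."""
    cfg = m.SimulationConfig(duration=60.0, snr=4.0, seed=11)
    rec, truth = m.simulate_subject(cfg)
    return rec, truth


@pytest.fixture(scope="session")
def diag_chain():
    """Strongly diagonal 4-state transition matrix (first-order null)."""
    t = np.full((4, 4), 0.1)
    np.fill_diagonal(t, 0.7)
    return t
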