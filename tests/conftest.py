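import numpy as np
import pytest

import lineattractor as la


@pytest.fixture(scope="session")
def default_session():
    """Standard synthetic line-attractor session (intruder-bout schedule)."""
    return la.generate_line_attractor_session(la.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def quiet_session():
    """Session without intruder input (post-removal epoch) for stimulation
    experiments."""
    cfg = la.GeneratorConfig(n_frames=3000, input_schedule=np.zeros(3000),
                             seed=3)
    return la.generate_line_attractor_session(cfg)


@pytest.fixture(scope="session")
def multi_bout_table():
    """Six attack bouts, enough trials for a well-behaved shuffle null."""
    return la.BoutTable.from_intervals(
        [(40 + k * 90, 70 + k * 90) for k in range(6)])
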