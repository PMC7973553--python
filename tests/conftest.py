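import numpy as np
import pytest

import osrt


@pytest.fixture(scope="session")
def table():
    return osrt.semantic_table(osrt.SEQUENCE_A, osrt.SEQUENCE_B)


@pytest.fixture(scope="session")
def fs_stream():
    return osrt.build_fs_stream()


@pytest.fixture(scope="session")
def noise_free_participant(fs_stream):
    """One noise-free simulated FS participant plus its classified records."""
    params = osrt.default_scenarios()["fs-learner"].noise_free()
    gaze, events, truth = osrt.simulate_participant(params, fs_stream, seed=7)
    table = osrt.semantic_table()
    records = osrt.classify_isis(gaze, events, fs_stream, table)
    return {"params": params, "gaze": gaze, "events": events,
            "truth": truth, "records": records}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
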