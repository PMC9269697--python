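import numpy as np
import pytest

import mobiso as m


COHORT_SEED = 2


@pytest.fixture(scope="session")
def cohort():
    """Four contrasting users, two simulated days: traces plus feature tables.

    Session-scoped because trace generation and window extraction dominate
    suite runtime; tests must not mutate the returned objects.
    """
    profiles = m.make_profiles(4, seed=COHORT_SEED)
    config = m.SynthConfig(n_users=4, days=2, seed=COHORT_SEED)
    traces = m.generate_traces(profiles, config)
    indoor_tab, outdoor_tab = m.build_feature_table(
        indoor=traces.indoor, outdoor=traces.outdoor
    )
    labels = m.labels_to_frame(traces.labels)
    return {
        "profiles": profiles,
        "config": config,
        "traces": traces,
        "indoor_tab": indoor_tab,
        "outdoor_tab": outdoor_tab,
        "labels": labels,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
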