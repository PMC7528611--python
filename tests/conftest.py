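import numpy as np
import pytest

import circuitclock as cc
from circuitclock.synthetic import AcuteProtocol, electrical_components

CLASSES = [
    "GABA_inhibited",
    "Mixed",
    "GABA_activated",
    "Glu_activated",
    "Glu_disinhibited",
    "non_responsive",
]


@pytest.fixture(scope="session")
def acute_session_sixpack():
    """One simulated acute session with one unit per response class."""
    specs = [
        cc.CellSpec(
            f"u{i}",
            true_class=cls,
            baseline_rate=5.0,
            components=electrical_components(cls),
            dv_offset=100.0 * i,
        )
        for i, cls in enumerate(CLASSES)
    ]
    session, truth = cc.simulate_session(specs, AcuteProtocol(opto=False), seed=11)
    return session, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
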