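import numpy as np
import pytest

from ovigait import calibrate_template, simulate_session

SAMPLING_RATE = 50.0
BODY_WEIGHT = 57.9


@pytest.fixture
def control_hind_template():
    """Healthy hindlimb template: peak 42 / mean 28 %BW, 0.58 s, M-shaped."""
    return calibrate_template(42.0, 28.0, 0.58, SAMPLING_RATE, style="m_shape")


@pytest.fixture
def noise_free_session(control_hind_template):
    """One 8-phase noise-free hindlimb recording with its generation truth."""
    rng = np.random.default_rng(11)
    sims = simulate_session(
        {"IH": control_hind_template},
        n_phases=8,
        noise_cv=0.0,
        body_weight=BODY_WEIGHT,
        rng=rng,
        sampling_rate=SAMPLING_RATE,
        animal_id="A1",
        day_postop=7,
        session_id="A1-d007",
    )
    return sims["IH"]
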