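import numpy as np
import pytest

from sivent import VirtualPatientConfig, generate_patient_stream

CLEAN_CONFIG = VirtualPatientConfig(
    noise_sd=0.0, asynchrony_rate=0.0, log_walk_sd=0.0, seed=7
)


@pytest.fixture(scope="session")
def clean_stream():
    """20 noise-free VC breaths at RR 15 (E 33.8, R 9.8, PEEP 10, 65 kg)."""
    stream, truth = generate_patient_stream(CLEAN_CONFIG, n_intervals=1, interval_len=80.0)
    return stream, truth


@pytest.fixture(scope="session")
def transition_pairs():
    """Synthetic elastance transitions with a known conditional law.

    x = y * exp(eps), eps ~ N(0, 0.1^2), y ~ U(10, 70); 500 train / 200 test.
    """
    rng = np.random.default_rng(42)
    y = rng.uniform(10.0, 70.0, 700)
    x = y * np.exp(rng.normal(0.0, 0.1, 700))
    pairs = np.column_stack([y, x])
    return pairs[:500], pairs[500:]
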