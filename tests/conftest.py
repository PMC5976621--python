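import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_transcripts():
    """Ten short labelled transcripts, five per origin."""
    from holopart import CompositionModel, SimulationConfig, generate_transcriptome

    cfg = SimulationConfig(length_min=60, length_max=120, seed=5)
    host = generate_transcriptome(
        CompositionModel(label="host", gc_target=0.43), 5, cfg, seed=5)
    sym = generate_transcriptome(
        CompositionModel(label="symbiont", gc_target=0.54), 5, cfg, seed=6,
        id_prefix="symbiont")
    return host + sym
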