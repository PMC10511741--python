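import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small noiseless cohort with a strong effect, shared across tests."""
    from thermonet.synthgen import GeneratorConfig, generate_arrays

    cfg = GeneratorConfig(
        n_subjects_per_class=4, image_size=32, effect_size=0.35, noise_sd=0.0, seed=11
    )
    manifest, X = generate_arrays(cfg)
    y = (manifest["label"] == "RA").to_numpy().astype(int)
    return cfg, manifest, X, y
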