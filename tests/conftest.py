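import pytest
from hypothesis import HealthCheck, settings

from lumbargait import GaitSimConfig, run_pipeline, simulate_recording

settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_default():
    """One default-protocol simulated subject with ground truth."""
    cfg = GaitSimConfig(seed=1)
    rec, truth = simulate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def pipeline_default(sim_default):
    """Full pipeline result on the default simulated subject."""
    _, rec, _ = sim_default
    return run_pipeline(rec)


@pytest.fixture(scope="session")
def sim_clean():
    """Noise-free simulated subject (exact signal morphology checks)."""
    cfg = GaitSimConfig(seed=2, noise_sd=0.0, gyro_noise_sd=0.0)
    rec, truth = simulate_recording(cfg)
    return cfg, rec, truth
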