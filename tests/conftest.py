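import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import plumekin as pk

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_small_config() -> pk.SynthConfig:
    """Small noiseless cloud following the pure decay law (no diffusion switch)."""
    return pk.SynthConfig(
        amplitude=1000.0,
        decay_rate=22.0,
        offset=0.0,
        frame_width=480,
        frame_height=240,
        duration=0.15,
        n_particles=250,  # dense seeding: several particles per window
        n_large_droplets=0,
        noise_sd=0.0,
        diffusion_sd=0.0,
        momentum_floor=0.0,
        mouth_position=(20.0, 80.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_small_truth(noiseless_small_config):
    return pk.simulate_trajectories(noiseless_small_config)


@pytest.fixture(scope="session")
def noiseless_small_frames(noiseless_small_config, noiseless_small_truth):
    return pk.render_frames(noiseless_small_truth, noiseless_small_config)


@pytest.fixture(scope="session")
def noiseless_small_fields(noiseless_small_frames):
    seq = noiseless_small_frames
    return [
        pk.compute_vector_field(seq.frame(i), seq.frame(i + 1))
        for i in range(seq.n_frames - 1)
    ]
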