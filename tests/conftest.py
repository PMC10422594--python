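import numpy as np
import pytest

import radarhrv as rh


@pytest.fixture(scope="session")
def chirp_cfg() -> rh.ChirpConfig:
    return rh.ChirpConfig()


@pytest.fixture(scope="session")
def clean_record(chirp_cfg):
    """One noise-free 20 s simulated record shared across tests:
    (motion, cube, demodulated 250 Hz displacement)."""
    ibis = rh.generate_ibis(22, seed=11)
    motion = rh.synthesize_motion(ibis, seed=12)
    cube = rh.synthesize_if_cube(motion, chirp_cfg)
    phase = rh.demodulate_cube(cube, motion.nominal_range_r0, motion.azimuth_theta)
    phase250 = rh.resample_to(phase, 250.0)
    return motion, cube, phase250


@pytest.fixture(scope="session")
def tiled_instance():
    from radarhrv.pipeline import make_tiled_instance

    return make_tiled_instance(seed=42)
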