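import numpy as np
import pytest

from hifumap import (AcquisitionMeta, APMovieConfig, EnvelopeSequence,
                     SpecklePhantomConfig, simulate_ap_movie,
                     simulate_speckle_sequence)


def small_speckle_config(**overrides) -> SpecklePhantomConfig:
    """Scaled-down speckle phantom: same acquisition clock, smaller grid."""
    kw = dict(shape=(60, 40), lesion_center=(30.0, 20.0),
              lesion_semiaxes=(15.0, 8.0))
    kw.update(overrides)
    return SpecklePhantomConfig(**kw)


def small_ap_config(**overrides) -> APMovieConfig:
    """Scaled-down AP movie: 40×40 px, 12 s (baseline + ablation + recovery)."""
    kw = dict(shape=(40, 40), duration_s=12.0, lesion_center=(20.0, 20.0),
              lesion_semiaxes=(10.0, 7.0))
    kw.update(overrides)
    return APMovieConfig(**kw)


@pytest.fixture(scope="session")
def speckle_phantom():
    cfg = small_speckle_config()
    env, mask = simulate_speckle_sequence(cfg, seed=11)
    return cfg, env, mask


@pytest.fixture(scope="session")
def clean_ap_movie():
    """Noiseless, drift-free movie with lesion — generative identities hold."""
    cfg = small_ap_config(noise_sd=0.0, drift_linear_per_s=0.0, drift_exp_amp=0.0)
    movie, truth, mask = simulate_ap_movie(cfg, seed=7)
    return cfg, movie, truth, mask


@pytest.fixture(scope="session")
def noisy_ap_movie():
    cfg = small_ap_config()
    movie, truth, mask = simulate_ap_movie(cfg, seed=7)
    return cfg, movie, truth, mask


@pytest.fixture()
def flat_envelope():
    meta = AcquisitionMeta(frame_rate_hz=11.0, pixel_spacing_um=(50.0, 100.0),
                           time_origin_s=4.0, ablation_window_s=(4.5, 8.5))
    return EnvelopeSequence(frames=np.full((8, 12, 10), 2.0), meta=meta)
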