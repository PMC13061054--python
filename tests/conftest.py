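import numpy as np
import pytest

from mitophen import synthetic_data as syn


@pytest.fixture(scope="session")
def default_acq() -> syn.AcquisitionParams:
    return syn.AcquisitionParams()


@pytest.fixture(scope="session")
def small_movie_acq() -> syn.AcquisitionParams:
    """Cheap movie acquisition for unit tests (full field, fewer frames)."""
    return syn.AcquisitionParams(n_frames=12)


@pytest.fixture(scope="session")
def wt_movie(small_movie_acq):
    return syn.generate_anaphase_movie(
        syn.get_preset("wt"), small_movie_acq, seed=7
    )


@pytest.fixture(scope="session")
def clean_wt_movie(small_movie_acq):
    """Noiseless, jitter-free movie for exact-recovery checks."""
    return syn.generate_anaphase_movie(
        syn.get_preset("wt"), small_movie_acq, seed=7,
        jitter=False, apply_noise=False,
    )


@pytest.fixture(scope="session")
def monopole_image(default_acq):
    return syn.generate_monopolar_image(
        syn.get_preset("gfp_ctrl"), default_acq, seed=11
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
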