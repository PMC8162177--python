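import numpy as np
import pytest

from prefcorr3d import (
    SpaceConfig,
    build_generative_space,
    make_participant,
    random_preference,
    simulate_ratings,
    synthesize_stimuli,
)
from prefcorr3d.space import Cell, GenerativeSpaceSpec


@pytest.fixture(scope="session")
def desk_space():
    """Default desk-scale space (500 vertices, 40 shape dims, 80x60 grid)."""
    return build_generative_space(seed=1)


@pytest.fixture(scope="session")
def small_space():
    """Reduced space for expensive end-to-end tests."""
    cfg = SpaceConfig(
        n_vertices=60, n_shape_dims=8, n_complexion_dims=6, n_sf_bands=3,
        texture_shape=(48, 64),
    )
    return build_generative_space(cfg, seed=5)


@pytest.fixture(scope="session")
def small_stimuli(small_space):
    return synthesize_stimuli(small_space, 600, seed=11)


@pytest.fixture(scope="session")
def linear_rater(small_space, small_stimuli):
    """One simulated rater with a planted linear preference at drive SNR 2."""
    rng = np.random.default_rng(21)
    ws, wc = random_preference(small_space, rng)
    p = make_participant(small_space, "p_lin", "WE", "WE", ws, wc, snr=2.0, seed=77)
    rated = simulate_ratings(p, small_stimuli, small_space)
    return p, rated


def make_identity_space(n_vertices=2, n_complexion_dims=6):
    """Hand-fixture space whose bases are identity matrices.

    Vertex and pixel maps of a model then equal its beta2 entries directly,
    which makes sign-rule and rank-correlation fixtures hand-checkable.
    """
    nv = n_vertices
    k = nv * 3
    h, w = 1, 2
    kc = n_complexion_dims
    assert kc == h * w * 3
    cfg = SpaceConfig(
        n_vertices=nv, n_shape_dims=k, n_complexion_dims=kc, n_sf_bands=1,
        texture_shape=(h, w),
    )
    cells = {
        "WE_female": Cell("WE", "female", np.zeros((nv, 3)), np.zeros((h, w, 3))),
        "WE_male": Cell("WE", "male", np.ones((nv, 3)), np.ones((h, w, 3))),
    }
    return GenerativeSpaceSpec(
        config=cfg, seed=0, cells=cells, faces=np.zeros((0, 3), dtype=np.int64),
        shape_basis=np.eye(k), complexion_bases=[np.eye(kc)],
        band_edges=[(0.0, 0.5)],
        shape_coeff_scale=np.ones(k),
        complexion_coeff_scale=np.ones((kc, 1)),
    )
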