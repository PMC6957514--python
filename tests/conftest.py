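"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

import memkin as mk

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def lattice_movie():
    """Small lattice-border movie with moderate event statistics.

    Frame interval chosen so k_tot * dt ~ 0.2 (frame sampling resolves
    individual events); ~32 bins * 4.3/s * 5 s = ~700 events.
    """
    params = mk.LatticeSimParams(
        n_frames=100,
        frame_interval=0.05,
        n_theta=32,
        grid_size_px=(224, 224),
        pixel_size=2.0,
        patch_radius=190.0,
        init_lattice_radius=95.0,
        seed=42,
    )
    movie, log = mk.generate_afm_lattice_movie(params)
    return params, movie, log


@pytest.fixture(scope="session")
def rate_movie():
    """Larger movie sized for rate recovery (>= 2000 pooled events)."""
    params = mk.LatticeSimParams(
        n_frames=200,
        frame_interval=0.05,
        n_theta=64,
        grid_size_px=(256, 256),
        pixel_size=2.0,
        patch_radius=180.0,
        init_lattice_radius=90.0,
        k_assoc=2.3,
        k_dissoc=2.0,
        seed=1,
    )
    movie, log = mk.generate_afm_lattice_movie(params)
    return params, movie, log


@pytest.fixture(scope="session")
def frap_default():
    params = mk.FRAPSimParams(D_true=2.6, seed=3)
    series, log = mk.generate_frap_series(params)
    return params, series, log


@pytest.fixture(scope="session")
def guv_default():
    params = mk.GUVSimParams(gp_true=0.17, g_factor=1.0 / 3.0, seed=5)
    imgs, log = mk.generate_guv_images(params)
    return params, imgs, log


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
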