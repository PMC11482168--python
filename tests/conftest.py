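"""Shared fixtures: small optical configs and synthetic stacks.

Everything is generated programmatically; session-scoped fixtures cache
the more expensive phantom renderings so the whole suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

import holodop as hd


@pytest.fixture(scope="session")
def small_config() -> hd.OpticalConfig:
    return hd.OpticalConfig(n_lateral=64)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_stack() -> hd.ComplexFieldStack:
    """Mid-size optic-nerve-head phantom used by the sensing tests.

    160 px with a 5x5 grid gives 32-px subapertures that tile the pupil
    exactly.
    """
    scene = hd.default_scene(image_size=160, seed=11)
    return hd.generate_phantom_stack(scene, n_frames=48, noise_level=0.05)


@pytest.fixture(scope="session")
def mesh_image() -> np.ndarray:
    """Power-Doppler image of an isotropic capillary-mesh phantom."""
    stack = hd.generate_phantom_stack(hd.mesh_scene(seed=7), n_frames=48)
    return hd.power_doppler(hd.svd_clutter_filter(stack, 2)).power


@pytest.fixture(scope="session")
def sensing_160(phantom_stack) -> hd.SensingResult:
    """One unaberrated sensing pass on the 160-px phantom, 5x5 grid."""
    return hd.sense_shifts(phantom_stack, n_side=5)


def make_random_field(rng, n_frames=4, n=32,
                      config=None) -> hd.ComplexFieldStack:
    field = rng.standard_normal((n_frames, n, n)) \
        + 1j * rng.standard_normal((n_frames, n, n))
    if config is None:
        config = hd.OpticalConfig(n_lateral=n)
    return hd.ComplexFieldStack(field, hd.Plane.IMAGE, 0.0, config)
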