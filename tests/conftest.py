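"""Shared fixtures: phantoms and their segmentations are expensive, so they
are generated once per session and reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from neseg.phantom import PhantomParams, generate_phantom
from neseg.volume import segment_volume


@pytest.fixture(scope="session")
def easy_phantom():
    """Low-deformation full-size phantom with default study parameters."""
    params = PhantomParams(seed=1)
    stack, gt, envelope = generate_phantom(params)
    return stack, gt, envelope, params


@pytest.fixture(scope="session")
def easy_nucleus(easy_phantom):
    stack, _, _, _ = easy_phantom
    return segment_volume(stack)


@pytest.fixture(scope="session")
def notched_phantom():
    """Phantom with a polar groove deep enough to split near-pole
    cross-sections into disjoint islands."""
    params = PhantomParams(seed=5, notch_depth=25.0, notch_width=12.0)
    stack, gt, envelope = generate_phantom(params)
    return stack, gt, envelope, params


@pytest.fixture(scope="session")
def notched_nucleus(notched_phantom):
    stack, _, _, _ = notched_phantom
    return segment_volume(stack)


@pytest.fixture(scope="session")
def small_phantom():
    """Quick phantom for I/O, alignment and pipeline tests."""
    params = PhantomParams(shape=(128, 128, 30), nucleus_radius=48.0, seed=3)
    stack, gt, envelope = generate_phantom(params)
    return stack, gt, envelope, params


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
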