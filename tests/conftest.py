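"""Shared fixtures: small synthetic plants and camera rings.

The "small" plant (96 x 96 x 128 grid, 3 leaves) keeps unit tests fast;
the full-scale default plant (192 x 192 x 256, 5 leaves) is built once
per session for the tests that need production geometry.
"""

from __future__ import annotations

import numpy as np
import pytest

from phenovox import synthetic as syn


SMALL_SPEC = syn.SyntheticPlantSpec(
    grid_dims=(96, 96, 128),
    stem_height=95,
    n_leaves=3,
    node_heights=(30.0, 45.0, 60.0),
    leaf_arc_lengths=(36.0, 32.0, 28.0),
    tlc_radius=9.0,
    tlc_height=8.0,
    leaf_width=4.0,
    stem_radius_base=3.2,
    stem_radius_top=2.2,
)


@pytest.fixture(scope="session")
def small_model() -> syn.LabeledModel:
    return syn.make_plant(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_cameras(small_model):
    return syn.default_cameras(
        small_model, n_views=8, image_size=(480, 480), focal=1200.0
    )


@pytest.fixture(scope="session")
def default_model() -> syn.LabeledModel:
    return syn.make_plant(syn.SyntheticPlantSpec())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def grid_bounds(model: syn.LabeledModel):
    lo = tuple(model.grid.origin)
    hi = tuple(model.grid.origin + np.array(model.grid.dims) * model.grid.edge)
    return (lo, hi)
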