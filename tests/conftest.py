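"""Shared fixtures: small models sized so the whole suite runs in minutes.

The 'tiny' configurations (1-2 deg patches) exercise every code path at
negligible cost; the full-size mosaic is cheap to generate (only the
cascade is expensive) and is session-scoped where needed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from orisel.params import ModelParams, MosaicSpec
from orisel.mosaic import build_channel_array, ChannelArray
from orisel.dynamics import default_model


@pytest.fixture(scope="session")
def tiny_spec() -> MosaicSpec:
    """1 deg half-width patch: 221 channels."""
    return MosaicSpec(patch_half_width=1.0, seed=3)


@pytest.fixture(scope="session")
def tiny_params() -> ModelParams:
    return dataclasses.replace(ModelParams(), cortical_spacing=0.2)


@pytest.fixture(scope="session")
def tiny_model(tiny_spec, tiny_params):
    return default_model(tiny_spec, tiny_params)


@pytest.fixture(scope="session")
def standard_array() -> ChannelArray:
    """The standard 8x8 deg mosaic (3281 channels), seed 1."""
    return build_channel_array(MosaicSpec(seed=1))


def two_channel_model(offset: float = 0.2, half_width: float = 1.0):
    """One on- and one off-channel straddling a single cortical node."""
    from orisel.dynamics import CorticalSheet, Model
    spec = MosaicSpec(patch_half_width=half_width, seed=0)
    channels = ChannelArray(
        x=np.array([-offset / 2, offset / 2]),
        y=np.zeros(2),
        sign=np.array([1, -1]),
        spec=spec,
    )
    params = dataclasses.replace(ModelParams(), cortical_spacing=0.2)
    sheet = CorticalSheet(half_width=0.01, spacing=0.2)
    return Model(params, channels, sheet)
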