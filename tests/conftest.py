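"""Shared fixtures.

The default torso phantom and its reciprocal lead fields are expensive
(eight multigrid solves on a ~500k-node system), so they are built once per
session and shared by the integration and acceptance tests. Unit tests use
tiny block models instead.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardioloc.forward import assemble_system
from cardioloc.leadfield import (LEADS_INDEPENDENT, build_leadfield,
                                 place_candidates, reciprocal_lead_fields)
from cardioloc.synth import HEART_LABEL, PhantomSpec, build_phantom
from cardioloc.voxelmodel import VoxelModel


@pytest.fixture(scope="session")
def phantom():
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def system(phantom):
    return phantom.assemble()


@pytest.fixture(scope="session")
def fields(phantom, system):
    return reciprocal_lead_fields(system, phantom.montage, LEADS_INDEPENDENT)


@pytest.fixture(scope="session")
def lfm(phantom, system, fields):
    grid = place_candidates(phantom.model, HEART_LABEL, spacing=2)
    return build_leadfield(system, grid, phantom.montage, LEADS_INDEPENDENT,
                           fields=fields)


def make_block_model(outer: int = 8, tissue_label: int = 3,
                     heart: tuple | None = None, pitch: float = 1.0) -> VoxelModel:
    """Cube of tissue with a 1-voxel air shell; optional heart sub-block.

    ``heart`` is (lo, hi) voxel bounds of a heart-labeled cube.
    """
    labels = np.zeros((outer, outer, outer), dtype=np.uint8)
    labels[1:-1, 1:-1, 1:-1] = tissue_label
    if heart is not None:
        lo, hi = heart
        labels[lo:hi, lo:hi, lo:hi] = HEART_LABEL
    return VoxelModel(labels=labels, pitch=pitch)


@pytest.fixture()
def block_model():
    return make_block_model()
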