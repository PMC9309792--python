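"""Shared fixtures: synthetic volumes, extracted geometry, assembled models.

Everything is generated programmatically from the synthetic-spine module;
heavy stages are session-scoped so the suite builds each spine once.
"""

from __future__ import annotations

import numpy as np
import pytest

from spineforge import extract_all
from spineforge.anatomy import assemble_model, load_param_json
from spineforge.mass_model import assign_to_levels, bone_mass, classify_tissues, scale_generic_segments
from spineforge.synthetic_spine import (
    LEVELS,
    SpineParams,
    generate_spine_volume,
    generate_tissue_volume,
)


def _build_model(params: SpineParams):
    inst, sub = generate_spine_volume(params)
    tis = generate_tissue_volume(params, inst)
    geoms, tr = extract_all(inst, sub)
    tissue = classify_tissues(tis, bone_mask=inst.voxels > 0)
    segs = assign_to_levels(tissue, geoms, transform=tr)
    bones = {lev: bone_mass(inst, lev) for lev in LEVELS}
    torso = sum(s.mass_kg for s in segs) + sum(bones.values())
    generic = scale_generic_segments(1.75, torso, load_param_json("anthropometry"))
    return assemble_model(geoms, segs, generic, bones)


@pytest.fixture(scope="session")
def straight_params():
    return SpineParams(seed=7)


@pytest.fixture(scope="session")
def lordotic_params():
    return SpineParams(lumbar_lordosis_deg=29.0, thoracic_kyphosis_deg=31.0, seed=7)


@pytest.fixture(scope="session")
def straight_volumes(straight_params):
    return generate_spine_volume(straight_params)


@pytest.fixture(scope="session")
def lordotic_volumes(lordotic_params):
    return generate_spine_volume(lordotic_params)


@pytest.fixture(scope="session")
def straight_geometry(straight_volumes):
    inst, sub = straight_volumes
    return extract_all(inst, sub)


@pytest.fixture(scope="session")
def lordotic_geometry(lordotic_volumes):
    inst, sub = lordotic_volumes
    return extract_all(inst, sub)


@pytest.fixture(scope="session")
def straight_model(straight_params):
    return _build_model(straight_params)


@pytest.fixture(scope="session")
def lordotic_model(lordotic_params):
    return _build_model(lordotic_params)


@pytest.fixture(scope="session")
def bare_straight_model(straight_model):
    """The straight-spine model stripped of passive elements and muscles.

    Handy for closed-form checks: joint loads reduce to the weight of the
    superstructure.
    """
    import copy

    m = copy.deepcopy(straight_model)
    m.ligaments = []
    m.muscles = []
    for d in m.discs.values():
        d.stiffness_nm_per_deg = np.zeros(3)
    return m
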