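"""Shared fixtures: phantoms and solved baselines at desk-scale voxel sizes.

Solves are session-scoped so the expensive ones run once.  Grids are kept
coarse (3-4 mm) wherever the check is about structure rather than
discretisation accuracy.
"""

from __future__ import annotations

import numpy as np
import pytest

from lesionfield import (
    Electrode,
    VolumeConductorModel,
    build_phantom,
    define_roi,
    place_electrodes,
    roi_stats,
    scalp_position,
)
from lesionfield.phantom import assign_conductivity

#: Default montage directions: anode over the vertex target, cathode over
#: the orbit-like position 70 deg away (mirrors a motor-cortex montage).
ANODE_DIR = np.array([0.0, 0.0, 1.0])
CATHODE_DIR = np.array([0.0, np.sin(np.radians(70.0)), np.cos(np.radians(70.0))])


def make_setup(voxel_size_mm: float, current_mA: float = 1.0, tol: float = 1e-8):
    """Phantom + vertex ROI + placed default montage + baseline solve."""
    ph = build_phantom(voxel_size_mm=voxel_size_mm)
    roi = define_roi(ph, (0.0, 0.0, 1.0))
    montage = [
        Electrode(tuple(scalp_position(ph, ANODE_DIR)), +current_mA),
        Electrode(tuple(scalp_position(ph, CATHODE_DIR)), -current_mA),
    ]
    placed = place_electrodes(ph, montage)
    sigma = assign_conductivity(placed)
    model = VolumeConductorModel(sigma, placed.electrode_voxels,
                                 [e.current_mA for e in montage])
    result = model.fit(tol=tol)
    stats = roi_stats(result.magnitude, result.efield, roi, ph.mask("gm"), ph)
    return dict(phantom=ph, roi=roi, montage=montage, placed=placed,
                sigma=sigma, model=model, result=result, stats=stats)


@pytest.fixture(scope="session")
def phantom2():
    return build_phantom(voxel_size_mm=2.0)


@pytest.fixture(scope="session")
def phantom3():
    return build_phantom(voxel_size_mm=3.0)


@pytest.fixture(scope="session")
def phantom4():
    return build_phantom(voxel_size_mm=4.0)


@pytest.fixture(scope="session")
def setup4():
    """Solved baseline on the 4 mm phantom (fast, shared)."""
    return make_setup(4.0)


@pytest.fixture(scope="session")
def setup3():
    """Solved baseline on the 3 mm phantom (shared)."""
    return make_setup(3.0)
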