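"""Fixtures with known ground truth: slab conductors, analytic fields,
planted-effect tables.

Every fixture ships its closed-form answer, so solver, analysis and trend
fitting can each be tested against an independent truth:

* layered-slab conductors obey the series-resistor law E_i = (I/A)/sigma_i;
* analytic field volumes (uniform / linear-potential / radial) have exact
  ROI statistics;
* planted-effect tables have known regression coefficients so trend
  recovery can be checked against the OLS sampling distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .phantom import LABELS, ConductivityVolume, LabelVolume
from .lesions import (DEFAULT_CONDUCTIVITIES, DEFAULT_GAPS_MM, DEFAULT_RADII_MM)

__all__ = ["SlabFixture", "PlantedEffectTable", "make_slab_fixture",
           "make_planted_table", "make_field_fixture"]


@dataclass
class SlabFixture:
    """Voxelised layered slab between full-face plate electrodes.

    The closed-form field in layer i at current density J = I/A is
    E_i = J / sigma_i, normal current continuous across the layers.
    """

    volume: LabelVolume
    sigma: ConductivityVolume
    electrode_voxels: list[np.ndarray]
    currents_mA: list[float]
    layer_masks: list[np.ndarray]
    #: layer masks eroded by one voxel along z: the central-difference
    #: gradient straddles material interfaces, so the closed form holds in
    #: the layer interiors
    layer_interior_masks: list[np.ndarray]
    expected_E_V_per_m: list[float]
    current_density_A_per_m2: float
    cross_section_mm2: float


def make_slab_fixture(thicknesses_mm, conductivities, current_density_A_per_m2=1.0,
                      cross_section_mm=(20.0, 20.0), voxel_size_mm=2.0) -> SlabFixture:
    """Layered slab along z with plate electrodes on both faces.

    ``current_density_A_per_m2`` is I/A; the injected current is derived
    from the cross-section.  Layers are stacked bottom (cathode side) to
    top (anode side).
    """
    thicknesses = [float(t) for t in thicknesses_mm]
    sigmas = [float(s) for s in conductivities]
    if len(thicknesses) != len(sigmas):
        raise ParameterError("one conductivity per layer required")
    if any(t <= 0 for t in thicknesses) or any(s <= 0 for s in sigmas):
        raise ParameterError("layer thicknesses and conductivities must be positive")

    h = float(voxel_size_mm)
    nx = max(int(round(cross_section_mm[0] / h)), 1)
    ny = max(int(round(cross_section_mm[1] / h)), 1)
    nz_layers = [max(int(round(t / h)), 1) for t in thicknesses]
    plate = 1  # one voxel of electrode material at each face
    nz = sum(nz_layers) + 2 * plate

    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    sigma = np.zeros((nx, ny, nz), dtype=float)
    labels[:, :, :plate] = LABELS["electrode"]
    labels[:, :, -plate:] = LABELS["electrode"]
    sigma[:, :, :plate] = 5.9e7
    sigma[:, :, -plate:] = 5.9e7

    layer_masks = []
    interior_masks = []
    z0 = plate
    # reuse head-tissue label codes for the slab layers (labels are cosmetic here)
    layer_codes = [LABELS["wm"], LABELS["gm"], LABELS["csf"], LABELS["skull"],
                   LABELS["skin"], LABELS["lesion"]]
    for li, (nzl, s) in enumerate(zip(nz_layers, sigmas)):
        mask = np.zeros((nx, ny, nz), dtype=bool)
        mask[:, :, z0:z0 + nzl] = True
        labels[mask] = layer_codes[li % len(layer_codes)]
        sigma[mask] = s
        layer_masks.append(mask)
        interior = np.zeros_like(mask)
        interior[:, :, z0 + 1:z0 + nzl - 1] = True
        interior_masks.append(interior)
        z0 += nzl

    origin = np.array([-(nx - 1) / 2.0 * h, -(ny - 1) / 2.0 * h, -(nz - 1) / 2.0 * h])
    volume = LabelVolume(labels=labels, voxel_size_mm=h, origin_mm=origin)
    sig = ConductivityVolume(sigma=sigma, voxel_size_mm=h, origin_mm=origin.copy())

    area_m2 = nx * ny * (h * 1e-3) ** 2
    current_A = current_density_A_per_m2 * area_m2
    flat = np.arange(labels.size).reshape(labels.shape)
    anode = flat[:, :, -plate:].ravel()   # top face injects
    cathode = flat[:, :, :plate].ravel()
    volume.electrode_voxels = [anode, cathode]

    expected = [current_density_A_per_m2 / s for s in sigmas]
    return SlabFixture(volume=volume, sigma=sig,
                       electrode_voxels=[anode, cathode],
                       currents_mA=[current_A * 1e3, -current_A * 1e3],
                       layer_masks=layer_masks,
                       layer_interior_masks=interior_masks,
                       expected_E_V_per_m=expected,
                       current_density_A_per_m2=current_density_A_per_m2,
                       cross_section_mm2=nx * ny * h * h)


@dataclass
class PlantedEffectTable:
    """Synthetic factorial results table with known linear structure."""

    table: pd.DataFrame
    coefficients: dict
    noise_sd: float
    seed: int


def make_planted_table(coefficients: dict | None = None, noise_sd: float = 1.0,
                       n_rows: int = 630, seed: int = 0) -> PlantedEffectTable:
    """Table of (angle, gap, radius, conductivity) rows with a planted response.

    The response is ``intercept + sum(coef * predictor) + N(0, noise_sd)``.
    Angles are drawn uniformly on [0, 180]; gap/radius/conductivity cycle
    through the default factorial grids.  Regeneration with the same seed
    is bit-identical.
    """
    if n_rows < 30:
        raise ParameterError("need at least 30 rows")
    coefs = {"intercept": 0.0, "angle_deg": -0.06, "gap_mm": 0.0,
             "radius_mm": 0.0, "conductivity_S_per_m": 0.0}
    if coefficients:
        coefs.update(coefficients)
    rng = np.random.default_rng(seed)
    angle = rng.uniform(0.0, 180.0, size=n_rows)
    gaps = np.array([DEFAULT_GAPS_MM[i % 3] for i in range(n_rows)])
    radii = np.array([DEFAULT_RADII_MM[(i // 3) % 3] for i in range(n_rows)])
    conds = np.array([DEFAULT_CONDUCTIVITIES[(i // 9) % 5] for i in range(n_rows)])
    lin = (coefs["intercept"] + coefs["angle_deg"] * angle + coefs["gap_mm"] * gaps
           + coefs["radius_mm"] * radii + coefs["conductivity_S_per_m"] * conds)
    noise = rng.normal(0.0, noise_sd, size=n_rows) if noise_sd > 0 else 0.0
    resp = lin + noise
    table = pd.DataFrame({
        "angle_deg": angle, "gap_mm": gaps, "radius_mm": radii,
        "conductivity_S_per_m": conds,
        "pct_diff": resp, "abs_pct_diff": np.abs(resp),
        "valid": True,
    })
    return PlantedEffectTable(table=table, coefficients=coefs,
                              noise_sd=noise_sd, seed=seed)


def make_field_fixture(profile: str, amplitude: float, volume: LabelVolume):
    """Analytic potential + E-field grids on an existing volume's geometry.

    Profiles
    --------
    ``uniform``
        E = (0, 0, amplitude) everywhere; potential -amplitude * z.
    ``linear``
        Alias of uniform (linear potential along z).
    ``radial``
        E points towards the head centre with constant magnitude
        ``amplitude`` (radially inward); potential = amplitude * r.

    Returns ``(potential, efield, magnitude)`` arrays with the exact ROI
    statistics implied by the profile.
    """
    if profile not in ("uniform", "linear", "radial"):
        raise ParameterError(f"unknown profile {profile!r}")
    ax = [volume.axis_coords(a) * 1e-3 for a in range(3)]  # metres
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    if profile in ("uniform", "linear"):
        potential = -amplitude * Z
        efield = np.zeros(volume.shape + (3,))
        efield[..., 2] = amplitude
    else:
        r = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
        potential = amplitude * r
        efield = np.zeros(volume.shape + (3,))
        with np.errstate(invalid="ignore", divide="ignore"):
            for k, C in enumerate((X, Y, Z)):
                efield[..., k] = np.where(r > 0, -amplitude * C / r, 0.0)
    magnitude = np.sqrt((efield ** 2).sum(axis=-1))
    return potential, efield, magnitude
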