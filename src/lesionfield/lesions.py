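"""Factorial synthetic-lesion generation relative to an ROI.

Lesions are spheres placed at one of 14 cardinal/intercardinal directions
from the ROI, at an exact edge-to-edge gap, and constrained to grey and
white matter.  A lesion state is excluded if its centre falls outside the
brain or if less than 20% of the full sphere volume survives the gm/wm
constraint.  The default grids (14 directions x 3 gaps x 3 radii x 5
conductivities) give 630 states per ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import GeometryError, ParameterError
from .phantom import LABELS, LabelVolume, SphericalROI

__all__ = [
    "DIRECTION_LABELS",
    "DEFAULT_GAPS_MM",
    "DEFAULT_RADII_MM",
    "DEFAULT_CONDUCTIVITIES",
    "VOLUME_FRACTION_THRESHOLD",
    "LesionSpec",
    "LesionState",
    "direction_vector",
    "place_lesion",
    "rasterize_lesion",
    "validate_lesion",
    "enumerate_states",
    "states_to_frame",
]

#: The 14 lesion directions: 6 cardinal plus the 8 oblique corners.
DIRECTION_LABELS = ("R", "L", "A", "P", "S", "I",
                    "RAS", "RAI", "RPS", "RPI", "LAS", "LAI", "LPS", "LPI")

DEFAULT_GAPS_MM = (1.0, 5.0, 10.0)
DEFAULT_RADII_MM = (4.0, 12.0, 24.0)
DEFAULT_CONDUCTIVITIES = (0.2, 0.6, 1.0, 1.4, 1.8)

#: Minimum surviving fraction of the sphere volume (inclusive).
VOLUME_FRACTION_THRESHOLD = 0.20

_AXIS = {"R": (1, 0, 0), "L": (-1, 0, 0),
         "A": (0, 1, 0), "P": (0, -1, 0),
         "S": (0, 0, 1), "I": (0, 0, -1)}


def direction_vector(label: str) -> np.ndarray:
    """Unit vector for a direction label (RAS axes).

    Cardinal labels map to signed unit axes; three-letter labels to the
    normalised sum of their axes, e.g. RAS -> (1,1,1)/sqrt(3).
    """
    if label not in DIRECTION_LABELS:
        raise ParameterError(f"unknown direction label {label!r}; "
                             f"expected one of {DIRECTION_LABELS}")
    v = np.sum([_AXIS[ch] for ch in label], axis=0).astype(float)
    return v / np.linalg.norm(v)


@dataclass(frozen=True)
class LesionSpec:
    """Parametric lesion description: direction, gap, radius, conductivity."""

    direction_label: str
    gap_mm: float
    radius_mm: float
    conductivity_S_per_m: float

    def __post_init__(self):
        if self.direction_label not in DIRECTION_LABELS:
            raise ParameterError(f"unknown direction label {self.direction_label!r}")
        if min(self.gap_mm, self.radius_mm, self.conductivity_S_per_m) <= 0:
            raise ParameterError("gap, radius and conductivity must be positive")


@dataclass
class LesionState:
    """A rasterised, validated lesion realisation on a phantom grid."""

    spec: LesionSpec
    center_mm: np.ndarray
    mask: np.ndarray                 # boolean grid, subset of gm|wm
    volume_fraction: float
    valid: bool = False
    exclusion_reason: str | None = None  # centre_outside_brain | volume_below_threshold

    @property
    def key(self) -> tuple:
        s = self.spec
        return (s.direction_label, s.gap_mm, s.radius_mm, s.conductivity_S_per_m)


def place_lesion(roi: SphericalROI, spec: LesionSpec) -> np.ndarray:
    """Lesion centre so the edge-to-edge ROI distance equals the gap exactly.

    center = roi.center + u * (roi.radius + gap + lesion radius).
    """
    u = direction_vector(spec.direction_label)
    return roi.center + u * (roi.radius_mm + spec.gap_mm + spec.radius_mm)


def rasterize_lesion(phantom: LabelVolume, center_mm, radius_mm: float
                     ) -> tuple[np.ndarray, float]:
    """Sphere mask constrained to gm/wm, plus the surviving volume fraction.

    Membership is by voxel-centre containment.  The denominator of the
    volume fraction is the voxel count of the *unconstrained* sphere on the
    same grid, so fraction 1.0 means the lesion lies fully in the brain.
    """
    if radius_mm < phantom.voxel_size_mm / 2.0:
        raise ParameterError(f"lesion radius {radius_mm} mm is degenerate at "
                             f"{phantom.voxel_size_mm} mm voxels")
    c = np.asarray(center_mm, dtype=float)
    # restrict to the sphere's bounding box: enumeration rasterises hundreds
    # of lesions, so full-grid distance fields would dominate the runtime
    h = phantom.voxel_size_mm
    lo = np.maximum(np.floor((c - radius_mm - phantom.origin_mm) / h), 0).astype(int)
    hi = np.minimum(np.ceil((c + radius_mm - phantom.origin_mm) / h) + 1,
                    phantom.shape).astype(int)
    mask = np.zeros(phantom.shape, dtype=bool)
    if np.any(lo >= hi):
        return mask, 0.0  # sphere entirely off-grid
    ax = [phantom.axis_coords(a)[lo[a]:hi[a]] - c[a] for a in range(3)]
    d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
          + ax[2][None, None, :] ** 2)
    sphere = d2 <= radius_mm ** 2
    full = int(sphere.sum())
    if full == 0:
        return mask, 0.0
    box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    brain = np.isin(phantom.labels[box], (LABELS["gm"], LABELS["wm"]))
    mask[box] = sphere & brain
    return mask, float(mask.sum()) / full


def validate_lesion(state: LesionState, phantom: LabelVolume) -> LesionState:
    """Apply the exclusion rules and set the valid flag.

    A state is excluded if the voxel containing its centre is not grey or
    white matter, or if the surviving volume fraction is below 20%
    (threshold inclusive: exactly 0.20 is valid).
    """
    idx = phantom.index_of(state.center_mm)
    inside = (phantom.contains_index(idx)
              and phantom.labels[idx] in (LABELS["gm"], LABELS["wm"]))
    if not inside:
        reason = "centre_outside_brain"
    elif state.volume_fraction < VOLUME_FRACTION_THRESHOLD:
        reason = "volume_below_threshold"
    else:
        reason = None
    return replace(state, valid=reason is None, exclusion_reason=reason)


def enumerate_states(roi: SphericalROI, phantom: LabelVolume,
                     directions=DIRECTION_LABELS,
                     gaps_mm=DEFAULT_GAPS_MM,
                     radii_mm=DEFAULT_RADII_MM,
                     conductivities=DEFAULT_CONDUCTIVITIES) -> list[LesionState]:
    """Full factorial over direction x gap x radius x conductivity.

    Enumeration order is deterministic (direction outermost, conductivity
    innermost) so result tables are reproducible row-for-row.  Conductivity
    does not affect geometry, so the mask is rasterised once per
    (direction, gap, radius) and shared across conductivity variants.
    """
    if not (len(directions) and len(gaps_mm) and len(radii_mm) and len(conductivities)):
        raise ParameterError("all lesion grids must be nonempty")
    states = []
    for d in directions:
        for g in gaps_mm:
            for r in radii_mm:
                spec0 = LesionSpec(d, float(g), float(r), float(conductivities[0]))
                center = place_lesion(roi, spec0)
                mask, vf = rasterize_lesion(phantom, center, float(r))
                for s in conductivities:
                    st = LesionState(spec=LesionSpec(d, float(g), float(r), float(s)),
                                     center_mm=center.copy(), mask=mask,
                                     volume_fraction=vf)
                    states.append(validate_lesion(st, phantom))
    return states


def states_to_frame(states: list[LesionState]):
    """Lesion-state table: one row per state (for CSV export)."""
    import pandas as pd

    rows = []
    for st in states:
        rows.append({
            "direction": st.spec.direction_label,
            "gap_mm": st.spec.gap_mm,
            "radius_mm": st.spec.radius_mm,
            "conductivity_S_per_m": st.spec.conductivity_S_per_m,
            "center_x_mm": st.center_mm[0],
            "center_y_mm": st.center_mm[1],
            "center_z_mm": st.center_mm[2],
            "volume_fraction": st.volume_fraction,
            "valid": st.valid,
            "exclusion_reason": st.exclusion_reason or "",
        })
    return pd.DataFrame(rows)
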