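"""Montage optimisation and stimulator-dose individualisation.

Two objectives are supported for the exhaustive bipolar search:

* ``magnitude`` — mean E-field magnitude over the ROI grey matter;
* ``radial_inward`` — mean of the E-field component along the inward
  cortical normal (on a spherical phantom the inward normal is the
  direction towards the head centre).  The signed mean is used, so
  outward-flowing current counts against the objective.

Dose individualisation rescales the stimulator output by
target / achieved ROI magnitude, exploiting the linearity of the
volume-conductor problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .analysis import roi_stats
from .exceptions import GeometryError, ParameterError
from .phantom import Electrode, LabelVolume, SphericalROI, place_electrodes, scalp_position
from .solver import FieldResult, VolumeConductorModel

__all__ = ["MontageResult", "DoseAdjustment", "candidate_positions",
           "objective_radial_inward", "optimise_montage", "individualise_dose"]


@dataclass
class MontageResult:
    """Outcome of the exhaustive bipolar montage search."""

    anode_position: np.ndarray
    cathode_position: np.ndarray
    anode_index: int
    cathode_index: int
    objective_name: str
    objective_value: float
    roi_mean_mag: float
    evaluated_count: int
    failed_count: int = 0
    leaderboard: list = field(default_factory=list)  # (i, j, objective) per pair


@dataclass(frozen=True)
class DoseAdjustment:
    """Stimulator-output rescaling to hit a target ROI magnitude."""

    target_mag: float
    actual_mag: float
    fixed_dose_mA: float
    individualised_dose_mA: float
    capped: bool = False


def candidate_positions(n: int, phantom: LabelVolume,
                        latitude_cutoff_deg: float = -30.0) -> list[np.ndarray]:
    """Deterministic quasi-uniform scalp positions on the upper head.

    Points come from a Fibonacci sphere restricted to latitudes above the
    cutoff (degrees; 0 = equator, -30 keeps everything above the ears/neck
    line), projected onto the scalp surface.  The same inputs always yield
    the same ordered list.
    """
    if n < 8:
        raise ParameterError("need at least 8 candidate positions")
    cut = np.sin(np.radians(latitude_cutoff_deg))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    dirs: list[np.ndarray] = []
    m = n
    while len(dirs) < n:
        dirs = []
        for k in range(m):
            z = 1.0 - 2.0 * (k + 0.5) / m
            if z < cut:
                continue
            rho = np.sqrt(max(1.0 - z * z, 0.0))
            th = golden * k
            dirs.append(np.array([rho * np.cos(th), rho * np.sin(th), z]))
            if len(dirs) == n:
                break
        m += max(1, m // 8)
    return [scalp_position(phantom, d) for d in dirs[:n]]


def objective_radial_inward(result: FieldResult, roi: SphericalROI,
                            gm_mask: np.ndarray, volume: LabelVolume,
                            normals: np.ndarray | None = None) -> float:
    """Mean radially-inward E-field component over the ROI grey matter.

    ``normals`` (same grid, trailing axis 3) overrides the default
    spherical-phantom inward normal -(p - head centre)/|p - head centre|.
    """
    sel = roi.mask_on(volume) & gm_mask
    if not sel.any():
        raise GeometryError("ROI contains no grey-matter voxels")
    if normals is None:
        ax = [volume.axis_coords(a) for a in range(3)]
        p = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)[sel]
        norm = np.linalg.norm(p, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        nvecs = -p / norm
    else:
        nvecs = normals[sel]
    evecs = result.efield[sel]
    return float(np.mean(np.sum(evecs * nvecs, axis=1)))


def optimise_montage(phantom: LabelVolume, candidates, roi: SphericalROI,
                     objective: str = "magnitude", fixed_current_mA: float = 1.0,
                     table: dict | None = None, sigma=None,
                     tol: float = 1e-8,
                     disc_radius_mm: float = 17.0, thickness_mm: float = 2.0
                     ) -> MontageResult:
    """Exhaustive search over ordered anode/cathode candidate pairs.

    Every ordered pair (i != j) is placed, solved and scored; the argmax is
    returned, with ties broken by the lowest (anode index, cathode index).
    A solver failure on a pair is recorded and the pair skipped.

    ``sigma`` may be a callable mapping a placed LabelVolume to a
    ConductivityVolume (used to paint lesions in before solving).
    """
    if objective not in ("magnitude", "radial_inward"):
        raise ParameterError(f"unknown objective {objective!r}")
    if len(candidates) < 2:
        raise ParameterError("need at least 2 candidate positions")
    gm_mask = phantom.mask("gm")

    best = None
    leaderboard = []
    failed = 0
    evaluated = 0
    for i, pa in enumerate(candidates):
        for j, pc in enumerate(candidates):
            if i == j:
                continue
            montage = [Electrode(tuple(pa), +fixed_current_mA,
                                 disc_radius_mm, thickness_mm),
                       Electrode(tuple(pc), -fixed_current_mA,
                                 disc_radius_mm, thickness_mm)]
            try:
                placed = place_electrodes(phantom, montage)
                if callable(sigma):
                    model = VolumeConductorModel.from_phantom(
                        placed, montage, sigma=sigma(placed))
                else:
                    model = VolumeConductorModel.from_phantom(placed, montage, table=table)
                result = model.fit(tol=tol)
                stats = roi_stats(result.magnitude, result.efield, roi, gm_mask, phantom)
                if objective == "magnitude":
                    value = stats.mean_mag
                else:
                    value = objective_radial_inward(result, roi, gm_mask, phantom)
            except Exception as exc:  # noqa: BLE001 - per-pair robustness
                warnings.warn(f"montage pair ({i},{j}) failed: {exc}", stacklevel=2)
                failed += 1
                continue
            evaluated += 1
            leaderboard.append((i, j, value))
            if best is None or value > best[2] + 0.0:
                best = (i, j, value, stats.mean_mag)
    if best is None:
        raise GeometryError("every candidate pair failed to solve")
    i, j, value, mean_mag = best
    return MontageResult(anode_position=np.asarray(candidates[i]),
                         cathode_position=np.asarray(candidates[j]),
                         anode_index=i, cathode_index=j,
                         objective_name=objective, objective_value=value,
                         roi_mean_mag=mean_mag,
                         evaluated_count=evaluated, failed_count=failed,
                         leaderboard=leaderboard)


def individualise_dose(target_mag: float, actual_mag: float, fixed_dose_mA: float,
                       max_dose_mA: float = 4.0) -> DoseAdjustment:
    """Stimulator output needed to reach the target ROI magnitude.

    individualised dose = (target / actual) x fixed dose, clipped at the
    per-electrode safety cap ``max_dose_mA`` (flagged when clipping occurs).
    """
    if min(target_mag, actual_mag, fixed_dose_mA) <= 0:
        raise ParameterError("target, actual and fixed dose must all be positive")
    dose = (target_mag / actual_mag) * fixed_dose_mA
    capped = dose > max_dose_mA
    if capped:
        dose = max_dose_mA
    return DoseAdjustment(target_mag=target_mag, actual_mag=actual_mag,
                          fixed_dose_mA=fixed_dose_mA,
                          individualised_dose_mA=dose, capped=capped)
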