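"""Outcome measures: difference images, ROI statistics, the lesion angle.

The workflow mirrors how lesioned and non-lesioned field models are
compared: subtract the non-lesioned magnitude image from the lesioned one,
summarise the difference over grey-matter voxels inside the ROI (mean,
16th and 84th percentile), and quantify lesion location by the angle
between the ROI-to-lesion direction and the mean current direction in the
non-lesioned ROI.  Angle near 0 deg = lesion downstream, in the path of
current; near 180 deg = upstream, opposite the current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError, ParameterError
from .lesions import LesionState
from .phantom import LabelVolume, SphericalROI
from .solver import FieldResult

__all__ = ["RoiFieldStats", "LesionEffect", "difference_image", "roi_stats",
           "lesion_angle", "percent_difference", "lesion_effect"]


@dataclass(frozen=True)
class RoiFieldStats:
    """E-field summary over the grey-matter voxels of an ROI.

    ``mean_direction`` is the normalised mean of the raw E-vectors (not of
    unit vectors), so coherent strong current dominates the direction.
    Percentiles use linear interpolation between order statistics.
    """

    mean_mag: float
    p16_mag: float
    p84_mag: float
    mean_direction: np.ndarray
    n_voxels: int


@dataclass(frozen=True)
class LesionEffect:
    """Lesioned-vs-non-lesioned comparison for one lesion state."""

    state: LesionState
    diff_mean: float
    diff_p16: float
    diff_p84: float
    pct_diff: float
    abs_pct_diff: float
    angle_deg: float
    baseline_mean: float


def difference_image(lesioned_mag: np.ndarray, nonlesioned_mag: np.ndarray) -> np.ndarray:
    """Voxelwise lesioned minus non-lesioned magnitude (positive = increase)."""
    lesioned_mag = np.asarray(lesioned_mag)
    nonlesioned_mag = np.asarray(nonlesioned_mag)
    if lesioned_mag.shape != nonlesioned_mag.shape:
        raise GeometryError(f"magnitude grids differ in shape: "
                            f"{lesioned_mag.shape} vs {nonlesioned_mag.shape}")
    return lesioned_mag - nonlesioned_mag


def roi_stats(magnitude: np.ndarray, efield: np.ndarray, roi: SphericalROI,
              gm_mask: np.ndarray, volume: LabelVolume) -> RoiFieldStats:
    """Mean / 16th / 84th percentile magnitude and mean direction in the ROI.

    Statistics are taken over grey-matter voxels whose centres lie within
    the ROI sphere; ``volume`` supplies the grid geometry.
    """
    sel = roi.mask_on(volume) & gm_mask
    n = int(sel.sum())
    if n == 0:
        raise GeometryError("ROI contains no grey-matter voxels")
    mags = magnitude[sel]
    vecs = efield[sel]
    mean_vec = vecs.mean(axis=0)
    norm = np.linalg.norm(mean_vec)
    if norm == 0:
        direction = np.zeros(3)
    else:
        direction = mean_vec / norm
    return RoiFieldStats(mean_mag=float(mags.mean()),
                         p16_mag=float(np.percentile(mags, 16)),
                         p84_mag=float(np.percentile(mags, 84)),
                         mean_direction=direction,
                         n_voxels=n)


def lesion_angle(roi: SphericalROI, lesion_center_mm, mean_direction) -> float:
    """Angle (degrees, 0-180) between ROI->lesion direction and current.

    Measured centre-to-centre.  0 deg: lesion exactly downstream of the ROI
    current; 180 deg: exactly upstream.
    """
    d = np.asarray(lesion_center_mm, dtype=float) - roi.center
    nd = np.linalg.norm(d)
    u = np.asarray(mean_direction, dtype=float)
    nu = np.linalg.norm(u)
    if nd == 0 or nu == 0:
        raise ParameterError("lesion displacement and mean direction must be nonzero")
    cosang = np.clip(np.dot(d / nd, u / nu), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def percent_difference(lesioned: RoiFieldStats, nonlesioned: RoiFieldStats
                       ) -> tuple[float, float]:
    """Signed and absolute percentage change of the ROI mean magnitude.

    The denominator is the non-lesioned ROI mean.
    """
    if nonlesioned.mean_mag <= 0:
        raise ParameterError("non-lesioned ROI mean magnitude must be positive")
    pct = 100.0 * (lesioned.mean_mag - nonlesioned.mean_mag) / nonlesioned.mean_mag
    return pct, abs(pct)


def lesion_effect(state: LesionState, lesioned: FieldResult, baseline: FieldResult,
                  roi: SphericalROI, gm_mask: np.ndarray, volume: LabelVolume,
                  baseline_stats: RoiFieldStats | None = None) -> LesionEffect:
    """Full comparison for one lesion state.

    The difference statistics (mean/p16/p84) are computed on the voxelwise
    difference image over the ROI grey matter; the angle uses the
    *non-lesioned* mean direction.
    """
    if baseline_stats is None:
        baseline_stats = roi_stats(baseline.magnitude, baseline.efield, roi,
                                   gm_mask, volume)
    les_stats = roi_stats(lesioned.magnitude, lesioned.efield, roi, gm_mask, volume)
    diff = difference_image(lesioned.magnitude, baseline.magnitude)
    sel = roi.mask_on(volume) & gm_mask
    dvals = diff[sel]
    pct, abs_pct = percent_difference(les_stats, baseline_stats)
    ang = lesion_angle(roi, state.center_mm, baseline_stats.mean_direction)
    return LesionEffect(state=state,
                        diff_mean=float(dvals.mean()),
                        diff_p16=float(np.percentile(dvals, 16)),
                        diff_p84=float(np.percentile(dvals, 84)),
                        pct_diff=pct, abs_pct_diff=abs_pct,
                        angle_deg=ang,
                        baseline_mean=baseline_stats.mean_mag)
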