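"""Synthetic multi-shell head phantoms, ROIs, conductivity and electrodes.

A phantom is a voxelised tissue segmentation (:class:`LabelVolume`) built
from nested concentric spheres: skin, skull, CSF, grey matter and white
matter, surrounded by air.  It stands in for a segmented structural MRI,
using the same 7-tissue label convention the rest of the package expects
(air, skin, skull, csf, gm, wm, lesion) plus gel and electrode labels that
are added when a montage is placed on the scalp.

Coordinates are RAS millimetres: +x = Right, +y = Anterior, +z = Superior,
voxel-centre addressing, 0-based indices.  The head centre sits at the RAS
origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

from .exceptions import ConfigurationError, GeometryError, ParameterError, PlacementError

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "DEFAULT_CONDUCTIVITY",
    "DEFAULT_SHELL_RADII_MM",
    "LabelVolume",
    "ConductivityVolume",
    "SphericalROI",
    "Electrode",
    "build_phantom",
    "define_roi",
    "assign_conductivity",
    "place_electrodes",
    "scalp_position",
    "save_nifti",
    "load_label_volume",
]

#: Integer label codes used throughout the package.
LABELS = {
    "air": 0,
    "skin": 1,
    "skull": 2,
    "csf": 3,
    "gm": 4,
    "wm": 5,
    "lesion": 6,
    "gel": 7,
    "electrode": 8,
}
LABEL_NAMES = {code: name for name, code in LABELS.items()}

#: Tissue conductivities in S/m.  These are the standard literature values
#: used by ROAST-style pipelines; lesion conductivity is deliberately absent
#: (it is the experimental variable and must be supplied per state).
DEFAULT_CONDUCTIVITY = {
    "air": 2.5e-14,
    "skin": 0.126,
    "skull": 0.465,
    "csf": 1.65,
    "gm": 0.276,
    "wm": 0.126,
    "gel": 0.3,
    "electrode": 5.9e7,
}

#: Default shell radii in mm (skin, skull, CSF, GM, WM) — typical adult
#: 5-shell head dimensions.
DEFAULT_SHELL_RADII_MM = (92.0, 86.0, 80.0, 78.0, 70.0)


@dataclass
class LabelVolume:
    """Voxelised tissue segmentation with geometry metadata.

    Parameters
    ----------
    labels
        3-D int16 array, one tissue code per voxel (see :data:`LABELS`).
    voxel_size_mm
        Isotropic voxel edge length in millimetres.
    origin_mm
        RAS coordinates of the centre of voxel (0, 0, 0).
    label_table
        Mapping code -> tissue name for every code present.
    electrode_voxels
        Per-electrode flat voxel indices (filled by :func:`place_electrodes`).
    """

    labels: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray
    label_table: dict[int, str] = field(default_factory=lambda: dict(LABEL_NAMES))
    electrode_voxels: list[np.ndarray] | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ParameterError("labels must be a 3-D array")
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        present = np.unique(self.labels)
        missing = [int(c) for c in present if int(c) not in self.label_table]
        if missing:
            raise ConfigurationError(f"label codes {missing} absent from label_table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *tissues: str) -> np.ndarray:
        """Boolean mask of voxels carrying any of the named tissues."""
        codes = [LABELS[t] for t in tissues]
        return np.isin(self.labels, codes)

    @property
    def brain_mask(self) -> np.ndarray:
        """Grey plus white matter (the lesion-admissible domain)."""
        return self.mask("gm", "wm", "lesion")

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-centre RAS coordinate along one axis."""
        n = self.labels.shape[axis]
        return self.origin_mm[axis] + self.voxel_size_mm * np.arange(n)

    def voxel_center(self, index) -> np.ndarray:
        """RAS coordinates of a voxel centre given its (i, j, k) index."""
        return self.origin_mm + self.voxel_size_mm * np.asarray(index, dtype=float)

    def index_of(self, point_mm) -> tuple[int, int, int]:
        """Index of the voxel containing an RAS point (nearest centre)."""
        idx = np.round((np.asarray(point_mm, dtype=float) - self.origin_mm)
                       / self.voxel_size_mm).astype(int)
        return tuple(int(v) for v in idx)

    def contains_index(self, idx) -> bool:
        return all(0 <= i < n for i, n in zip(idx, self.labels.shape))

    def radius_grid(self) -> np.ndarray:
        """Distance of every voxel centre from the RAS origin, in mm."""
        ax = [self.axis_coords(a) for a in range(3)]
        return np.sqrt(ax[0][:, None, None] ** 2
                       + ax[1][None, :, None] ** 2
                       + ax[2][None, None, :] ** 2)

    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def copy(self) -> "LabelVolume":
        ev = None if self.electrode_voxels is None else [v.copy() for v in self.electrode_voxels]
        return replace(self, labels=self.labels.copy(),
                       origin_mm=self.origin_mm.copy(),
                       label_table=dict(self.label_table),
                       electrode_voxels=ev)


@dataclass
class ConductivityVolume:
    """Voxelwise conductivity in S/m on the same grid as its LabelVolume."""

    sigma: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self):
        return self.sigma.shape

    def copy(self) -> "ConductivityVolume":
        return ConductivityVolume(self.sigma.copy(), self.voxel_size_mm,
                                  self.origin_mm.copy())


@dataclass(frozen=True)
class SphericalROI:
    """Spherical region of interest at a cortical target.

    The default 12 mm radius matches the size conventionally used for
    motor-cortex / Broca-area stimulation targets.
    """

    center_mm: tuple[float, float, float]
    radius_mm: float = 12.0

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise ParameterError("ROI radius must be positive")
        object.__setattr__(self, "center_mm", tuple(float(v) for v in self.center_mm))

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.center_mm, dtype=float)

    def mask_on(self, volume: LabelVolume) -> np.ndarray:
        """Boolean mask of voxels whose centres lie within the sphere."""
        ax = [volume.axis_coords(a) - self.center[a] for a in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        return d2 <= self.radius_mm ** 2


@dataclass(frozen=True)
class Electrode:
    """Disc electrode on the scalp.

    17 mm disc radius and 2 mm thickness are the conventional sponge-pad
    dimensions; current is signed (anode > 0, cathode < 0, in mA).
    """

    center_mm: tuple[float, float, float]
    current_mA: float
    disc_radius_mm: float = 17.0
    thickness_mm: float = 2.0

    def __post_init__(self):
        if self.disc_radius_mm <= 0 or self.thickness_mm <= 0:
            raise ParameterError("electrode dimensions must be positive")
        object.__setattr__(self, "center_mm", tuple(float(v) for v in self.center_mm))

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.center_mm, dtype=float)


def build_phantom(shell_radii_mm=DEFAULT_SHELL_RADII_MM, voxel_size_mm: float = 2.0,
                  margin_mm: float = 8.0) -> LabelVolume:
    """Build a concentric-sphere head phantom.

    Parameters
    ----------
    shell_radii_mm
        Five strictly descending outer radii for skin, skull, CSF, grey
        matter and white matter, in mm.
    voxel_size_mm
        Isotropic voxel size.  2 mm is the desk-scale default; 1 mm mirrors
        typical structural-MRI resolution but is ~8x more voxels.
    margin_mm
        Air margin beyond the scalp so electrodes and gel fit on the grid.

    Voxels are labelled by the distance of their centre from the head
    centre; the outermost region is air.  Generation is deterministic.
    """
    radii = [float(r) for r in shell_radii_mm]
    if len(radii) != 5:
        raise ParameterError("expected 5 shell radii (skin, skull, csf, gm, wm)")
    if any(r <= 0 for r in radii) or any(a <= b for a, b in zip(radii, radii[1:])):
        raise ParameterError(f"shell radii must be positive and strictly descending, got {radii}")
    if voxel_size_mm <= 0:
        raise ParameterError("voxel size must be positive")

    h = float(voxel_size_mm)
    half = int(np.ceil((radii[0] + margin_mm) / h))
    n = 2 * half + 1  # odd so a voxel centre sits exactly at the head centre
    origin = np.full(3, -half * h)

    coords = origin[0] + h * np.arange(n)
    r = np.sqrt(coords[:, None, None] ** 2 + coords[None, :, None] ** 2
                + coords[None, None, :] ** 2)

    labels = np.zeros((n, n, n), dtype=np.int16)  # air
    r_skin, r_skull, r_csf, r_gm, r_wm = radii
    labels[r <= r_skin] = LABELS["skin"]
    labels[r <= r_skull] = LABELS["skull"]
    labels[r <= r_csf] = LABELS["csf"]
    labels[r <= r_gm] = LABELS["gm"]
    labels[r <= r_wm] = LABELS["wm"]
    return LabelVolume(labels=labels, voxel_size_mm=h, origin_mm=origin)


def define_roi(phantom: LabelVolume, direction_unit, radius_mm: float = 12.0) -> SphericalROI:
    """Place a spherical ROI at grey-matter mid-thickness along a direction.

    The ray from the head centre along ``direction_unit`` is sampled at
    quarter-voxel steps; the ROI centre is the midpoint of the outermost
    contiguous grey-matter run along that ray.
    """
    u = np.asarray(direction_unit, dtype=float)
    if abs(np.linalg.norm(u) - 1.0) > 1e-6:
        raise ParameterError("direction_unit must have unit norm")

    h = phantom.voxel_size_mm
    r_max = 0.5 * h * max(phantom.shape)
    ts = np.arange(0.0, r_max, h / 4.0)
    gm_code = LABELS["gm"]
    hits = []
    for t in ts:
        idx = phantom.index_of(u * t)
        if phantom.contains_index(idx) and phantom.labels[idx] == gm_code:
            hits.append(t)
    if not hits:
        raise GeometryError("no grey matter along the requested direction")
    # outermost contiguous run
    hits = np.asarray(hits)
    breaks = np.flatnonzero(np.diff(hits) > h)  # gap in the run
    start = hits[breaks[-1] + 1] if len(breaks) else hits[0]
    center = u * 0.5 * (start + hits[-1])

    roi = SphericalROI(center_mm=tuple(center), radius_mm=radius_mm)
    cidx = phantom.index_of(center)
    if not (phantom.contains_index(cidx) and phantom.brain_mask[cidx]):
        raise GeometryError("ROI centre does not fall inside the brain mask")
    if not np.any(roi.mask_on(phantom) & phantom.mask("gm")):
        raise GeometryError("ROI does not intersect grey matter")
    return roi


def assign_conductivity(phantom: LabelVolume, table: dict[str, float] | None = None
                        ) -> ConductivityVolume:
    """Voxelwise conductivity lookup from the tissue table.

    ``table`` entries override :data:`DEFAULT_CONDUCTIVITY`; every label
    present in the volume must resolve to a conductivity.
    """
    merged = dict(DEFAULT_CONDUCTIVITY)
    if table:
        merged.update(table)
    bad = [name for name, s in merged.items() if s is None or (s <= 0 and name != "air")]
    if bad:
        raise ConfigurationError(f"non-positive conductivity for {bad}")

    present = np.unique(phantom.labels)
    lut = np.zeros(int(present.max()) + 1, dtype=float)
    for code in present:
        name = phantom.label_table[int(code)]
        if name not in merged:
            raise ConfigurationError(f"no conductivity for tissue {name!r}")
        lut[int(code)] = merged[name]
    return ConductivityVolume(sigma=lut[phantom.labels],
                              voxel_size_mm=phantom.voxel_size_mm,
                              origin_mm=phantom.origin_mm.copy())


def scalp_position(phantom: LabelVolume, direction_unit) -> np.ndarray:
    """Outermost skin-voxel centre radius along a direction, as an RAS point."""
    u = np.asarray(direction_unit, dtype=float)
    u = u / np.linalg.norm(u)
    h = phantom.voxel_size_mm
    skin = LABELS["skin"]
    best = None
    for t in np.arange(0.0, 0.5 * h * max(phantom.shape), h / 4.0):
        idx = phantom.index_of(u * t)
        if phantom.contains_index(idx) and phantom.labels[idx] == skin:
            best = t
    if best is None:
        raise GeometryError("no skin surface along the requested direction")
    return u * best


def place_electrodes(phantom: LabelVolume, montage: list[Electrode]) -> LabelVolume:
    """Rasterise gel + electrode discs onto the scalp.

    Each electrode is modelled as one voxel layer of gel on the scalp
    followed by conductor voxels up to ``thickness_mm`` (at least one
    layer), within ``disc_radius_mm`` of the electrode axis (the ray from
    the head centre through the disc centre).  Original head tissues are
    never overwritten; only air voxels become gel/electrode.
    """
    if len(montage) < 2:
        raise PlacementError("a montage needs at least 2 electrodes (bipolar minimum)")
    total = sum(e.current_mA for e in montage)
    if abs(total) > 1e-9:
        raise ParameterError(f"montage currents must sum to zero, got {total} mA")

    out = phantom.copy()
    h = phantom.voxel_size_mm
    ax = [phantom.axis_coords(a) for a in range(3)]
    px = ax[0][:, None, None]
    py = ax[1][None, :, None]
    pz = ax[2][None, None, :]
    r = np.sqrt(px ** 2 + py ** 2 + pz ** 2)
    air = phantom.labels == LABELS["air"]

    claimed = np.zeros(phantom.shape, dtype=bool)
    electrode_voxels: list[np.ndarray] = []
    for elec in montage:
        c = elec.center
        r_surf = np.linalg.norm(c)
        if r_surf == 0:
            raise PlacementError("electrode centre cannot be the head centre")
        u = c / r_surf
        # verify the disc centre sits by the skin surface
        sidx = phantom.index_of(c - u * (h / 2.0))
        if not (phantom.contains_index(sidx)
                and phantom.labels[sidx] in (LABELS["skin"], LABELS["gel"])):
            near = phantom.index_of(c)
            if not (phantom.contains_index(near) and phantom.labels[near] == LABELS["skin"]):
                raise PlacementError("electrode disc centre is not on the skin surface")
        t = px * u[0] + py * u[1] + pz * u[2]           # axial coordinate
        d2 = np.maximum(r ** 2 - t ** 2, 0.0)            # squared distance to axis
        in_disc = (t > 0) & (d2 <= elec.disc_radius_mm ** 2)

        gel_h = h  # one voxel layer of gel
        elec_h = max(elec.thickness_mm, h)
        gel_band = in_disc & air & (r > r_surf) & (r <= r_surf + gel_h)
        elec_band = in_disc & air & (r > r_surf + gel_h) & (r <= r_surf + gel_h + elec_h)
        patch = gel_band | elec_band
        if not np.any(elec_band):
            raise PlacementError("electrode produced no conductor voxels; "
                                 "check disc geometry and voxel size")
        if np.any(patch & claimed):
            raise PlacementError("electrode discs overlap")
        claimed |= patch
        out.labels[gel_band] = LABELS["gel"]
        out.labels[elec_band] = LABELS["electrode"]
        electrode_voxels.append(np.flatnonzero(elec_band.ravel()))

    out.electrode_voxels = electrode_voxels
    return out


def save_nifti(path, array: np.ndarray, voxel_size_mm: float, origin_mm) -> None:
    """Write a 3-D or 4-D array as NIfTI-1 with an RAS affine."""
    aff = np.diag([voxel_size_mm] * 3 + [1.0])
    aff[:3, 3] = np.asarray(origin_mm, dtype=float)
    img = nib.Nifti1Image(np.asarray(array), aff)
    nib.save(img, str(path))


def load_label_volume(path) -> LabelVolume:
    """Read a tissue-label NIfTI written with the package's convention."""
    img = nib.load(str(path))
    aff = img.affine
    vox = float(aff[0, 0])
    if not np.allclose(np.diag(aff)[:3], vox):
        raise ConfigurationError("expected an isotropic diagonal affine")
    labels = np.asarray(img.dataobj).astype(np.int16)
    return LabelVolume(labels=labels, voxel_size_mm=vox, origin_mm=aff[:3, 3].copy())


def export_label_volume(path, volume: LabelVolume) -> None:
    save_nifti(path, volume.labels.astype(np.int16), volume.voxel_size_mm, volume.origin_mm)


def export_conductivity(path, sigma: ConductivityVolume) -> None:
    save_nifti(path, sigma.sigma.astype(np.float32), sigma.voxel_size_mm, sigma.origin_mm)
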