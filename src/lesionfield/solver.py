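"""Quasi-static volume-conduction solver on the voxel grid.

The electric potential V in a head with heterogeneous conductivity sigma
satisfies the current-conservation (Laplace) equation

    div( sigma grad V ) = 0

inside the conductor, with zero normal current on the outer boundary and
the stimulator current injected/extracted at the electrodes.  The domain is
discretised with a cell-centred finite-volume scheme: one unknown per
conductive voxel, face conductances from the harmonic mean of the two
adjacent voxel conductivities (exact for layered media), and the injected
current distributed uniformly over each electrode's conductor voxels.  The
resulting symmetric positive-semidefinite system is gauge-fixed by pinning
one cathode voxel to 0 V and solved with Jacobi-preconditioned conjugate
gradients.

The model/results split follows the statsmodels convention:
:class:`VolumeConductorModel` holds the assembled system,
:meth:`VolumeConductorModel.fit` returns a :class:`FieldResult` with the
potential, the vector E-field, convergence diagnostics and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .exceptions import ConvergenceError, GeometryError, ParameterError, TopologyError
from .phantom import LABELS, ConductivityVolume, LabelVolume, assign_conductivity

__all__ = ["VolumeConductorModel", "FieldResult", "check_current_conservation",
           "electrode_box_region"]

#: Conductivities at or below this are treated as non-conductive (air).
AIR_SIGMA_THRESHOLD = 1e-10

#: Conductivities above this are clipped in the discretisation.  The metal
#: electrode label (5.9e7 S/m) would give the system a ~9-decade conductance
#: contrast that stalls iterative solvers, while the pad's internal
#: resistance is physically negligible either way (~1e-6 ohm at 1e3 S/m vs
#: tissue resistances of tens of ohms): clipping changes the potential by
#: well under one part in 1e6 but restores tractable conditioning.
SIGMA_CLIP_S_PER_M = 1e3


def _face_conductances(sigma: np.ndarray, h_m: float, axis: int):
    """Harmonic-mean face conductance between adjacent voxels along an axis.

    For face area A = h^2 and spacing h the conductance is
    A/h * 2*s1*s2/(s1+s2) = h * harmonic_mean(s1, s2).
    """
    s1 = np.moveaxis(sigma, axis, 0)[:-1]
    s2 = np.moveaxis(sigma, axis, 0)[1:]
    denom = s1 + s2
    g = np.where(denom > 0, 2.0 * s1 * s2 / np.where(denom > 0, denom, 1.0), 0.0)
    return h_m * np.moveaxis(g, 0, axis)


class VolumeConductorModel:
    """Finite-volume model of tDCS current flow in a voxelised head.

    Parameters
    ----------
    sigma
        Conductivity volume (S/m per voxel).
    electrode_voxels
        One flat-index array of conductor voxels per electrode.
    currents_mA
        Signed electrode currents (anode > 0); must sum to zero.

    Use :meth:`from_phantom` to build the model straight from a
    :class:`~lesionfield.phantom.LabelVolume` with placed electrodes.
    """

    def __init__(self, sigma: ConductivityVolume, electrode_voxels, currents_mA,
                 sigma_clip: float = SIGMA_CLIP_S_PER_M):
        if len(electrode_voxels) != len(currents_mA):
            raise ParameterError("one current per electrode required")
        if len(electrode_voxels) < 2:
            raise ParameterError("at least two electrodes required")
        if abs(sum(currents_mA)) > 1e-9:
            raise ParameterError("electrode currents must sum to zero")
        if np.any(sigma.sigma < 0):
            raise ParameterError("conductivities must be non-negative")
        self.sigma = sigma
        self.sigma_clip = float(sigma_clip)
        self.electrode_voxels = [np.asarray(v, dtype=np.int64) for v in electrode_voxels]
        self.currents_mA = [float(c) for c in currents_mA]
        self._system = None

    @classmethod
    def from_phantom(cls, phantom: LabelVolume, electrodes, table=None,
                     sigma: ConductivityVolume | None = None) -> "VolumeConductorModel":
        """Build from a phantom with placed electrodes.

        ``electrodes`` is the montage (for the currents); the voxel sets come
        from ``phantom.electrode_voxels``.  ``sigma`` may be passed directly
        (e.g. with a lesion painted in) instead of a tissue ``table``.
        """
        if phantom.electrode_voxels is None:
            raise ParameterError("phantom has no placed electrodes; "
                                 "call place_electrodes first")
        if sigma is None:
            sigma = assign_conductivity(phantom, table)
        return cls(sigma, phantom.electrode_voxels, [e.current_mA for e in electrodes])

    # -- assembly -----------------------------------------------------------

    def assemble(self):
        """Assemble the sparse conservation system (cached).

        Returns the tuple ``(A, b, unknown_of_voxel, conductive_flat, ref)``
        where ``A`` excludes the pinned reference row/column.
        """
        if self._system is not None:
            return self._system

        sig = np.minimum(self.sigma.sigma, self.sigma_clip)
        h_m = self.sigma.voxel_size_mm * 1e-3
        conductive = sig > AIR_SIGMA_THRESHOLD
        n_cond = int(conductive.sum())
        if n_cond == 0:
            raise TopologyError("conductive domain is empty (all air)")
        ncomp = ndi.label(conductive, structure=ndi.generate_binary_structure(3, 1))[1]
        if ncomp != 1:
            raise TopologyError(f"conductive domain is disconnected ({ncomp} components)")

        unknown = -np.ones(sig.size, dtype=np.int64)
        flat_cond = np.flatnonzero(conductive.ravel())
        unknown[flat_cond] = np.arange(n_cond)

        rows, cols, vals = [], [], []
        strides = np.array(sig.shape)
        flat_stride = [int(np.prod(sig.shape[a + 1:])) for a in range(3)]
        for axis in range(3):
            g = _face_conductances(sig, h_m, axis)
            sl1 = [slice(None)] * 3
            sl2 = [slice(None)] * 3
            sl1[axis] = slice(0, -1)
            sl2[axis] = slice(1, None)
            both = conductive[tuple(sl1)] & conductive[tuple(sl2)]
            gsel = g[both]
            # flat indices of the lower voxel of each interior face
            idx = np.flatnonzero(np.pad(both, [(0, 1) if a == axis else (0, 0)
                                               for a in range(3)]).ravel())
            i = unknown[idx]
            j = unknown[idx + flat_stride[axis]]
            rows.append(i); cols.append(j); vals.append(-gsel)
            rows.append(j); cols.append(i); vals.append(-gsel)
            rows.append(i); cols.append(i); vals.append(gsel)
            rows.append(j); cols.append(j); vals.append(gsel)

        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        A = sp.coo_matrix((vals, (rows, cols)), shape=(n_cond, n_cond)).tocsr()

        b = np.zeros(n_cond)
        for voxels, I in zip(self.electrode_voxels, self.currents_mA):
            u = unknown[voxels]
            if np.any(u < 0):
                raise TopologyError("electrode voxels fall outside the conductive domain")
            b[u] += (I * 1e-3) / len(voxels)

        # gauge: pin the most negative electrode's first voxel to 0 V
        cathode = int(np.argmin(self.currents_mA))
        ref = int(unknown[self.electrode_voxels[cathode][0]])

        keep = np.ones(n_cond, dtype=bool)
        keep[ref] = False
        A_red = A[keep][:, keep].tocsr()
        self._system = (A_red, b[keep], unknown, flat_cond, ref, keep)
        return self._system

    # -- solve --------------------------------------------------------------

    def fit(self, tol: float = 1e-8, maxiter: int | None = None) -> "FieldResult":
        """Solve for the potential and derive the E-field.

        ``tol`` is the relative residual target of the conjugate-gradient
        solve; the default 1e-8 keeps conservation errors far below the
        ~0.1 V/m scale of lesion effects.  Deterministic: zero initial guess.
        """
        A, b, unknown, flat_cond, ref, keep = self.assemble()
        n = A.shape[0]
        if maxiter is None:
            maxiter = int(1000 * max(n, 1) ** (1.0 / 3.0)) + 1000

        # Symmetric Jacobi scaling: the electrode conductivity (~6e7 S/m)
        # gives the raw matrix a ~9-decade dynamic range, which floors the
        # attainable unscaled residual.  CG runs on D^-1/2 A D^-1/2.
        d = A.diagonal()
        s = 1.0 / np.sqrt(np.where(d > 0, d, 1.0))
        As = sp.diags(s) @ A @ sp.diags(s)
        bs = b * s

        it = 0

        def cb(_):
            nonlocal it
            it += 1

        # CG's recursively-updated residual can drift from the true one on
        # long runs; verify the true residual and restart until it is met.
        bnorm = np.linalg.norm(bs)
        y = np.zeros_like(bs)
        residual = 1.0
        info = 0
        for _round in range(8):
            left = maxiter - it
            if left <= 0:
                info = 1
                break
            y, info = spla.cg(As, bs, x0=y, rtol=tol, atol=0.0,
                              maxiter=left, callback=cb)
            residual = float(np.linalg.norm(As @ y - bs) / bnorm) if bnorm > 0 else 0.0
            if residual <= tol or info > 0:
                break
        x = y * s
        if info > 0 or residual > tol:
            raise ConvergenceError(
                f"CG failed to converge within {it} iterations "
                f"(relative residual {residual:.3e}, target {tol:.1e})",
                residual=residual, iterations=it)

        pot = np.full(self.sigma.sigma.size, np.nan)
        sol = np.empty(unknown[flat_cond].size, dtype=float)
        sol[keep] = x
        sol[~keep] = 0.0
        pot[flat_cond] = sol
        potential = pot.reshape(self.sigma.shape)

        efield, magnitude = _gradient_efield(potential, self.sigma.voxel_size_mm)
        injected = sum(c for c in self.currents_mA if c > 0)
        return FieldResult(model=self, potential=potential, efield=efield,
                           magnitude=magnitude, injected_current_mA=injected,
                           residual=residual, iterations=it, tol=tol)


def _gradient_efield(potential: np.ndarray, voxel_size_mm: float):
    """E = -grad V, central differences interior, one-sided at air boundaries.

    Air voxels (NaN potential) get a zero field.
    """
    h_m = voxel_size_mm * 1e-3
    valid = np.isfinite(potential)
    V = np.where(valid, potential, 0.0)
    E = np.zeros(potential.shape + (3,))
    for axis in range(3):
        vp = np.roll(V, -1, axis=axis)
        vm = np.roll(V, 1, axis=axis)
        fp = np.roll(valid, -1, axis=axis)
        fm = np.roll(valid, 1, axis=axis)
        # roll wraps around; kill the wrapped slice
        sl = [slice(None)] * 3
        sl[axis] = -1
        fp[tuple(sl)] = False
        sl[axis] = 0
        fm[tuple(sl)] = False

        grad = np.zeros_like(V)
        both = fp & fm
        grad[both] = (vp[both] - vm[both]) / (2 * h_m)
        onlyp = fp & ~fm
        grad[onlyp] = (vp[onlyp] - V[onlyp]) / h_m
        onlym = fm & ~fp
        grad[onlym] = (V[onlym] - vm[onlym]) / h_m
        E[..., axis] = -grad
    E[~valid] = 0.0
    magnitude = np.sqrt((E ** 2).sum(axis=-1))
    return E, magnitude


@dataclass
class FieldResult:
    """Solved field: potential (V), E-field (V/m) and solver diagnostics.

    ``potential`` is NaN in air; ``magnitude`` is the voxelwise Euclidean
    norm of ``efield``.
    """

    model: VolumeConductorModel
    potential: np.ndarray
    efield: np.ndarray
    magnitude: np.ndarray
    injected_current_mA: float
    residual: float
    iterations: int
    tol: float = 1e-8

    @property
    def voxel_size_mm(self) -> float:
        return self.model.sigma.voxel_size_mm

    @property
    def converged(self) -> bool:
        return self.residual <= self.tol

    def conservation_error(self, region: np.ndarray) -> float:
        """Relative current-conservation error through a region boundary."""
        return check_current_conservation(self, region)

    def to_nifti(self, directory, prefix: str = "field") -> list:
        """Write potential, E-vector (4-D) and magnitude volumes as NIfTI."""
        from pathlib import Path

        from .phantom import save_nifti

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        vox = self.voxel_size_mm
        origin = self.model.sigma.origin_mm
        paths = []
        for name, arr in (("potential", self.potential.astype(np.float32)),
                          ("efield", self.efield.astype(np.float32)),
                          ("magnitude", self.magnitude.astype(np.float32))):
            p = d / f"{prefix}_{name}.nii.gz"
            save_nifti(p, arr, vox, origin)
            paths.append(p)
        return paths

    def summary(self) -> str:
        cond = np.isfinite(self.potential)
        lines = [
            "Volume conductor solve",
            "=" * 46,
            f"unknowns            : {int(cond.sum())}",
            f"voxel size          : {self.voxel_size_mm:g} mm",
            f"injected current    : {self.injected_current_mA:g} mA",
            f"CG iterations       : {self.iterations}",
            f"relative residual   : {self.residual:.3e}  (tol {self.tol:g})",
            f"max |E| (tissue)    : {np.nanmax(self.magnitude[cond]):.4g} V/m",
            f"potential range     : [{np.nanmin(self.potential):.4g}, "
            f"{np.nanmax(self.potential):.4g}] V",
        ]
        return "\n".join(lines)


def electrode_box_region(result_or_model, electrode_index: int, pad_voxels: int = 2
                         ) -> np.ndarray:
    """Axis-aligned box region enclosing one electrode, for conservation checks."""
    model = result_or_model.model if isinstance(result_or_model, FieldResult) else result_or_model
    shape = model.sigma.shape
    vox = model.electrode_voxels[electrode_index]
    ijk = np.array(np.unravel_index(vox, shape))
    lo = np.maximum(ijk.min(axis=1) - pad_voxels, 0)
    hi = np.minimum(ijk.max(axis=1) + pad_voxels + 1, shape)
    region = np.zeros(shape, dtype=bool)
    region[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return region


def check_current_conservation(result: FieldResult, region: np.ndarray) -> float:
    """Relative error of the current flux through a closed voxel surface.

    ``region`` is a boolean volume whose boundary is the surface; it must
    enclose exactly one electrode (i.e. the net current injected inside it
    must be nonzero).  Returns |flux / I_enclosed - 1|.
    """
    region = np.asarray(region, dtype=bool)
    model = result.model
    if region.shape != model.sigma.shape:
        raise GeometryError("region shape does not match the model grid")

    enclosed = 0.0
    rflat = region.ravel()
    for voxels, I in zip(model.electrode_voxels, model.currents_mA):
        inside = rflat[voxels]
        if inside.any() and not inside.all():
            raise GeometryError("region boundary cuts through an electrode")
        if inside.all():
            enclosed += I * 1e-3
    if enclosed == 0.0:
        raise GeometryError("region must enclose exactly one electrode "
                            "(net enclosed current is zero)")

    sig = np.minimum(model.sigma.sigma, model.sigma_clip)
    h_m = model.sigma.voxel_size_mm * 1e-3
    V = np.where(np.isfinite(result.potential), result.potential, 0.0)
    cond = sig > AIR_SIGMA_THRESHOLD

    flux = 0.0
    for axis in range(3):
        g = _face_conductances(sig, h_m, axis)
        sl1 = [slice(None)] * 3
        sl2 = [slice(None)] * 3
        sl1[axis] = slice(0, -1)
        sl2[axis] = slice(1, None)
        a, b_ = tuple(sl1), tuple(sl2)
        both = cond[a] & cond[b_]
        # faces crossing the region boundary, oriented outward
        out_lo = region[a] & ~region[b_] & both   # current a -> b leaves
        out_hi = ~region[a] & region[b_] & both   # current b -> a leaves
        flux += np.sum(g[out_lo] * (V[a][out_lo] - V[b_][out_lo]))
        flux += np.sum(g[out_hi] * (V[b_][out_hi] - V[a][out_hi]))
    return abs(flux / enclosed - 1.0)
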