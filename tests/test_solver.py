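"""Finite-volume solver: analytic oracles, conservation, invariances."""

import numpy as np
import pytest

from lesionfield import VolumeConductorModel, check_current_conservation
from lesionfield.exceptions import ConvergenceError, ParameterError, TopologyError
from lesionfield.phantom import ConductivityVolume
from lesionfield.solver import _face_conductances, _gradient_efield, electrode_box_region
from lesionfield.synthetic import make_slab_fixture


def slab_model(fx, tol=1e-10):
    return VolumeConductorModel(fx.sigma, fx.electrode_voxels, fx.currents_mA)


@pytest.fixture(scope="module")
def three_layer():
    fx = make_slab_fixture((10.0, 10.0, 10.0), (0.1, 1.0, 0.5),
                           current_density_A_per_m2=1.0)
    res = slab_model(fx).fit(tol=1e-10)
    return fx, res


class TestSlabOracles:
    def test_three_layer_magnitude_ratio(self, three_layer):
        """Series-resistor closed form: E_i = J/sigma_i gives 10:1:2."""
        fx, res = three_layer
        mags = [res.magnitude[m].mean() for m in fx.layer_interior_masks]
        assert mags[0] == pytest.approx(10.0, rel=0.01)
        assert mags[1] == pytest.approx(1.0, rel=0.01)
        assert mags[2] == pytest.approx(2.0, rel=0.01)

    def test_homogeneous_slab_ohms_law(self):
        fx = make_slab_fixture((20.0,), (0.4,), current_density_A_per_m2=2.0)
        res = slab_model(fx).fit(tol=1e-10)
        interior = fx.layer_interior_masks[0]
        expected = 2.0 / 0.4
        assert np.allclose(res.magnitude[interior], expected, rtol=0.005)

    def test_current_conservation(self, three_layer):
        fx, res = three_layer
        region = np.zeros(fx.sigma.shape, dtype=bool)
        region[:, :, : fx.sigma.shape[2] // 2] = True  # encloses the cathode plate
        assert check_current_conservation(res, region) <= 0.01

    def test_conservation_linear_in_current(self):
        fx1 = make_slab_fixture((10.0, 10.0), (0.2, 1.0), current_density_A_per_m2=1.0)
        fx2 = make_slab_fixture((10.0, 10.0), (0.2, 1.0), current_density_A_per_m2=2.0)
        r1 = slab_model(fx1).fit(tol=1e-10)
        r2 = slab_model(fx2).fit(tol=1e-10)
        region = np.zeros(fx1.sigma.shape, dtype=bool)
        region[:, :, :2] = True
        e1 = check_current_conservation(r1, region)
        e2 = check_current_conservation(r2, region)
        assert e1 == pytest.approx(e2, abs=1e-8)
        assert np.allclose(r2.potential, 2 * r1.potential, atol=1e-9)

    def test_doubling_conductivity_halves_potential(self):
        """sigma -> 2 sigma everywhere at fixed current halves V."""
        fx = make_slab_fixture((10.0, 10.0), (0.2, 0.8))
        sig1 = fx.sigma.copy()
        sig1.sigma = np.minimum(sig1.sigma, 50.0)  # modest plates so x2 is real
        sig2 = sig1.copy()
        sig2.sigma = 2.0 * sig1.sigma
        r1 = VolumeConductorModel(sig1, fx.electrode_voxels, fx.currents_mA).fit(1e-10)
        r2 = VolumeConductorModel(sig2, fx.electrode_voxels, fx.currents_mA).fit(1e-10)
        assert np.allclose(r2.potential, 0.5 * r1.potential, atol=1e-12)


class TestAssembly:
    def test_harmonic_mean_face_conductance(self):
        """Two voxels sigma1, sigma2: g = A/h * 2 s1 s2 / (s1 + s2)."""
        h = 2.0
        sig = np.array([[[0.3]], [[0.6]]])
        g = _face_conductances(sig, h * 1e-3, axis=0)
        expected = (h * 1e-3) * 2 * 0.3 * 0.6 / (0.3 + 0.6)
        assert g[0, 0, 0] == pytest.approx(expected)

    def test_all_air_raises(self):
        sigma = ConductivityVolume(np.full((4, 4, 4), 2.5e-14), 2.0, np.zeros(3))
        model = VolumeConductorModel(sigma, [np.array([0]), np.array([1])], [1.0, -1.0])
        with pytest.raises(TopologyError):
            model.assemble()

    def test_disconnected_domain_raises(self):
        sig = np.full((5, 5, 5), 2.5e-14)
        sig[0, 0, 0] = 1.0
        sig[4, 4, 4] = 1.0
        sigma = ConductivityVolume(sig, 2.0, np.zeros(3))
        model = VolumeConductorModel(sigma, [np.array([0]), np.array([124])], [1.0, -1.0])
        with pytest.raises(TopologyError):
            model.assemble()

    def test_nonzero_current_sum_rejected(self):
        sigma = ConductivityVolume(np.ones((3, 3, 3)), 2.0, np.zeros(3))
        with pytest.raises(ParameterError):
            VolumeConductorModel(sigma, [np.array([0]), np.array([1])], [1.0, -0.5])

    def test_row_sums_zero_away_from_sources(self):
        fx = make_slab_fixture((10.0, 10.0), (0.2, 1.0))
        model = slab_model(fx)
        A, b, unknown, flat_cond, ref, keep = model.assemble()
        # conservation structure: full matrix rows sum to ~0; in the reduced
        # matrix only rows adjacent to the pinned voxel have nonzero sums
        rowsum = np.abs(np.asarray(A.sum(axis=1)).ravel())
        scale = np.abs(A.diagonal())
        interior = rowsum / scale
        assert np.median(interior) < 1e-12

    def test_dense_direct_oracle_small_grid(self):
        """Iterative CG matches a dense direct solve to <= 1e-6 relatively."""
        fx = make_slab_fixture((8.0, 8.0), (0.3, 1.2), cross_section_mm=(12.0, 12.0))
        model = slab_model(fx)
        A, b, unknown, flat_cond, ref, keep = model.assemble()
        assert A.shape[0] <= 20 ** 3
        x_direct = np.linalg.solve(A.toarray(), b)
        res = model.fit(tol=1e-10)
        pot = res.potential.ravel()[flat_cond][keep]
        denom = np.linalg.norm(x_direct)
        assert np.linalg.norm(pot - x_direct) / denom <= 1e-6


class TestSolveProperties:
    def test_linearity_double_current(self, setup4):
        """2 mA solve equals 2 x the 1 mA solve voxelwise."""
        base = setup4["result"]
        model2 = VolumeConductorModel(setup4["sigma"],
                                      setup4["placed"].electrode_voxels,
                                      [2.0, -2.0])
        res2 = model2.fit(tol=1e-8)
        ok = np.isfinite(base.potential)
        denom = np.abs(base.potential[ok]).max()
        assert np.nanmax(np.abs(res2.potential - 2 * base.potential)) / (2 * denom) <= 1e-6
        assert np.max(np.abs(res2.efield - 2 * base.efield)) <= 2e-6 * base.magnitude.max()

    def test_polarity_swap_negates_field(self, setup4):
        base = setup4["result"]
        model = VolumeConductorModel(setup4["sigma"],
                                     setup4["placed"].electrode_voxels,
                                     [-1.0, 1.0])
        res = model.fit(tol=1e-8)
        # potentials are gauge-fixed at different electrodes: compare after
        # removing the mean over conductive voxels
        ok = np.isfinite(base.potential)
        va = base.potential[ok] - base.potential[ok].mean()
        vb = res.potential[ok] - res.potential[ok].mean()
        scale = np.abs(va).max()
        assert np.max(np.abs(va + vb)) / scale < 1e-6
        assert np.allclose(res.efield, -base.efield,
                           atol=1e-6 * base.magnitude.max())
        assert np.allclose(res.magnitude, base.magnitude,
                           atol=1e-6 * base.magnitude.max())

    def test_repeatability_bit_identical(self):
        fx = make_slab_fixture((10.0, 10.0), (0.2, 1.0))
        r1 = slab_model(fx).fit(tol=1e-10)
        r2 = slab_model(fx).fit(tol=1e-10)
        assert np.array_equal(np.nan_to_num(r1.potential), np.nan_to_num(r2.potential))
        assert np.array_equal(r1.efield, r2.efield)

    def test_residual_within_tolerance_and_summary(self, setup4):
        res = setup4["result"]
        assert res.converged and res.residual <= 1e-8
        text = res.summary()
        assert "residual" in text and "mA" in text

    def test_unconverged_solve_flagged(self):
        fx = make_slab_fixture((10.0, 10.0, 10.0), (0.1, 1.0, 0.5))
        with pytest.raises(ConvergenceError) as exc:
            slab_model(fx).fit(tol=1e-12, maxiter=1)
        assert exc.value.residual is not None and exc.value.residual > 1e-12

    def test_phantom_conservation_through_electrode_box(self, setup4):
        res = setup4["result"]
        region = electrode_box_region(res, 0)
        assert check_current_conservation(res, region) <= 0.01


class TestEfield:
    def test_linear_potential_gives_uniform_field(self):
        """V = -0.3 z volts -> E = (0, 0, 0.3) V/m."""
        shape = (6, 6, 6)
        h = 2.0
        z = (np.arange(shape[2]) * h * 1e-3)[None, None, :]
        V = np.broadcast_to(-0.3 * z, shape).copy()
        E, mag = _gradient_efield(V, h)
        assert np.allclose(E[..., 2], 0.3)
        assert np.allclose(E[..., :2], 0.0)
        assert np.allclose(mag, 0.3)

    def test_uniform_potential_gives_zero_field(self):
        V = np.full((5, 5, 5), 0.7)
        E, mag = _gradient_efield(V, 1.0)
        assert np.allclose(E, 0.0) and np.allclose(mag, 0.0)

    def test_one_sided_at_air_boundary(self):
        V = np.full((4, 4, 4), np.nan)
        h = 1.0
        z = np.arange(4) * h * 1e-3
        V[1:3, 1:3, :] = -0.5 * z[None, None, :]
        E, mag = _gradient_efield(V, h)
        assert np.allclose(E[1:3, 1:3, :, 2], 0.5)
        assert np.all(E[0, 0, :, :] == 0)  # air voxels carry zero field


def test_field_result_nifti_roundtrip(tmp_path, setup4):
    """Potential/E-field/magnitude export as NIfTI with correct geometry."""
    import nibabel as nib

    paths = setup4["result"].to_nifti(tmp_path)
    assert len(paths) == 3
    img = nib.load(str(paths[2]))  # magnitude
    assert img.shape == setup4["phantom"].shape
    assert float(img.affine[0, 0]) == setup4["phantom"].voxel_size_mm
    back = np.asarray(img.dataobj)
    assert np.allclose(back, setup4["result"].magnitude, atol=1e-5)
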