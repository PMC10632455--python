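"""Factorial experiment orchestration, trend fits, summaries, CLI."""

import numpy as np
import pandas as pd
import pytest

from lesionfield import ExperimentConfig, fit_trends, run_factorial, summarise
from lesionfield.exceptions import ConfigurationError, ParameterError
from lesionfield.experiment import RoiTarget
from lesionfield.synthetic import make_planted_table


def small_config(tmpdir=None, voxel=4.0):
    """Reduced factorial: 14 directions x 1 gap x 1 radius x 2 conductivities."""
    return ExperimentConfig(
        voxel_size_mm=voxel,
        gaps_mm=(1.0,),
        radii_mm=(12.0,),
        conductivities=(0.6, 1.8),
        solver_tol=1e-7,
        output_dir=str(tmpdir) if tmpdir else None,
    )


@pytest.fixture(scope="module")
def small_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    cfg = small_config(outdir)
    table = run_factorial(cfg)
    return cfg, outdir, table


class TestRunFactorial:
    def test_row_count_matches_grid(self, small_run):
        _, _, table = small_run
        assert len(table) == 14 * 1 * 1 * 2

    def test_valid_rows_have_effects(self, small_run):
        _, _, table = small_run
        valid = table[table["valid"] == True]  # noqa: E712
        assert len(valid) > 0
        assert valid["pct_diff"].notna().all()
        assert valid["angle_deg"].between(0, 180).all()
        invalid = table[table["valid"] != True]  # noqa: E712
        assert invalid["pct_diff"].isna().all()
        assert (invalid["exclusion_reason"] != "").all()

    def test_resume_skips_completed_rows(self, small_run, monkeypatch):
        """Re-running a completed directory performs zero new solves."""
        cfg, outdir, table = small_run
        import lesionfield.experiment as exp

        calls = {"n": 0}
        orig = exp.VolumeConductorModel.fit

        def counting_fit(self, *a, **kw):
            calls["n"] += 1
            return orig(self, *a, **kw)

        monkeypatch.setattr(exp.VolumeConductorModel, "fit", counting_fit)
        table2 = run_factorial(cfg)
        # one baseline solve per target still happens; no lesion re-solves
        assert calls["n"] <= len(cfg.targets)
        assert len(table2) == len(table)

    def test_default_enumeration_is_630_per_roi(self):
        cfg = ExperimentConfig()
        n = (len(cfg.directions) * len(cfg.gaps_mm) * len(cfg.radii_mm)
             * len(cfg.conductivities))
        assert n == 630

    def test_yaml_roundtrip(self, tmp_path):
        cfg = small_config()
        cfg.targets = [RoiTarget("t", (0, 0, 1.0), (0, 0, 1.0), (0, 1.0, 0))]
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = ExperimentConfig.from_yaml(path)
        assert back.voxel_size_mm == cfg.voxel_size_mm
        assert tuple(back.conductivities) == tuple(cfg.conductivities)
        assert back.targets[0].name == "t"


class TestFitTrends:
    def test_planted_angle_slope_recovery(self):
        """Noisy planted table: slope recovered within 3 standard errors."""
        planted = make_planted_table({"angle_deg": -0.06}, noise_sd=1.0,
                                     n_rows=630, seed=7)
        fit = fit_trends(planted.table, response="pct_diff")
        est = fit.params["angle_deg"]
        se = fit.bse["angle_deg"]
        assert abs(est - (-0.06)) <= 3 * se

    def test_noiseless_recovery_exact(self):
        planted = make_planted_table({"angle_deg": -0.06, "radius_mm": 0.4},
                                     noise_sd=0.0, n_rows=200, seed=0)
        fit = fit_trends(planted.table, response="pct_diff")
        assert fit.params["angle_deg"] == pytest.approx(-0.06, abs=1e-8)
        assert fit.params["radius_mm"] == pytest.approx(0.4, abs=1e-8)
        for term in ("angle_deg:gap_mm", "angle_deg:radius_mm"):
            assert fit.params[term] == pytest.approx(0.0, abs=1e-8)

    def test_constant_response_zero_slopes(self):
        planted = make_planted_table({"angle_deg": 0.0, "intercept": 5.0},
                                     noise_sd=0.0, n_rows=100, seed=0)
        fit = fit_trends(planted.table, response="abs_pct_diff")
        assert fit.params["Intercept"] == pytest.approx(5.0, abs=1e-8)
        assert fit.params["angle_deg"] == pytest.approx(0.0, abs=1e-10)

    def test_collinear_design_rejected(self):
        planted = make_planted_table(noise_sd=1.0, n_rows=100, seed=0)
        t = planted.table.copy()
        t["gap_mm"] = t["radius_mm"]  # duplicated predictor
        with pytest.raises(ConfigurationError) as exc:
            fit_trends(t, response="abs_pct_diff")
        assert "collinear" in str(exc.value)

    def test_too_few_rows_rejected(self):
        planted = make_planted_table(noise_sd=1.0, n_rows=40, seed=0)
        with pytest.raises(ParameterError):
            fit_trends(planted.table.head(10))

    def test_summary_available(self):
        planted = make_planted_table(noise_sd=1.0, n_rows=100, seed=0)
        fit = fit_trends(planted.table, response="pct_diff")
        assert "angle_deg" in str(fit.summary())


class TestSummarise:
    def test_single_row_verbatim(self):
        row = dict(phantom_id="p", roi_name="r", state_key="k", direction="I",
                   gap_mm=1.0, radius_mm=12.0, conductivity_S_per_m=1.8,
                   volume_fraction=1.0, valid=True, exclusion_reason="",
                   baseline_mean=0.5, diff_mean=0.05, diff_p16=0.0,
                   diff_p84=0.1, pct_diff=10.0, abs_pct_diff=10.0, angle_deg=20.0)
        rep = summarise(pd.DataFrame([row]))
        assert rep["n_solved"] == 1
        assert rep["pct_diff_by_direction"]["I"] == 10.0
        assert rep["abs_pct_diff_by_radius_mm"]["12.0"] == 10.0

    def test_all_invalid(self):
        rows = [dict(phantom_id="p", roi_name="r", state_key=str(i), direction="S",
                     gap_mm=1.0, radius_mm=24.0, conductivity_S_per_m=1.8,
                     volume_fraction=0.0, valid=False,
                     exclusion_reason="centre_outside_brain",
                     baseline_mean=0.5, diff_mean=np.nan, diff_p16=np.nan,
                     diff_p84=np.nan, pct_diff=np.nan, abs_pct_diff=np.nan,
                     angle_deg=np.nan) for i in range(4)]
        rep = summarise(pd.DataFrame(rows))
        assert rep["n_solved"] == 0
        assert sum(rep["exclusions"].values()) == 4

    def test_factor_means_match_hand_computation(self):
        rows = []
        for i, (rad, ab) in enumerate([(4.0, 1.0), (4.0, 3.0), (12.0, 5.0),
                                       (12.0, 7.0), (24.0, 9.0), (24.0, 11.0)]):
            rows.append(dict(phantom_id="p", roi_name="r", state_key=str(i),
                             direction="I", gap_mm=1.0, radius_mm=rad,
                             conductivity_S_per_m=1.8, volume_fraction=1.0,
                             valid=True, exclusion_reason="", baseline_mean=0.5,
                             diff_mean=0.0, diff_p16=0.0, diff_p84=0.0,
                             pct_diff=ab, abs_pct_diff=ab, angle_deg=10.0))
        rep = summarise(pd.DataFrame(rows))
        assert rep["abs_pct_diff_by_radius_mm"] == {"4.0": 2.0, "12.0": 6.0,
                                                    "24.0": 10.0}

    def test_empty_table_rejected(self):
        with pytest.raises(ParameterError):
            summarise(pd.DataFrame())


class TestCli:
    def test_lesions_and_report_roundtrip(self, tmp_path):
        from click.testing import CliRunner
        from lesionfield.cli import main

        runner = CliRunner()
        out = tmp_path / "states.csv"
        r = runner.invoke(main, ["lesions", "--voxel-size", "4.0",
                                 "--out", str(out)])
        assert r.exit_code == 0, r.output
        frame = pd.read_csv(out)
        assert len(frame) == 630

    def test_phantom_command_writes_nifti(self, tmp_path):
        from click.testing import CliRunner
        from lesionfield.cli import main
        from lesionfield.phantom import load_label_volume

        runner = CliRunner()
        out = tmp_path / "phantom.nii.gz"
        r = runner.invoke(main, ["phantom", "--voxel-size", "4.0",
                                 "--out", str(out)])
        assert r.exit_code == 0, r.output
        vol = load_label_volume(out)
        assert vol.voxel_size_mm == 4.0
        assert vol.brain_mask.sum() > 0
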