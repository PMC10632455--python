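"""Factorial lesion experiments and trend models on the results table.

``run_factorial`` orchestrates the whole study on a phantom: solve the
non-lesioned baseline once per ROI/montage, then every valid lesion state,
and emit one table row per state.  Runs are resumable: each state is
content-addressed by a hash of its spec plus the solver/phantom
configuration, and rows already present in the output CSV are skipped.

``fit_trends`` replaces the mixed-effects analysis with ordinary least
squares on the factorial table (a phantom has no subject-level random
effect; multi-phantom tables carry a ``phantom_id`` column so mixed models
can be fitted externally).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import lesion_effect, roi_stats
from .exceptions import ConfigurationError, ParameterError
from .lesions import (DEFAULT_CONDUCTIVITIES, DEFAULT_GAPS_MM, DEFAULT_RADII_MM,
                      DIRECTION_LABELS, enumerate_states)
from .phantom import (DEFAULT_SHELL_RADII_MM, Electrode, LabelVolume, assign_conductivity,
                      build_phantom, define_roi, place_electrodes, scalp_position)
from .solver import VolumeConductorModel

__all__ = ["RoiTarget", "ExperimentConfig", "TrendFit", "run_factorial",
           "fit_trends", "summarise"]

RESULT_COLUMNS = [
    "phantom_id", "roi_name", "state_key", "direction", "gap_mm", "radius_mm",
    "conductivity_S_per_m", "volume_fraction", "valid", "exclusion_reason",
    "baseline_mean", "diff_mean", "diff_p16", "diff_p84",
    "pct_diff", "abs_pct_diff", "angle_deg",
]


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


@dataclass
class RoiTarget:
    """One stimulation target: ROI direction plus its bipolar montage.

    Directions are unit vectors from the head centre; the anode
    conventionally sits over the target and the cathode contralateral
    (e.g. over the opposite orbit), mimicking motor/language montages.
    """

    name: str
    roi_direction: tuple[float, float, float]
    anode_direction: tuple[float, float, float]
    cathode_direction: tuple[float, float, float]
    current_mA: float = 1.0
    roi_radius_mm: float = 12.0


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a factorial run."""

    shell_radii_mm: tuple = DEFAULT_SHELL_RADII_MM
    voxel_size_mm: float = 2.0
    targets: list[RoiTarget] = dc_field(default_factory=lambda: [
        RoiTarget(name="M1-like",
                  roi_direction=(0.0, 0.0, 1.0),
                  anode_direction=(0.0, 0.0, 1.0),
                  cathode_direction=(0.0, 0.9396926207859084, 0.3420201433256687)),
    ])
    directions: tuple = DIRECTION_LABELS
    gaps_mm: tuple = DEFAULT_GAPS_MM
    radii_mm: tuple = DEFAULT_RADII_MM
    conductivities: tuple = DEFAULT_CONDUCTIVITIES
    conductivity_overrides: dict = dc_field(default_factory=dict)
    solver_tol: float = 1e-8
    electrode_disc_radius_mm: float = 17.0
    electrode_thickness_mm: float = 2.0
    output_dir: str | None = None
    phantom_id: str = "phantom-01"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        targets = [RoiTarget(**t) for t in raw.pop("targets", [])]
        cfg = cls(**raw) if not targets else cls(targets=targets, **raw)
        if len(cfg.targets) == 0:
            raise ConfigurationError("at least one ROI target is required")
        return cfg

    def to_yaml(self, path) -> None:
        raw = {
            "shell_radii_mm": list(self.shell_radii_mm),
            "voxel_size_mm": self.voxel_size_mm,
            "targets": [vars(t) for t in self.targets],
            "directions": list(self.directions),
            "gaps_mm": list(self.gaps_mm),
            "radii_mm": list(self.radii_mm),
            "conductivities": list(self.conductivities),
            "conductivity_overrides": dict(self.conductivity_overrides),
            "solver_tol": self.solver_tol,
            "electrode_disc_radius_mm": self.electrode_disc_radius_mm,
            "electrode_thickness_mm": self.electrode_thickness_mm,
            "output_dir": self.output_dir,
            "phantom_id": self.phantom_id,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    def _context_hash(self) -> str:
        ctx = (tuple(self.shell_radii_mm), self.voxel_size_mm, self.solver_tol,
               tuple(sorted(self.conductivity_overrides.items())),
               self.electrode_disc_radius_mm, self.electrode_thickness_mm)
        return hashlib.sha1(repr(ctx).encode()).hexdigest()[:8]

    def state_key(self, roi_name: str, spec_key: tuple) -> str:
        payload = repr((self.phantom_id, roi_name, spec_key, self._context_hash()))
        return hashlib.sha1(payload.encode()).hexdigest()[:16]


def run_factorial(config: ExperimentConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full factorial lesion study described by ``config``.

    Returns one row per lesion state per target.  Invalid states carry
    their exclusion reason and NaN field values.  If ``config.output_dir``
    is set, rows are appended to ``results.csv`` there and states whose
    key already appears in that file are not re-solved (resume semantics).
    """
    outdir = Path(config.output_dir) if config.output_dir else None
    existing = pd.DataFrame(columns=RESULT_COLUMNS)
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        csv = outdir / "results.csv"
        if csv.exists():
            existing = pd.read_csv(csv, keep_default_na=False,
                                   na_values=[""], dtype={"state_key": str})
    done = set(existing["state_key"]) if len(existing) else set()

    phantom = build_phantom(config.shell_radii_mm, config.voxel_size_mm)
    gm_mask = phantom.mask("gm")

    iterator = config.targets
    rows: list[dict] = []
    for target in iterator:
        roi = define_roi(phantom, _unit(target.roi_direction), target.roi_radius_mm)
        montage = [
            Electrode(tuple(scalp_position(phantom, _unit(target.anode_direction))),
                      +target.current_mA, config.electrode_disc_radius_mm,
                      config.electrode_thickness_mm),
            Electrode(tuple(scalp_position(phantom, _unit(target.cathode_direction))),
                      -target.current_mA, config.electrode_disc_radius_mm,
                      config.electrode_thickness_mm),
        ]
        placed = place_electrodes(phantom, montage)
        base_sigma = assign_conductivity(placed, config.conductivity_overrides)
        baseline = VolumeConductorModel(base_sigma, placed.electrode_voxels,
                                        [e.current_mA for e in montage]
                                        ).fit(tol=config.solver_tol)
        baseline_stats = roi_stats(baseline.magnitude, baseline.efield, roi,
                                   gm_mask, phantom)

        states = enumerate_states(roi, phantom, config.directions, config.gaps_mm,
                                  config.radii_mm, config.conductivities)
        it = states
        if progress:
            from tqdm import tqdm
            it = tqdm(states, desc=target.name)
        for st in it:
            key = config.state_key(target.name, st.key)
            if key in done:
                continue
            row = {
                "phantom_id": config.phantom_id, "roi_name": target.name,
                "state_key": key, "direction": st.spec.direction_label,
                "gap_mm": st.spec.gap_mm, "radius_mm": st.spec.radius_mm,
                "conductivity_S_per_m": st.spec.conductivity_S_per_m,
                "volume_fraction": st.volume_fraction, "valid": st.valid,
                "exclusion_reason": st.exclusion_reason or "",
                "baseline_mean": baseline_stats.mean_mag,
            }
            if st.valid:
                try:
                    sigma = base_sigma.copy()
                    sigma.sigma[st.mask] = st.spec.conductivity_S_per_m
                    lesioned = VolumeConductorModel(
                        sigma, placed.electrode_voxels,
                        [e.current_mA for e in montage]).fit(tol=config.solver_tol)
                    eff = lesion_effect(st, lesioned, baseline, roi, gm_mask,
                                        phantom, baseline_stats)
                    row.update(diff_mean=eff.diff_mean, diff_p16=eff.diff_p16,
                               diff_p84=eff.diff_p84, pct_diff=eff.pct_diff,
                               abs_pct_diff=eff.abs_pct_diff,
                               angle_deg=eff.angle_deg)
                except Exception as exc:  # noqa: BLE001 - keep the run going
                    row["exclusion_reason"] = f"solver_failure: {exc}"
                    row["valid"] = False
            rows.append(row)

    new = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if len(existing) == 0:
        table = new
    elif len(new) == 0:
        table = existing
    else:
        table = pd.concat([existing, new], ignore_index=True)
    if outdir is not None:
        table.to_csv(outdir / "results.csv", index=False)
    return table


@dataclass
class TrendFit:
    """OLS trend-model results on the factorial table.

    Wraps the statsmodels results object; ``params``/``bse``/``conf_int``
    are indexed by term name.
    """

    response: str
    params: pd.Series
    bse: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    rsquared: float
    nobs: int
    sm_results: object = None

    def summary(self):
        return self.sm_results.summary()


def fit_trends(table: pd.DataFrame, response: str = "abs_pct_diff",
               min_rows: int = 30) -> TrendFit:
    """OLS trend model over valid rows of the factorial results table.

    Main effects: angle_deg, gap_mm, radius_mm, conductivity_S_per_m.  For
    the signed ``pct_diff`` response, angle interactions with gap, radius
    and conductivity are added (the sign structure depends on where the
    lesion sits relative to the current path).
    """
    import statsmodels.formula.api as smf

    if response not in ("abs_pct_diff", "pct_diff"):
        raise ParameterError(f"unsupported response {response!r}")
    data = table[table["valid"] == True].copy()  # noqa: E712 - CSV bools
    data = data.dropna(subset=[response, "angle_deg"])
    if len(data) < min_rows:
        raise ParameterError(f"need at least {min_rows} valid rows, got {len(data)}")
    if not np.isfinite(data[response]).all():
        raise ParameterError("non-finite response values")

    terms = ["angle_deg", "gap_mm", "radius_mm", "conductivity_S_per_m"]
    if response == "pct_diff":
        terms += ["angle_deg:gap_mm", "angle_deg:radius_mm",
                  "angle_deg:conductivity_S_per_m"]
    formula = f"{response} ~ " + " + ".join(terms)

    model = smf.ols(formula, data=data)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        # identify collinear columns by QR diagonal
        _, r = np.linalg.qr(model.exog)
        bad = [model.exog_names[k] for k in range(r.shape[1])
               if abs(r[k, k]) < 1e-8 * abs(r[0, 0])]
        raise ConfigurationError(f"rank-deficient design; collinear columns: {bad}")
    res = model.fit()
    return TrendFit(response=response, params=res.params, bse=res.bse,
                    conf_int=res.conf_int(), pvalues=res.pvalues,
                    rsquared=float(res.rsquared), nobs=int(res.nobs),
                    sm_results=res)


def summarise(table: pd.DataFrame) -> dict:
    """Descriptive report of a factorial run (JSON-serialisable).

    Per-factor means of the absolute percentage difference, per-direction
    signed means, and exclusion accounting.
    """
    if len(table) == 0:
        raise ParameterError("empty results table")
    valid = table[table["valid"] == True]  # noqa: E712
    report = {
        "n_states": int(len(table)),
        "n_solved": int(len(valid)),
        "exclusions": {str(k): int(v) for k, v in
                       table.loc[table["valid"] != True, "exclusion_reason"]
                       .value_counts().items()},
    }
    if len(valid):
        for factor in ("radius_mm", "gap_mm", "conductivity_S_per_m"):
            report[f"abs_pct_diff_by_{factor}"] = {
                str(k): float(v) for k, v in
                valid.groupby(factor)["abs_pct_diff"].mean().items()}
        report["pct_diff_by_direction"] = {
            str(k): float(v) for k, v in
            valid.groupby("direction")["pct_diff"].mean().items()}
        report["baseline_mean_V_per_m"] = float(valid["baseline_mean"].iloc[0])
    return report
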