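# lesionfield

Brain lesions distort the electric field that transcranial direct current
stimulation (tDCS) delivers to a cortical target — a problem for anyone
using tDCS in stroke rehabilitation, where every brain has a lesion.
`lesionfield` is a desk-scale pipeline for studying this systematically:
it solves the quasi-static volume-conduction problem on voxelised head
models with a dedicated **lesion** tissue compartment, sweeps a factorial
family of synthetic spherical lesions around a target region of interest
(ROI), and quantifies how each lesion changes the field — including the
two individualisation strategies that can compensate for it (electrode
montage re-optimisation and stimulator-output rescaling).

## The model

Under the quasi-static approximation the potential $V$ in a head with
conductivity $\sigma(\mathbf{r})$ satisfies

$$\nabla \cdot (\sigma \nabla V) = 0,$$

with no current through the scalp except at the electrodes, where the
stimulator current (±1 mA by default) is injected. The electric field is
$\mathbf{E} = -\nabla V$ (V/m). The domain is a voxelised multi-shell
spherical head phantom (air, skin, skull, CSF, grey matter, white matter,
plus lesion, gel and electrode labels; a user-supplied NIfTI label volume
with the same convention also works). The discretisation is cell-centred
finite volume: one unknown per conductive voxel, harmonic-mean face
conductances, and a conjugate-gradient solve that is verified against its
*true* residual.

Each lesion state is a sphere with a **direction** (14 cardinal and
intercardinal labels: R, L, A, P, S, I, RAS, RAI, RPS, RPI, LAS, LAI,
LPS, LPI), an edge-to-edge **gap** from the ROI (1/5/10 mm), a **radius**
(4/12/24 mm) and a **conductivity** (0.2–1.8 S/m), constrained to grey and
white matter — the default grids give the full 630-state factorial per
ROI. States whose centre leaves the brain, or that retain under 20 % of
their volume, are excluded. Outcomes per state: the ROI mean / 16th / 84th
percentile of the lesioned-minus-baseline magnitude difference, the signed
and absolute percentage change of the ROI mean, and the **lesion angle** —
the angle between the ROI→lesion direction and the mean current direction
in the non-lesioned ROI (0° = lesion squarely in the path of current).

## Worked example

```python
from lesionfield import ExperimentConfig, run_factorial, summarise, fit_trends

cfg = ExperimentConfig(voxel_size_mm=3.0, gaps_mm=(1.0, 10.0),
                       radii_mm=(4.0, 24.0), conductivities=(0.6, 1.8),
                       solver_tol=1e-7)
table = run_factorial(cfg)
report = summarise(table)
```

On the default phantom (shells 92/86/80/78/70 mm; anode over the vertex
target, cathode 70° away; 1 mA) this solves 48 valid lesion states (64 of
the 112 are excluded because a large or distant lesion's centre leaves the
brain shell) around a baseline ROI mean of **0.839 V/m** and prints, among
others:

```
abs_pct_diff by radius:        4 mm -> 0.61 %    24 mm -> 4.59 %
abs_pct_diff by gap:           1 mm -> 3.30 %    10 mm -> 0.82 %
abs_pct_diff by conductivity:  0.6  -> 1.75 %    1.8   -> 2.79 %
pct_diff by direction:         I -> +4.36 %      P -> -1.18 %
```

Larger, closer, more conductive lesions perturb the target field more,
and the *sign* depends on where the lesion sits relative to the current:
a CSF-like lesion downstream of the ROI (small angle) increases the ROI
field, while off-path lesions decrease it. An OLS trend fit
(`fit_trends(table, "pct_diff")`) on this run recovers an angle slope of
−0.012 %/° with the angle×conductivity interaction at −0.027.

Montage and dose individualisation live in `lesionfield.optimise`:

```python
from lesionfield import individualise_dose
adj = individualise_dose(target_mag=0.2, actual_mag=0.839, fixed_dose_mA=1.0)
adj.individualised_dose_mA   # 0.238 mA — rescaled output hits the target
```

A thin CLI wraps the same calls: `lesionfield phantom`, `lesionfield
lesions`, `lesionfield run`, `lesionfield report`, `lesionfield optimise`.

## Acceptance script

`scripts/acceptance.py` re-runs the pipeline from scratch — the reduced
factorial above, the trend fits, a planted-slope recovery, dose
individualisation and a small exhaustive montage search — and writes a
JSON manifest:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

A human-readable report of the run lands next to the manifest as
`report.json`.
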