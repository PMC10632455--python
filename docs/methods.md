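# Methods

## Head phantom

The phantom is a nested set of concentric spheres standing in for a
segmented structural MRI: skin, skull, CSF, grey matter (GM) and white
matter (WM), with air outside. Default outer radii are 92/86/80/78/70 mm
— typical adult five-shell head dimensions. Voxels are labelled by the
distance of their centre from the head centre; coordinates are RAS
millimetres (+x Right, +y Anterior, +z Superior), voxel-centre
addressing. The default voxel size is 2 mm (desk scale); 1 mm is
supported but ~8× more voxels. Phantom generation is deterministic.

What the phantom deliberately lacks: gyri and sulci, a CSF geometry with
folds, skull inhomogeneity, and any left/right asymmetry. A green test on
the phantom therefore establishes the *mechanics* of the pipeline and the
conductor physics of smooth layered media — not the anatomy-dependent
details of field distributions in real heads (see "Directional effects"
below for the one place this matters scientifically).

The ROI is a 12 mm sphere placed at GM mid-thickness along a chosen
direction (for the default shells, 74 mm from the centre) — the size
conventionally used for motor-cortex or Broca-area stimulation targets.

Tissue conductivities (S/m): WM 0.126, GM 0.276, CSF 1.65, skull 0.465,
skin 0.126, air 2.5e-14, gel 0.3, electrode 5.9e7. Lesion conductivity is
the experimental variable (grid 0.2–1.8 S/m, spanning roughly
GM-like to above-CSF values). Electrodes are 17 mm radius, 2 mm thick
discs realised as one voxel layer of gel on the scalp plus conductor
voxels, with current injected uniformly over each electrode's conductor
voxels; a montage must carry zero net current.

## Solver

Cell-centred finite volume on the voxel grid: one unknown per conductive
voxel, face conductances $g = (A/h)\,\frac{2\sigma_1\sigma_2}{\sigma_1+\sigma_2}$
(harmonic mean — exact for layered media), zero normal current on the
outer boundary, gauge fixed by pinning one cathode voxel to 0 V. The
reduced system is symmetric positive definite and solved by conjugate
gradients on the symmetrically Jacobi-scaled matrix, with a fixed zero
initial guess so repeated solves are bit-identical.

Two numerical choices deserve a note:

* **Conductivity clipping.** Values above 1000 S/m are clipped inside the
  discretisation only. The metal electrode label (5.9e7 S/m) would give
  the matrix a ~9-decade conductance contrast under which conjugate
  gradients stall at a true relative residual of ~3e-5 even though the
  recursively-updated internal residual claims convergence. Physically
  the clip is inconsequential: the pad's internal resistance is of order
  1e-6 Ω at 1000 S/m against tissue resistances of tens of ohms, and ROI
  means agree to more than five decimals with and without the clip. The
  conductivity *table* is untouched — only the face-conductance
  computation clips.
* **True-residual verification.** After each CG run the solver recomputes
  the actual scaled residual and restarts CG from the current iterate if
  it misses the tolerance (up to 8 rounds within the global iteration
  cap). The reported `residual` is therefore honest; a solve that cannot
  reach tolerance raises rather than returning quietly.

Defaults: relative tolerance 1e-8 (conservation errors then sit around
1e-11, far below percent-level lesion effects); factorial sweeps use 1e-7
for speed. The E-field is $-\nabla V$ by central differences, one-sided at
tissue–air boundaries; air voxels carry zero field. Current conservation
can be checked through any closed voxel surface enclosing one electrode.

Isotropic conductivity only; WM anisotropy is out of scope.

## Lesion states and exclusion rules

Lesion centre = ROI centre + direction × (ROI radius + gap + lesion
radius), so the edge-to-edge distance equals the gap exactly. Masks are
rasterised by voxel-centre containment and intersected with GM∪WM. A
state is excluded if the voxel containing its centre is not GM/WM
("centre outside brain") or if the surviving volume fraction is below
20 % — the threshold is inclusive (exactly 0.20 is valid). The fraction's
denominator is the unconstrained sphere's voxel count on the same grid,
so on-grid discretisation cancels. Enumeration order is fixed (direction,
gap, radius, conductivity) and conductivity variants share one rasterised
mask.

## Outcome measures

* Difference image: lesioned minus non-lesioned magnitude.
* ROI statistics: mean, 16th and 84th percentile over GM voxels whose
  centres fall in the ROI sphere. Percentiles use linear interpolation
  between order statistics (numpy's default), stated here so the
  sort-based test oracle matches exactly. The difference percentiles are
  computed on the voxelwise difference image, not on the two magnitude
  images separately.
* Percentage difference: 100 × (lesioned − baseline)/baseline of the ROI
  *mean* magnitude; the baseline (non-lesioned) mean is the denominator.
  By solver linearity this is independent of the applied current.
* Mean current direction: the normalised mean of the raw E-vectors over
  ROI GM (not a mean of unit vectors), so strong coherent current
  dominates; computed on the *non-lesioned* solution.
* Lesion angle: angle between the ROI-centre→lesion-centre vector and the
  mean current direction, in [0°, 180°]. Centre-to-centre, not
  edge-to-edge.

## Directional effects on a spherical phantom

Two geometry-driven caveats for interpreting the angle analyses:

1. With the default montage (anode over the target, cathode 70° away,
   like a motor montage), the ROI current is predominantly radially
   inward, and lesions with angles above ~90° barely exist: a lesion
   displaced radially *outward* from a mid-GM ROI exits the brain shell
   and is excluded by the centre-in-brain rule. The headline directional
   check (small-angle lesions increase the ROI field) is therefore
   one-sided on this phantom.
2. If the montage is instead arranged so the ROI current is tangential
   (electrodes symmetric about the target), upstream states do exist —
   and a CSF-like lesion there *increases* the ROI field, same as a
   downstream one. That is textbook conductor physics: a conductive
   sphere in a locally uniform field enhances the field at both of its
   poles and reduces it at its equator (an even, quadrupole-like angular
   response). The odd, sign-flipping angle response reported for real
   heads rides on layered/gyral anatomy (superficial shunt paths above
   the target) that a smooth spherical phantom does not have. The
   package's factorial machinery reproduces the monotone distance, size
   and conductivity trends and the angle-interaction structure, but not
   the anatomy-dependent upstream sign flip.

## Trend models

`fit_trends` fits ordinary least squares on the factorial table: main
effects of angle, gap, radius and conductivity for `abs_pct_diff`, plus
angle×gap, angle×radius and angle×conductivity interactions for the
signed `pct_diff`. OLS replaces a mixed-effects analysis deliberately: a
phantom run has a single "subject", so there is no random-intercept
structure to estimate; multi-phantom tables carry a `phantom_id` column
so mixed models can be fitted externally. The design matrix is checked
for full rank and collinear columns are named in the error.

The synthetic `make_planted_table` generator produces tables with known
linear structure (angle uniform on [0°, 180°], factors cycling through
the default grids, Gaussian noise on the response) for calibrating slope
recovery; Gaussian noise reflects the approximately normal residuals such
factorial tables show. All randomness flows through one explicitly-seeded
generator.

## Montage optimisation and dose individualisation

Candidate electrode sites are Fibonacci-sphere points restricted to
latitudes above −30° (a stand-in for a scalp electrode grid on a phantom
without fiducials), projected to the scalp. The search is exhaustive over
ordered anode/cathode pairs — exact and self-oracling at ≤ ~64
candidates — under either objective: mean ROI GM magnitude, or the mean
*signed* component of E along the inward cortical normal (on the phantom,
the inward radial direction; for arbitrary volumes a smoothed GM-gradient
normal would be substituted). The signed mean was chosen over
inward-only rectification because it penalises montages that drive
current outward through part of the ROI. Ties break on the lowest
(anode, cathode) index pair; per-pair solver failures are skipped and
counted.

Dose individualisation applies
dose = (target magnitude / achieved magnitude) × fixed dose,
exact by linearity of the conduction problem, with an explicit
per-electrode safety cap (default 4 mA, configurable) — the cap is a
stated configuration rather than an implied guideline.

## Degenerate inputs and tie-breaks

Non-descending shell radii, non-unit ROI directions, unknown direction
labels, zero-current-sum montages, single electrodes and overlapping
discs all raise typed errors; an all-air or disconnected conductive
domain raises a topology error before assembly returns. Lesion radii
under half a voxel are rejected as degenerate. A zero mean E-vector in
the ROI yields a zero direction vector and the angle computation then
raises, rather than fabricating a direction.

## Known limitations

* Smooth spherical anatomy only — see "Directional effects" above.
* Voxel staircase boundaries bias patch areas and thin-shell (CSF)
  conduction at coarse voxels; 3–4 mm grids are adequate for relative
  lesion effects, not absolute dosimetry.
* The complete-electrode model (contact impedance) is not implemented;
  highly conductive electrode voxels with uniform current injection play
  that role.
* Lesions are spheres by design, for parametric comparability — not
  morphologically realistic strokes.
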