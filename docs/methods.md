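# Methods

## Problem and scope

The package benchmarks indirect estimators of single-axon path length against
the ground truth defined by a 3D digital reconstruction: the sum of Euclidean
edge lengths over the axonal (structure code 2) edges of an SWC file.
Coordinates are micrometres throughout; radii are parsed but ignored — the
axon is treated as a space curve. Multi-root SWC files are accepted and all
axonal edges contribute regardless of tree membership. Dendrite morphometrics,
topological analysis, and repair of corrupt reconstructions are out of scope.

## Projection correction

The orthogonal projection of a segment with polar angle θ to the projection
axis has length `ℓ·sin θ`; averaging over the uniform sphere gives
`E[sin θ] = π/4`, hence 3D length = (4/π) × expected projected length for
zero-anisotropy curves (and π/2 for planar curves projected to a line). Real
arbors are anisotropic, so per-class empirical factors α are estimated by
least squares of 3D length on projected length with class as a factor.

Choices made where the procedure was genuinely open:

- **Through-origin regression.** The slopes are interpreted directly as
  multiplicative correction factors, which forces a zero intercept; a
  common-intercept variant is kept as an option (`fit_alpha(...,
  intercept=True)`). Adjusted R² is reported from the pooled fit.
- **Residual ("error-resampling") bootstrap.** Residuals of the within-class
  fit are resampled with replacement, added back to fitted values, and the
  slope refitted; CI95 is the 2.5–97.5 percentile band of the 2000 draws
  (default). A convergence stop-criterion (batches of 100 until the CI bounds
  move by < 0.1% of α) is available via `stop_tol`, but fixed counts are the
  default so results are exactly reproducible. The reported interval is
  widened, if necessary, to contain the point estimate.
- **Cross-validation.** Signed out-of-sample errors
  `100·(α̂·L2D − L3D)/L3D` come from 5-fold CV inside each (class, plane)
  stratum, repeated over 100 bootstrap resamples and pooled.

The residual bootstrap assumes exchangeable residuals; under noise
proportional to size its percentile interval is only approximately calibrated,
which is why the coverage check uses a homogeneous-length design (2D lengths
~ Normal(30 000, 1 500) µm, noise sd 2% of each length, n = 300).

## Stereological simulation

Sectioning and sampling follow the standard microscope workflow: half-open
50 µm z-slabs, and within each section a square grid of sampling boxes
(default 50×50×50 µm³) with period `step ≥ box`. Placement is systematic
uniform random (SURS): one uniform z-phase for the section stack, an
independent uniform XY-phase per section, and — when `box_z` is smaller than
the section thickness — a uniform height offset inside the section. Boxes are
instantiated at every grid node whose half-open footprint overlaps the
geometry's bounding box. Two named profiles exist: `computational`
(50×50×50 boxes filling the section) and `lab-table1` (50×50×10 boxes,
spacing 5 µm, step 75 µm — the microscope settings of the bundled six-neuron
comparison).

**Probes.** Spheres are centred in their box (diameter ≤ box edges);
crossings solve the segment–sphere quadratic. Plane stacks draw one
orientation per box, uniform on the upper hemisphere (antipodal normals give
identical planes), plus a uniform phase in [0, spacing); crossing points must
fall inside the half-open box. Degenerate events follow deterministic rules:
tangency (zero discriminant) counts 0, a segment lying in a plane counts 0,
box membership is half-open per axis, and crossing parameters use t ∈ [0, 1)
so a shared polyline vertex on a probe surface is counted once. Segments are
never clipped to sections; only crossing-point membership decides counting.

**Estimator.** `L̂ = 2·ΣQ·(v/a)/f` with probe area `a = πd²` (sphere) or
`a = v/spacing` (planes, exact in expectation over the phase for any
orientation), and sampled fraction `f = (box_xy/step)²·(box_z/T)`. The height
factor makes the thin-box laboratory profile consistent; it is 1 for the
default cubic boxes. Unbiasedness for isotropic probe–fiber encounters
follows from `E[Q] = L·a/(2v)` per sampled box and is verified by Monte-Carlo
(mean over 500 independent frames within 2% for planes, 3% for spheres —
sphere counts are ~6× sparser at the tested settings, hence the wider band).
An exact per-box plane∩box polygon area is *not* computed; the expectation
form is unbiased and simpler.

**CE.** The Gundersen-type coefficient of error of one systematic sample:
`CE = √(Noise + Var_SURS)/ΣQ`, `Noise = ΣQ`,
`Var_SURS = (3A − 4B + C)/12` with `A = ΣQᵢ²`, `B = ΣQᵢQᵢ₊₁`, `C = ΣQᵢQᵢ₊₂`,
over counts ordered along the section-major sampling path. Published variants
differ in the noise and smoothness terms; this is the classical choice, so CE
values should be compared across runs of this package, not across software.

## Synthetic data

The generator provides the study conditions for every Monte-Carlo claim:

- `isotropic_polyline` — segment directions iid uniform on S² (normalized
  Gaussian triples); total length exact by construction. This is the analytic
  reference for 4/π.
- `fiber_slab` — an unbranched persistent walk confined to one slab by
  splitting steps at the faces and reflecting; used for estimator bias/effort
  studies where the whole fiber must sit in a known number of sections.
  Reflection mildly distorts the direction distribution near the faces, so
  4/π is not exact here and is never asserted on slabs.
- `synth_axon` — schematic arbors of the four architecture classes: focal
  (trunk + one dense terminal cluster), multi-focal (trunk + several separated
  clusters), disperse (sparse arbor in a large ball), local (arbor around the
  soma). Growth is a branching random walk with fixed 10 µm steps, a fixed
  per-step branching probability inside cluster phases, and von Mises–Fisher
  directional persistence κ about the current heading (κ = 0 recovers
  isotropic growth; the inverse-CDF vMF sampler is used). Length budgets are
  closed exactly by trimming the final step. Defaults (30 000 µm target,
  4 000 µm trunk, 250 µm clusters, 1 500 µm dispersion) are placeholders at
  mouse thalamocortical scale — no published per-class morphometry constrains
  them, and they claim nothing about biology.

What the synthetic classes do *not* emulate: realistic branch-order
statistics, diameter taper, tortuosity spectra of real axons, tissue
deformation, or the length distribution of any curated database sample.
Passing Monte-Carlo tests therefore demonstrates correctness of the
*estimators and their sampling mathematics*, not field performance on any
particular real dataset; dataset-level error magnitudes depend on the
morphologies analyzed.

All randomness uses NumPy's PCG64 (`default_rng`); replicate streams are
derived with `SeedSequence((master, neuron, combo, replicate))`, so every
record of a sweep is individually reproducible.

## Benchmark statistics

Signed error is uniformly `100·(estimate − truth)/truth` (absolute error is
its magnitude; raw µm differences are stored alongside). Error densities are
Gaussian KDEs with Silverman ("automatic") bandwidth; a zero-spread sample is
represented as a point mass. `P(|err| ≤ τ)` is the density mass on [−τ, τ].
Error/effort surfaces are node-exact aggregates over the parameter grid with
bilinear interpolation between nodes and no extrapolation. The accuracy of a
mean error is its t-based upper 95% confidence limit. Normalized RMSE per
parameter combination comes from 5-fold CV of a linear model of true length
on estimate, normalized by the training-fold range of true lengths. The
expected-error report rounds per-item percentages and their unrounded mean to
2 decimals.

Default grids mirror standard practice: sphere diameters 10–50 µm (step 5),
plane spacings 3–30 µm (step 3), grid steps 70–150 µm (step 10).

## Problem sizes

Monte-Carlo checks use 400 000 segments for the 4/π identity, 20 000 µm slab
fibers with 500 sampling frames for estimator bias, 200 frames for effort
orderings, and 20 000 µm class 1–3 arbors with 8 replicates for the
planes-vs-spheres comparison — sizes at which the expected Monte-Carlo error
is several times smaller than the asserted tolerances.

## Known limitations

- Guard zones and z-shrinkage correction are not modelled (real tissue shrinks
  up to ~70% axially after dehydration; measurements on tissue need that
  correction, the simulation does not).
- The plane counter draws one orientation per box independently; correlated
  orientation designs (e.g. one orientation per section) are not implemented.
- `fit_alpha` CIs are percentile bootstrap only; BCa is not provided.
- Population-level (multi-neuron) stereology and interactive on-microscope
  sampling are out of scope.
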