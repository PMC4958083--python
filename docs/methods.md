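# Methods

## Scope and data model

The package operates on coregistered volumes from a hybrid PET/CT
acquisition: a low-dose CT in Hounsfield units on its native grid
(1.17 × 1.17 × 5.00 mm) and a series of PET volumes in Bq/mL on a 4 mm
isotropic grid, one per scan time (default 1, 24, 48, 96 and 144 h post
injection). Arrays are indexed (x, y, z); voxel (i, j, k) is centred at
`origin + index·spacing` in mm. Acquisition metadata that NIfTI cannot
carry (modality, time post injection, injected activity, patient weight)
lives in a JSON sidecar. Volumes are assumed coregistered; registration is
out of scope.

## Rebinning

The CT is resampled onto the PET grid with trilinear interpolation at
output voxel centres. The output grid is anchored at the input origin with
`ceil(extent/spacing)` voxels per axis, or pinned to an explicit matrix
(`target_shape`) when the mask must lie voxel-for-voxel on a given PET
grid — necessary in general because the CT and PET fields of view differ.
Out-of-support queries clamp to edge values rather than inventing HU.
Trilinear weights are convex, so output values are bounded by the input
range, and affine intensity fields are reproduced exactly at interior
sample points; both properties are tested.

## Automatic delineation

Per axial slice of the rebinned CT, the outer bone contour is the zero
level set of φ evolved under a two-phase region energy (piecewise-constant
Chan–Vese) with a distance-regularisation term:

E(φ) = μ_reg ∫ ½(|∇φ|−1)² + μ_len L_ε(φ)
     + λ_in ∫ H_ε(φ)(I−c_in)² + λ_out ∫ (1−H_ε(φ))(I−c_out)²

H_ε and δ_ε are the arctan-smoothed Heaviside/Dirac pair of width ε; the
inside region is {φ > 0}; c_in/c_out are the H_ε-weighted region means,
recomputed every iteration. φ is initialised as the signed Euclidean
distance to the boundary of the loose region c₁ (positive inside); the
regularisation term keeps φ close to a signed distance function during
evolution, which stabilises the contour across weak boundaries.

Numerical scheme and defaults:

- Intensities are normalised to [0, 1] over the working window before
  evolution, making the weights scale-free and the result invariant to
  affine intensity changes of the slice (tested).
- The data+length force is rescaled to unit maximum per iteration, so the
  step `dt` is contour travel in pixels per iteration. Without this
  normalisation the descent speed depends on the squared intensity
  contrast, and no single raw step size converges within the fixed
  iteration budget on both high-contrast (solid disk) and shell-type
  (cortical ring) slices; with it, both converge well inside 30 iterations.
- Defaults: 30 iterations (fixed, no convergence test; an optional
  early-stop on mean |Δφ| exists but is off), dt = 1.0 px/iter,
  μ_reg = 0.2 (μ_reg·dt ≤ 0.25 for stability of the explicit scheme),
  μ_len = 0.1, λ_in = λ_out = 1, ε = 1.5 px. These are package choices,
  exposed in `ContourParams`.
- Degenerate slices (constant intensity) cannot evolve: the initial region
  is returned with a warning. If the converged inside region is darker
  than the outside — a polarity flip possible only on unusual
  initialisations — the complement is returned with a warning.

Evolution is strictly 2D per axial slice (the 5 mm native slice thickness
argues against 3D evolution); `find_outer_bone` crops each slice to the c₁
bounding box (3 px pad), evolves, and intersects results with c₁ so voxels
outside the loose region are never included. A slice contributes to c₂
only if its converged region contrast |c_in − c_out| (in original
intensity units) reaches `min_contrast` (default 50 HU, roughly the
soft-tissue/bone separation): slices inside the loose 3D box that contain
no bone — intervertebral gaps, axial margins — would otherwise contribute
noise-driven regions. All per-slice diagnostics (iterations, region means,
contrast, inclusion) are reported; slices whose c₃ area is an outlier can
be reviewed from that table, but no automatic editing is performed.

The intraosseous region c₃ is the per-slice binary erosion of c₂ by a
cross-shaped structuring element of radius k ∈ {1, 2, 3} pixels (k steps
vertically and horizontally; a square element is available). Erosion is
performed on the rebinned 4 mm grid. Nesting c₃(3) ⊆ c₃(2) ⊆ c₃(1) ⊆ c₂ ⊆
c₁ holds by construction and is tested, as is agreement with a brute-force
erosion oracle.

## Manual VOIs and evaluation

Manual RM VOIs are z-axis cylinders (default 1.9 cm diameter, 2 cm height —
five slices on the 4 mm grid) rasterised by voxel-centre inclusion. The
centre-inclusion rule makes the voxelised volume of a default cylinder
depend on placement relative to the grid (−10 % to +19 % around the
continuous 5.67 mL; the nominal "30 mL for five cylinders" often quoted for
such VOIs is a rounded continuous value, not a voxel count). For phantom
workflows the cylinders stand in for the radiologist: they are auto-placed
at ground-truth vertebral-body centroids with the axial centre snapped to
the nearest PET slice centre, since circular ROIs are drawn on displayed
slices. Overlap uses DSC = 2|A∩M|/(|A|+|M|) by voxel counts; both the
union-of-segments DSC (default) and per-segment DSCs are computed, since
either convention is defensible.

## Dosimetry

- Cumulated activity concentration: trapezoidal rule over the samples,
  plus a physical-decay tail C(t_last)/λ, plus a lead-in for the
  unmeasured [0, t₁]: constant back-extrapolation of C(t₁) by default
  (for t₁ = 1 h and ⁸⁹Zr kinetics this is < 1 % of the integral);
  linear-from-zero and exclusion are selectable.
- PET values are taken as true concentrations at scan time; inter-scan
  decay is in the measured curve, and only the post-last-scan tail assumes
  physical decay (⁸⁹Zr T½ = 78.41 h, λ = ln2/T½; the maximum possible
  residence time is T½/ln2 ≈ 113.12 h).
- Residence time τ = Ã/A₀ in hours; for RM the concentration integral is
  scaled by the *reference* RM volume from the S-value table, and
  concentration is integrated before volume scaling (equivalent for a
  fixed volume). Weight scaling uses τ × (reference weight / patient
  weight), the conventional correction; it is isolated in one function so
  the convention can be swapped.
- Remainder of body: τ_RB = T½/ln2 − Στ_organs, raising an error naming
  the excess if the organ residence times exceed the physical maximum.
- Dose: self = S(RM←RM)·τ_RM; total = Σ S(RM←src)·τ_src + S(RM←RB)·τ_RB,
  in mGy/MBq. S values and reference anatomy (RM volume, body weight) are
  user configuration; a template ships with placeholder unit entries and no
  published S values are bundled.
- Plasma method: RM TAC = 0.19 × plasma TAC (fixed red-marrow-to-plasma
  concentration ratio), provided as a comparator.
- Effective half-life: least squares on ln C(t) over all samples; a
  non-decreasing curve returns infinity with a warning (no measurable
  clearance) rather than an error.

Units are carried in names throughout (Bq/mL, MBq, h, mGy/MBq); the
Bq↔MBq conversion is centralised.

## Synthetic phantom

The generator emulates the acquisition: five vertebral bodies as cylinders
(radius 24 mm, height 30 mm, 10 mm gaps, 4 mm lateral cortical shell) at
40/120/400 HU (soft tissue / trabecular interior / cortical bone) on the
native CT grid with seeded additive Gaussian noise (default 20 HU), and a
PET series on the 4 mm grid where marrow clears mono-exponentially
(C(t) = C₀·2^(−t/T_eff), default C₀ = 5000 Bq/mL, T_eff = 73 h < 78.41 h),
background carries 5 % of the marrow uptake, and reconstruction resolution
is emulated by a Gaussian PSF (default 7 mm FWHM) before multiplicative
noise (default 5 %). Same seed ⇒ bit-identical output.

Design notes:

- Cylinders, not anatomical meshes: every operator under test is
  geometry-agnostic, and analytic shapes give closed-form volume and
  boundary oracles.
- The cortical shell is a lateral ring without endplates, matching the
  strictly in-plane contour and erosion; the intraosseous truth therefore
  spans the full body height.
- Axial placement (23 mm margin, 40 mm pitch) puts vertebra slab
  boundaries where neither the 5 mm CT sampling nor the 4 mm PET sampling
  straddles them ambiguously: every PET slice is then either clearly
  vertebra or clearly background after rebinning, so the ground truth is
  well defined on both grids. Without such alignment the truth itself is
  ambiguous on partial-volume slices and pipeline scores measure the
  rasterisation convention rather than the method.
- Both grids rasterise the same analytic geometry by voxel-centre
  inclusion; the PET-grid truth is computed directly, not resampled.

What the phantom does not emulate: beam hardening, PET scatter and
randoms, patient motion, marrow heterogeneity (red vs yellow marrow), and
anatomical shape variation. Passing phantom tests therefore demonstrates
the correctness of the pipeline's operators and their composition under
controlled contrast and kinetics — not clinical segmentation accuracy on
real anatomy, where cortical boundaries are weaker and manual review of
flagged slices remains appropriate.

## Problem sizes and determinism

Default phantom grids are 83 × 83 × 48 (CT) and 24 × 24 × 59 (PET); a full
delineation of the five-vertebra stack takes well under a second, and the
complete validation script a few seconds. All randomness flows from
explicit seeds (`PhantomSpec.seed`, the CLI `--seed`, the acceptance
script's `--seed`); noise generators derive their streams from that single
value.

## Known limitations

- The contour assumes bone is brighter than its surroundings within the
  loose region; polarity flips are handled but contrast inversions (e.g.
  contrast agents) are untested.
- The 50 HU slice-contrast gate is appropriate for bone-vs-soft-tissue CT;
  other applications may need to lower it.
- Erosion kernels are defined on the 4 mm rebinned grid. Whether an
  equivalent clinical workflow erodes on the native in-plane grid instead
  is configuration (`element`, kernel radius), not something the package
  decides.
- The weight-scaling formula and the plasma factor are conventions,
  deliberately isolated and overridable.
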