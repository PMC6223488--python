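# Methods

This note documents the models and procedures implemented in `atlasseg`,
the assumptions behind them, the parameters that matter, and the numerical
choices made where the underlying algorithm family leaves the details
open.

## Coordinate model

Volumes are axis-aligned regular grids: index `(i, j, k)` maps to world
millimetres as `origin + index * spacing`, with `i→x` (right–left),
`j→y` (anterior–posterior), `k→z` (inferior–superior). Direction cosines,
oblique acquisitions and 4-D series are out of scope. All warps are
backward maps (output-driven resampling): a displacement field stores, at
each test-grid voxel, the world offset added to that voxel's position to
find the source sampling location. Backward mapping cannot leave holes in
the output. Masks are warped by trilinear interpolation of the {0,1}
indicator followed by a 0.5 threshold (ties → foreground), which gives
smoother boundaries than nearest-neighbour warping; nearest remains
available. Rigid-plus-deformable warps are composed analytically and
applied in a *single* resampling pass — two sequential interpolations
visibly erode structures only a couple of voxels across (cochleae).

## Projection-based rigid registration

The rigid step operates on 2-D mean-intensity projections: sagittal
(collapse x) and coronal (collapse y). A mean projection commutes exactly
with in-plane rotation about the collapsed axis, so the sagittal pair
determines `(t_y, t_z, θ_x)` and the coronal pair `(t_x, t_z, θ_y)`.
Neither projection observes rotation about z; it is fixed at zero, a
stated limitation of the two-projection design (the deformable step
absorbs small θ_z).

Numerics:

* Similarity is normalized cross-correlation evaluated on a fixed
  interior region of the projection (a 20 mm boundary band is excluded,
  `RigidConfig.eval_margin_mm`). Full-frame NCC is biased by content
  rotating/translating through the image border; restricting instead to
  the moving-fixed *overlap* creates a degenerate optimum in which
  shrinking the overlap raises the score. A fixed evaluation region has
  neither failure mode for motions smaller than the margin.
* Search: per candidate angle (1° steps over ±10°), the translation is
  proposed by FFT cross-correlation, then the best `(θ, t_u, t_v)` is
  polished by Nelder–Mead on the continuous NCC.
* A rotation about x deforms the *coronal* projection and vice versa, so
  the two planes are estimated alternately, resampling the moving volume
  with the current 3-D estimate before each pass (3 sweeps,
  `RigidConfig.sweeps`).
* If the final transform does not improve the 3-D NCC over identity, the
  identity is returned.

On the default test phantom, transforms within ±10 mm / ±5° are recovered
to ≈0.5 mm and ≈0.4° (the test suite asserts 1 mm / 0.5°).

## Dual-force Demons registration

The force at each voxel combines a passive term (gradient of the fixed
image) and an active term (gradient of the warped moving image):

    u = d·∇f/(|∇f|² + α²d²) + d·∇m/(|∇m|² + α²d²),   d = m − f,

with central-difference gradients in HU/mm and the force in mm; where a
denominator falls below 1e-9 the contribution is zero. The loop is
coarse-to-fine (default 3 levels, ×2 downsampling), iterating warp →
force → update → Gaussian regularization, stopping at 50 iterations per
level or when the relative change of the mean squared intensity
difference stays below 1e-4 for 3 consecutive iterations. The returned
field composes the rigid initialization, so it maps test-grid voxels all
the way into the original atlas frame.

Parameters (`DemonsConfig`): `levels=3`, `iterations=50` per level,
regularization `sigma_mm=2.0`, force normalization `alpha=1.0`, intensity
clamp `[−1000, 1500]` HU, `tolerance=1e-4`.

Numerical choices that the dual-force formulation leaves open, each of
which was isolated with controlled experiments (zero-deformation and
pure-translation registrations, where the correct field is known):

* **Update sign.** Under the backward-field convention
  (`warped(x) = moving(x + field(x))`), the stated force points *away*
  from convergence if added: on a 1-D ramp with slope 1 HU/mm and d = 2,
  the formula yields +0.8 mm while the correcting displacement is −2 mm.
  The update is therefore `field ← smooth(field − step·u)`; with this
  sign the mean squared difference decreases, as required.
* **Step damping (`step_factor=0.5`).** Each force term is approximately
  the first-order displacement estimate d/|∇|, so their sum is ≈twice the
  correction; an undamped update overshoots and rings indefinitely at
  crisp boundaries (bone, skin). Halving the step removes the
  oscillation.
* **Image pre-blur (`presmooth_vox=1.0`).** The moving image reaches the
  force evaluation through trilinear resampling and is therefore blurred
  relative to the fixed image; near every sharp edge this mismatch in
  edge profile produces persistent opposite-signed intensity differences
  that drive spurious boundary deformation (≈2 mm in the zero-deformation
  control). Blurring both images by one voxel equalizes the profiles and
  simultaneously suppresses noise-chasing drift.
* **Moving-domain masking.** Where the (rigidly initialized) moving image
  has no data — an atlas case with a shorter scan — the mismatch is
  unfixable; forces are zeroed there, and those voxels are excluded from
  the convergence statistic. The field in such regions is the smooth
  continuation of its surroundings.
* **Per-level regularization floor.** The regularization sigma is applied
  in the level's voxel units with a floor of half a voxel; at coarse
  levels a fixed 2 mm sigma is a tiny fraction of a voxel and would leave
  the field effectively unregularized.
* **Divergence guard.** Iteration at a level stops (reverting to the
  best-seen field) if the mean squared difference exceeds 1.05× the
  level's best. Plain Demons iteration is not monotone when the inputs
  are already nearly aligned — the coarse levels of an initialized
  pyramid routinely are — and the guard both enforces the non-increasing
  similarity trace and protects the result.
* **Pyramid alignment.** Level grids are origin-aligned (coarse voxel i
  at fine voxel i·factor); field up/down-sampling uses exactly that
  mapping. Endpoint-aligned resizing (the default behaviour of generic
  zoom functions) stretches the field by ≈(n−1)/(n−factor) and biases
  displacements far from the origin.

## STAPLE fusion with a tissue-appearance model

Classic STAPLE estimates, by EM, a consensus probability `W_i` and
per-input sensitivity/specificity `(p_j, q_j)` (E- and M-steps as given in
the README). Implementation choices:

* EM runs only on voxels within a 10 mm dilation of the union of the
  inputs; the vast uninformative background would otherwise push every
  `q_j → 1` and swamp the prior. Voxels outside are fixed background.
* The global prior `π₀` is the mean foreground fraction of the inputs
  over that region; initialization `p_j = q_j = 0.99`; stop when no
  parameter moves by more than 1e-6, or at 100 iterations. The E-step is
  computed in log-space, and the observed-data log-likelihood
  `Σ log(a_i π_i + b_i(1−π_i))` is recorded each iteration (non-decreasing
  by the EM guarantee; asserted in the tests).
* **Appearance model.** The structure's intensity distribution is modelled
  as a Gaussian fitted with consensus-probability weights; the background
  Gaussian is fitted on `(1 − consensus)` restricted to the dilation band
  around the consensus support, so it describes the *surrounding* tissue,
  not the whole scan. The voxel prior becomes
  `π_i = (1−λ)π₀ + λ·P(fg | intensity_i)` with `λ = 0.5` by default;
  `λ = 0` recovers classic STAPLE exactly. SDs are floored at 1 HU so the
  densities stay proper on constant images.
* The fused mask thresholds `W` at 0.5 (ties → foreground). The
  standalone `staple_fuse` default keeps the largest connected component;
  the *pipeline* overrides this with a relative-size filter (keep every
  component ≥ 25% of the largest) because half of the default structure
  set consists of paired organs whose second side a largest-component
  rule would delete.
* Atlas cases lacking a structure are excluded from that structure's
  fusion rather than treated as empty ratings, which would bias the
  specificity estimates; fewer than two available inputs marks the
  structure absent.

## Contour metrics

Surfaces are discretized as centres of foreground voxels with at least
one of six face-neighbours outside the mask (the image border counts as
outside); distances are point-to-point Euclidean in mm. MSD is the
symmetrized mean nearest-neighbour distance; HD is reported both directed
(reference→auto, following the clinical convention of measuring how far
the physician's contour strays from the automatic one) and symmetric.
Percentile Hausdorff variants are intentionally not provided. Dice on two
empty masks is an error, not perfect agreement — an absent structure is a
data condition. The "modified" analysis zeroes the reference outside the
inclusive axial slice range of the autocontour and applies by default to
lungs and spinal cord, the two structures that reach the inferior scan
boundary.

## Rating analysis

Ratings are a three-level ordinal scale encoded 0/1/2 (no / minor / major
edits) for means. Agreement categories partition the 3×3 pair space as
3 (identical) / 2 (different but both ≤ minor) / 4 (exactly one major).
Identical major–major pairs are Category I: identity takes precedence
over the "both required major edits" reading, which is the one genuinely
ambiguous corner of the category definitions; the choice is asserted
explicitly in the tests. Percentages are serialized exactly and rounded
to integers only for display.

## The synthetic phantom

`make_phantom` builds a schematic head-and-neck CT: geometric primitives
(ellipsoids, z-tubes, a horseshoe arc) for the eight contoured
structures, plus intensity-only bony context — skull shell, temporal
bone, a vertebral canal annulus around the cord and brainstem — that
supplies the strong gradients which, in real CT, delimit the low-contrast
organs. Intensities are Hounsfield-like class means (air −1000, soft
tissue 60, bone 700–800, lungs −700, parotid −40, brain 30, cord 45)
modulated by a smooth multiplicative bias field (±2%) plus Gaussian noise
(SD 20 HU). Structure masks are painted in a fixed priority order so they
are disjoint by construction. Primitives scale with the field of view, so
the 48×48×32 @ 4 mm test grid holds the same anatomy as the full
96×96×64 @ 2 mm grid.

Atlas cohorts (`make_atlas_cohort`, default n = 12) derive each case from
the base phantom by a random rigid motion (per-axis uniform within ±5°
about x and y, ±10 mm; θ_z = 0 so the cohort stays within what the
projection rigid step can recover), a Gaussian-smoothed random
displacement field rescaled to a 6 mm maximum (12 mm smoothness —
diffeomorphic at these settings, checked by finite-difference Jacobian),
and a random truncation of 0–8 inferior slices emulating variable scan
extent. One master seed fans out to per-case seeds through
`numpy.random.SeedSequence`; every generator is a pure function of
(spec, seed).

What the phantom does *not* emulate: real anatomical shape variation
(organs deform coherently with one smooth field rather than
independently), CT physics (beam hardening, metal and dental artifacts,
partial-volume mixtures), topology changes, or inter-observer contouring
style. Passing the phantom suite therefore demonstrates that the
algorithms are implemented correctly and behave as designed under
controlled variation — not that clinical-grade accuracy would be achieved
on patient data, which is why the validation toolkit (metrics + ratings)
exists as a first-class part of the package.

Rater simulation (`simulate_raters`) applies independent per-voxel
corruption at given sensitivity/specificity — a deliberately simple error
model matching STAPLE's own independence assumption. Rating-pair
simulation draws each pair's agreement category from given proportions
and then a pair uniformly within the category.

## Test-scale choices

The test suite and the acceptance script run on the 48×48×32 @ 4 mm
phantom with 3-case atlases; the demonstration defaults are 96×96×64
@ 2 mm with 12 cases. The reduced grid keeps the full anatomy and the
full algorithm path (multi-resolution registration included) while every
suite stage completes in seconds.

## Known limitations

* Rotation about z is not recovered by the rigid step (by design of the
  two-projection approach).
* The Demons step assumes consistent intensity scales between test and
  atlas images (no histogram matching); the phantom satisfies this.
* STAPLE performance parameters are global per input, not spatially
  varying; fusion is single-label per structure.
* Structures truncated in most atlas cases (lungs, inferior spinal cord)
  are reproduced only over the extent the atlas supports — quantified,
  deliberately, by the modified-structure metrics rather than hidden.
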