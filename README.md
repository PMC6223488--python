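# atlasseg

Multi-atlas automated contouring of head-and-neck organs at risk, with the
quantitative toolkit used to validate such systems: projection-based rigid
registration, dual-force Demons deformable registration, contour
propagation through deformation vector fields, STAPLE label fusion with a
tissue-appearance model, contour-quality metrics (DSC, MSD, HD, including
the slice-restricted "modified structure" analysis), and inter-physician
rating-agreement analysis.

## Who this is for

Delineating normal structures (organs at risk, OARs) on a radiotherapy
simulation CT is slow and inter-observer variable; automating it matters
most where trained staff are scarce. `atlasseg` implements the classic
multi-atlas pipeline for eight head-and-neck OARs — brain, brainstem,
cochleae, eyes, lungs, mandible, parotid glands, spinal cord — together
with a seeded synthetic phantom generator so that every stage can be
exercised, validated and reproduced without clinical data.

## The algorithm

For a test image *T* and an atlas of contoured cases *(Aⱼ, Sⱼ)*:

1. **Rigid registration** of each atlas CT to *T* using its 2-D sagittal
   and coronal mean-intensity projections. Sagittal projections determine
   (t_y, t_z, θ_x), coronal projections (t_x, t_z, θ_y); the two planes are
   estimated alternately with a normalized-cross-correlation criterion.
   θ_z is unobservable from these projections and fixed at 0.
2. **Dual-force Demons registration**: iterated force updates

       u = d·∇f / (|∇f|² + α²d²) + d·∇m / (|∇m|² + α²d²),   d = m − f,

   using the gradients of both the fixed image *f* and the warped moving
   image *m*, with Gaussian regularization of the displacement field after
   every update, run coarse-to-fine over an image pyramid.
3. **Contour propagation and fusion**: each Sⱼ is resampled onto the test
   grid through its case's deformation vector field, and the propagated
   contours are combined with STAPLE — an EM estimator of the consensus
   segmentation and of each input's sensitivity pⱼ and specificity qⱼ:

       W_i = a_i π_i / (a_i π_i + b_i (1−π_i)),
       a_i = Π_j p_j^{D_ij}(1−p_j)^{1−D_ij},  b_i = Π_j (1−q_j)^{D_ij} q_j^{1−D_ij}

   where the voxel prior π_i blends a global prior with a two-Gaussian
   tissue-appearance posterior fitted to the propagated consensus.

Contours are compared with references using the Dice similarity
coefficient 2|A∩B|/(|A|+|B|), the symmetric mean surface distance, and the
Hausdorff distance (directed reference→auto and symmetric). For tubular
structures whose extent depends on how far the scan reaches (lungs, spinal
cord), "modified" metrics first truncate the reference to the axial slice
range of the autocontour, isolating true contouring error from
scan-extent mismatch.

Ordinal physician ratings (no / minor / major edits needed) are compared
pairwise: Category I = identical ratings, Category II = different but both
no-worse-than-minor, Category III = disagreement on acceptability.

## Worked example

Contour a synthetic test phantom from its own deformed 3-case atlas and
score the result against the phantom's ground truth:

```python
from atlasseg.phantom import PhantomSpec, make_phantom, make_atlas_cohort
from atlasseg.pipeline import PipelineConfig, run_autocontour
from atlasseg.metrics import compare_structures, metrics_table

spec = PhantomSpec(shape=(48, 48, 32), spacing=(4, 4, 4))
image, truth = make_phantom(spec, seed=11)
atlas = make_atlas_cohort(image, truth, n=3, seed=12)
contours, record = run_autocontour(image, atlas, PipelineConfig())

table = metrics_table(compare_structures(contours, truth))
print(table[["structure", "dsc", "msd_mm", "hd_mm", "modified_msd_mm"]]
      .round(3).to_string(index=False))
```

prints

```
     structure   dsc  msd_mm  hd_mm  modified_msd_mm
         brain 0.980   0.513  4.000              NaN
     brainstem 1.000   0.000  0.000              NaN
      cochleae 0.933   0.411  4.000              NaN
          eyes 0.989   0.061  4.000              NaN
         lungs 0.523   4.999 14.967            0.243
      mandible 0.988   0.074  4.000              NaN
parotid_glands 0.981   0.155  4.000              NaN
   spinal_cord 0.567   3.040 20.000            1.073
```

Six of the eight structures are recovered at DSC ≥ 0.93 with sub-voxel
mean surface distance. The lungs and spinal cord look poor on the whole-
structure metrics (MSD 5.0 and 3.0 mm) only because the atlas cases have
shorter inferior scan extents than the test image — the phantom generator
reproduces this artifact deliberately. Restricting the reference to the
slices the algorithm actually contoured drops their MSD more than
ten-fold, to 0.24 and 1.07 mm: the contours are accurate where image data
existed to support them.

The same pipeline is available from the shell:

```bash
atlasctl phantom --out data --seed 7 --cases 12
atlasctl contour data/test/image.nii --atlas data/atlas --out auto
atlasctl validate auto data/test --out report
atlasctl ratings ratings.csv --out report
```

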