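# roit

**Region-of-interest transfer between MRI slices and histology micrographs.**

Quantitative MRI parameters (e.g. the macromolecular proton fraction, MPF)
are validated against stained tissue sections — but an in-vivo MR slice and
its matching micrograph differ in resolution by an order of magnitude and in
geometry by sectioning distortions (the cut section spreads mediolaterally
on the slide). Comparing a structure across the two images therefore
requires transferring a region of interest (ROI) drawn on one image into
the coordinates of the other, *without* deforming or resampling either
source image, so that intensity measurements stay untouched.

`roit` implements this transfer as a scriptable pipeline:

1. **Scale.** A vertical reference line is drawn on each image; their length
   ratio `s = L_target / L_source` upscales the MR frame to histology
   resolution. ROIs are scaled *as vectors* (each vertex multiplied by `s`),
   so curved outlines survive any scale factor with no "stepped" raster
   artifacts.
2. **Encode.** The scaled image and up to two rasterized ROI masks are
   packed into one three-channel composite image.
3. **Register.** A thin-plate spline (TPS) is fitted to operator-placed
   landmark pairs,

   `f(p) = a₀ + A·p + Σᵢ wᵢ U(‖p − cᵢ‖)`, `U(r) = r² log r²`,

   with the classical side conditions `Σw = 0`, `Σw·c = 0`; at smoothing
   λ = 0 it interpolates every landmark exactly. The composite is pulled
   back onto the fixed frame (intensity bilinearly, masks nearest-neighbor).
4. **Decode.** The registered mask channels are traced back into vector
   polygons — the ROIs in target coordinates. For the histology→MRI
   direction the traced polygons are vector-*down*scaled to the native MR
   frame (registration always runs at histology resolution).

Validation metrics are included: Dice overlap `2|A∩B|/(|A|+|B|)`, ROI mean
intensity, stain optical density with background correction
`OD = log₁₀(I_bg / I_roi)` on the red channel, lesion-vs-contralateral
percent change, and Pearson correlation. A synthetic-phantom module
generates MRI/histology-like pairs with exact ground-truth deformation,
ROIs and landmarks, so the whole pipeline is testable with no external
data. ImageJ `.roi`/`.zip` files and landmark-pair CSVs are read and
written for interoperability with interactive workflows.

## Worked example

```python
import numpy as np
from roit import (PhantomParams, generate_phantom_pair,
                  transform_mri_to_histology, rasterize, dice)

pair = generate_phantom_pair(PhantomParams(seed=42))
result = transform_mri_to_histology(
    pair.mri,
    [pair.gt_rois_mri["cc"], pair.gt_rois_mri["brain"]],
    pair.lines, pair.landmarks, lambda_reg=0.0,
    target_shape=pair.histology.shape,
)
print(f"scale factor: {result.scale_factor:.1f}")
for name in ("cc", "brain"):
    got = rasterize([r for r in result.transformed_rois
                     if r.label.startswith(name)][0], pair.histology.shape)
    want = rasterize(pair.gt_rois_hist[name], pair.histology.shape)
    print(f"Dice({name} transferred vs truth) = {dice(got, want):.3f}")

from roit.synthetic import measure_percent_changes
pc_mri, pc_od = measure_percent_changes(pair)
print(f"lesion vs contralateral: MRI {pc_mri:+.1f}%  histology OD {pc_od:+.1f}%")
```

prints

```
scale factor: 10.0
Dice(cc transferred vs truth) = 0.982
Dice(brain transferred vs truth) = 0.998
lesion vs contralateral: MRI -29.9%  histology OD -30.0%
```

The phantom is a 180×180 "MR" slice (elliptical brain, bright
corpus-callosum band, hypointense lesion disc) paired with a 10×-scaled,
1.15×-laterally-stretched, smoothly warped RGB "histology" render. The
transferred corpus-callosum band and brain outline overlap their
ground-truth positions with Dice ≈ 0.98–1.0, and a 30 % programmed lesion
contrast reads out as ≈ −30 % on both the MR intensity and the stain
optical density — the two modalities agree because the ROI transfer, not
the images, moved.

The same pipeline is available from the shell:

```sh
roit phantom --out ph --seed 42
roit run --direction mri2hist --source ph/mri.tif --target ph/histology.tif \
     --rois rois.zip --lines ph/lines.zip --landmarks ph/landmarks.csv --out res
roit measure --image ph/histology.tif --rois res/transformed_rois.zip \
     --mode od --background bg.roi --out stats.csv
```

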