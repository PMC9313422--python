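# Methods

## The transfer model

The package moves ROIs between two 2D frames related by (i) a large,
known-by-measurement resolution ratio and (ii) an unknown smooth tissue
deformation. These are handled by different mechanisms on purpose:

* **Resolution** is handled by exact vector scaling. The scale factor is the
  Euclidean length ratio of two operator-drawn vertical reference lines,
  one per image; ROIs cross the resolution gap as coordinate lists
  multiplied by that factor, anchored at the pixel-frame origin (the image
  raster is scaled by the same factor, so relative position is preserved).
  A single isotropic factor is used: sectioning-induced anisotropy (the
  mediolateral stretch of mounted sections) is left to the deformable step,
  mirroring how a single vertical dimension is measured in practice.
* **Deformation** is handled by a thin-plate spline fitted to paired
  landmarks, kernel `U(r) = r² log r²` with `U(0) = 0`, affine part
  included, side conditions `Σw = 0`, `Σw·c = 0`. λ = 0 (the default) gives
  exact interpolation of the landmarks; λ > 0 adds diagonal regularization
  of the kernel matrix, trading landmark fidelity for smoothness (the
  landmark residual is non-decreasing in λ). No separate affine
  pre-alignment is performed — the TPS subsumes it; anyone comparing
  numerically against interactive tools that pre-align should expect
  bit-level differences away from landmarks.

ROIs ride through registration as color channels: one 8-bit composite holds
the (min–max rescaled) source intensity in channel 1 and up to two binary
masks ({0, 255}) in channels 2–3. This channel budget is structural — a
three-channel image with one channel spent on the intensity leaves room for
exactly two ROIs per run; more ROIs are either combined into one mask
beforehand or transferred in batches.

Resampling is pull-back: the export fits the fixed→moving spline (landmark
roles swapped) and samples the moving image at the mapped output pixel
centers. Both role assignments are exact at the landmarks, so vertex
transport (forward fit) and raster transport (inverse fit) agree there by
construction; the test suite holds them to Dice ≥ 0.99 everywhere on
phantoms. Intensity channels are sampled bilinearly, mask channels
nearest-neighbor only (values stay binary; a >127 threshold after warping
is kept as a safety net but is a no-op under nearest-neighbor). Samples
falling outside the moving image read 0, i.e. background for masks.

## Coordinate and rasterization conventions

Origin at the top-left pixel corner, x rightward, y downward; pixel
`(row i, col j)` covers `[j, j+1) × [i, i+1)`, center at `(j+0.5, i+0.5)`.
Rasterization sets a pixel iff its center lies inside the polygon under the
nonzero winding rule, implemented as an exact scanline fill whose work is
proportional to the number of edge/row crossings (important for traced
outlines with thousands of vertices). Mask→polygon conversion traces the
pixel-edge ("crack") boundary of each 8-connected component, preferring the
turn that carries the trace across diagonal contacts so a component yields
one outline; interior holes are filled (donut ROIs are out of scope). The
traced polygon reproduces its mask *exactly* on re-rasterization, which is
what makes the raster→vector→vector-scale→raster route in the
histology→MRI direction safe. Components under 50 px are kept but flagged:
regions a few pixels across at MR resolution do not survive transport
reliably. Closed-polygon smoothing uses a periodic cubic spline through the
vertices, resampled approximately uniformly in arc length with the original
vertices kept among the samples; the vertex count is a user parameter since
no single value is canonical.

## File formats

ImageJ `.roi` single files and `.zip` containers are read (polygon,
freehand, traced, polyline, freeline, rectangle, oval — discretized to
72 vertices — and straight line; point/multipoint and composite subtypes
raise a named unsupported error) and written (polygon/polyline/line, always
with sub-pixel float coordinates, version 228). Since coordinates are
stored as 32-bit floats in that format, round trips are exact for
float32-representable values and ~1e-4-accurate otherwise. Landmarks use
the headerless CSV dialect `name, active, moving_x, moving_y, fixed_x,
fixed_y`; inactive rows are preserved but excluded from fitting. A plain
`x,y` CSV is supported as a vector-ROI escape hatch.

## Optical density

`OD = log₁₀(mean_red(background) / mean_red(roi))` on the red channel of
the RGB micrograph, with the background region placed on blank glass. The
ratio form cancels global exposure scaling, which is the point of
background correction when all slides are photographed with the same
settings. Because the literature also quantifies stain as
background-subtracted inverted intensity, a `mean_inverted` mode is
available behind a flag; every result records which mode produced it. An
OD ≤ 0 (background darker than ROI) is allowed but warned about.

## The phantom generator

`generate_phantom_pair` emulates a coronal rodent-brain slice pair:

| parameter | default | meaning |
|---|---|---|
| `mri_shape` | 180×180 | MR frame, 0.2 mm/px nominal |
| `scale` | 10 | histology / MRI resolution ratio |
| `lateral_stretch` | 1.15 | mediolateral spread of the mounted section (brain width:height ≈ 1.85 on the MR side, ≈ 2.1 on the histology side) |
| `warp_amplitude_px` | 15 (histology px) | s.d. of control-point displacements of the ground-truth warp |
| `warp_grid` | 5×5 | ground-truth warp control grid |
| `noise_sd` | 2 (8-bit units) | additive Gaussian noise, both images |
| `lesion_contrast` | 0.3 | fractional signal/stain loss in the lesion |

Anatomy: elliptical brain (ratio 1.875), a C-shaped bright band above
bilateral "caudoputamen" discs, a hypointense lesion disc on one side with
a mirrored contralateral measurement circle. The histology render is
transmitted-light-like: channel intensity `235·10^(−k·OD)` with k = 1.0 /
0.7 / 0.25 for R/G/B, so the programmed lesion contrast appears as the same
*relative* drop in red-channel OD as in MR intensity — which is what makes
the cross-modality percent-change comparison meaningful.

The ground-truth deformation is itself a TPS on the jittered control grid —
deliberately in-family with the registration, so that with exact landmarks
recovery is near-perfect and any degradation in an experiment is
attributable to landmark count, placement jitter, or an out-of-family warp
(`warp_family="bspline"`, a bicubic displacement field, exists for that
stress test). Ground-truth histology ROIs are the exact vertex images of
the scaled MRI ROIs under this map, and all 30 landmark sites (18 brain
outline, 8 band midline, 4 interior) satisfy it exactly; `landmark_subsample`
draws k of them with optional Gaussian jitter emulating operator
imprecision. The histology raster is rendered through an approximate
inverse (a TPS fitted to reversed correspondences on a 9×9 grid); this
touches only pixel appearance, never the ground-truth geometry, and the
measurement circles sit ≥3 MR px inside their rendered regions so the
rendering approximation cannot leak into intensity statistics. All
randomness comes from one seeded generator; a pair is bit-reproducible
from its seed.

What the phantom does *not* emulate: tears, folds and missing tissue of
real sections, staining gradients, partial-volume effects at the MR scale,
and anatomy more complex than smooth convex-ish regions. Passing phantom
tests therefore demonstrates the correctness of the transfer machinery
under smooth deformations with well-identified landmarks — not robustness
to damaged sections or to operator disagreement about anatomy, which only
real data can probe.

## Problem sizes and numerical choices

Validation experiments run at the reference conditions above (histology
frames around 1800×2070). The channel-vs-vertex equivalence and round-trip
suites run 10–20 phantom repetitions; pipeline geometry experiments skip
the histology render (`render_histology=False`), which is bit-neutral for
every geometric quantity because the render consumes the random stream
last. Degenerate inputs are handled explicitly: zero-area polygons
rasterize to an empty mask with a warning; a constant intensity channel
rescales to zeros; an ROI whose warped mask is empty raises "ROI lost in
transformation" rather than silently vanishing; both-empty masks get
Dice 1.0 with a warning (agreement on emptiness, flagged to stay
auditable). Landmark sets are validated for count (≥3 active), duplicates
and collinearity before solving; more than 30 active landmarks warns but
proceeds.

## Known limitations

* Single 2D slice pairs only; slice selection/extraction from a 3D volume
  and oblique re-slicing happen upstream.
* Two ROIs per composite run (structural channel budget).
* Donut/composite ROIs and point-list ImageJ subtypes are unsupported.
* The TPS is fitted globally; very large landmark counts with conflicting
  local displacements can make the λ = 0 system ill-conditioned — use a
  small λ.
* The exact background-correction formula used alongside historical stain
  quantifications varies between labs; both supported OD modes are labeled
  and neither is claimed canonical.
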