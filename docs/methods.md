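# Methods

This note records the models, parameter choices and numerical conventions
behind `neseg`, and what its synthetic tests do and do not demonstrate.

## Image model and assumptions

The pipeline assumes 8-bit greyscale SBF-SEM stacks of one cropped cell per
volume, in `(row, col, slice)` order with voxel size (10, 10, 50) nm unless
stated otherwise. Three contrast assumptions are load-bearing: the nuclear
envelope is darker than nucleoplasm and cytoplasm; the resin background is
brighter than any cellular structure; and the cell of interest is centred
in the crop. Higher-bit-depth inputs are min–max rescaled to 8 bit on
load, because all intensity-derived thresholds operate on that scale.

## Alignment

Inter-slice displacement artefacts are detected by integer-precision
cross-correlation (`skimage.registration.phase_cross_correlation` with
`normalization=None`). Plain cross-correlation is used instead of whitened
phase correlation because the latter is dominated by noise on weakly
textured slices (bare resin at the ends of a crop). A consecutive-slice
shift counts as a discontinuity when its magnitude reaches 5 px (smaller
drifts are ordinary acquisition jitter) *and* undoing it raises the
inter-slice Pearson correlation by more than 0.1 — without that second
check, noise-driven correlation peaks on near-featureless slices produce
spurious records. Correction translates every slice from the discontinuity
onward; vacated border pixels are filled with the slice's 95th-percentile
intensity, an estimate of the resin level. The fill intensity matters: a
fill matching an interior grey class (e.g. the per-slice median, which in
organelle-rich slices lands on cytoplasm or nucleoplasm grey) can abut the
nucleoplasm through the cut envelope with no intervening edge and destroy
the slice's segmentation. Only pure translations are corrected; rotation
and non-rigid motion are out of scope.

## Per-slice segmentation

Stages and defaults:

| parameter | default | role |
|---|---|---|
| `gauss_size`, `gauss_sigma` | 7 px, 2.0 | low-pass kernel (replicated borders) |
| `canny_sigma` | 1.0 | Canny smoothing |
| `canny_low`, `canny_high` | auto | hysteresis thresholds |
| `dilate_radius` | 5 px | edge dilation disk (≈ NE width at 10 nm/px) |
| `min_region_fraction` | 0.001 | drop superpixels below 0.1% of slice area |
| `close_radius` | 5 px | closing of candidate outlines |
| `grow_radius` | 1.5 × dilate | expansion back toward the detected edge |

Canny thresholds default to an Otsu split of the Sobel gradient magnitude of
the σ-smoothed slice (the same gradient the detector thresholds
internally), with the low threshold at 0.4 × high. This adapts to
per-slice contrast; both thresholds can be fixed in configuration.

Structuring elements are disks, treating membrane orientation isotropically.
Superpixels are the 8-connected components of the dilated-edge complement;
their size is deliberately unrestricted so background and nucleoplasm stay
single components.

Two cleanup details deserve emphasis. First, hole-filling treats each
surviving superpixel independently, but a filled annulus must never claim
the pixels of a *different* surviving region inside its hole — original
superpixel pixels always stay with their own region. Without this rule a
ring-shaped cytoplasm component would swallow the nucleus. Second, because
dilating the edge map by radius r shaves an r-wide margin off every
enclosed region, and the Canny edge itself sits at the inner face of the
membrane, candidates are finally grown back by 1.5 × r using
`skimage.segmentation.expand_labels` (a distance-transform operation that
cannot make regions overlap). The factor 1.5 follows from sizing the
dilation to the membrane width: r restores the erosion, r/2 moves the
boundary from the membrane's inner face to its midline, where manual
annotation traces it.

## Volume propagation

Segmentation is seeded on the central slice (default ⌊n_d/2⌋), which is
assumed to hold a single, centrally positioned nuclear region — the largest
candidate wins, ties broken by centroid distance to the image centre. The
sweep proceeds outward in both directions; on each slice the union of all
candidates overlapping the nearest accepted slice toward the centre is
accepted. Two robustness parameters extend the plain overlap rule:

* `min_overlap_fraction` (default 0.5): a candidate must share at least
  this fraction of its own area with the reference footprint. Sweeping
  outward, a genuine nuclear cross-section lies almost entirely inside its
  inward neighbour, so true regions (including disjoint islands) pass
  easily; cytoplasm fragments that merely brush the footprint's rim — or
  hole-filled annuli that contain it — are rejected. Setting 0 recovers
  the strict any-overlap rule.
* `max_gap` (default 3): up to this many consecutive candidate-free slices
  are tolerated before propagation stops in a direction, so one failed
  slice does not truncate the nucleus.

The envelope is the per-slice inner boundary (mask minus its erosion by a
3 × 3 cross), matching how ground truth is delineated slice by slice; a
full 3D boundary would additionally paint the top and bottom caps.

## Evaluation metrics

JI = TP/(TP+FP+FN) and the symmetric Hausdorff distance are computed per
slice; HD acts on envelope boundary pixel centres with the Euclidean metric
in-plane, and "mean HD" is the mean over slices of the per-slice value (not
the modified/average Hausdorff distance). Slices where both masks are
empty carry no information and are excluded from means; a slice where
exactly one mask is empty scores JI = 0 and contributes no HD. Two empty
masks make JI undefined and raise rather than returning 0 or 1. Slice
ranges are inclusive on both ends.

## Spheroid model and surface map

The model surface is a sphere in physical coordinates with the same volume
as the nucleus, centred at the nucleus centroid; with 10 × 10 × 50 nm voxels
it rasterises to a 5:1 flattened ellipsoid in index space. Ray casting
uses an equirectangular longitude–latitude grid (default 360 × 180,
cell-centred), steps of half an in-plane pixel along each ray, and takes
the *outermost* mask crossing (midpoint-corrected by half a step), so
invaginations appear as negative map values instead of being skipped. Rays
that never meet the mask are NaN-flagged, never silently zero. Map values
are reported in in-plane pixel units; μ, σ (population), range and the
μ ± σ pixel ratios are computed on the raw grid without spherical area
weighting. The bundled seven-cell reference table
(`neseg.datasets.load_hela_cohort`) uses the same conventions; its
printed-precision columns reproduce the published JI–σ, JI–range and JI–μ
correlations to within a few 10⁻³.

## Synthetic phantoms

The generator renders, in physical coordinates: a radially perturbed sphere
(nucleus) whose smooth angular deformation field is scaled by
`deform_amplitude`; a dark NE shell of `envelope_thickness` (default 5 px)
straddling the true boundary; a cytoplasm partitioned into ~160 nm
compartments by ~5 px dark membranes (Voronoi foam — the essential realism
is that real EM cytoplasm is membrane-partitioned, so no open cytoplasm
region can encircle the nucleus); bright homogeneous resin; border-touching
fragments of neighbouring cells; Gaussian noise (σ = 6); and optionally a
rigid shift from a given slice onward, applied to image and ground truth
alike. An optional polar groove (`notch_depth`, `notch_width`) splits
near-pole cross-sections into disjoint islands. The default 256 × 256 × 60
phantom is a scaled-down cell (nucleus radius 1 µm rather than ~5 µm) so
the full pipeline runs in seconds; all geometry respects the 10:50 voxel
anisotropy. Cohorts share one deformation field shape and scale it along
a strictly increasing amplitude ladder, isolating the amplitude effect for
monotonicity and correlation studies.

What the phantoms do **not** emulate: SEM-specific noise (charging,
curtaining), nucleoli and chromatin clutter dark enough to trigger the edge
detector inside the nucleus, neighbouring whole cells, and staining
gradients across the volume. Passing phantom tests therefore demonstrates
the pipeline's geometric and topological correctness under the stated
contrast assumptions, not its accuracy on any particular acquisition.

## Numerical conventions and degenerate inputs

Coordinates are `(row, col, slice)`, 0-based, row increasing downward.
Slice files sort by the numeric content of their filenames; multipage TIFFs
keep page order. Masks are stored as 8-bit {0, 255} TIFF. Constant
images make translation detection degenerate (raised as an error); an empty
candidate list on the central slice is fatal (no nucleus); zero-variance
columns make correlations undefined (raised, not NaN-silenced). All
phantom randomness flows from one seeded generator, and identical seeds
give bitwise-identical volumes.

## Known limitations

* One nucleus per cropped volume; no multi-cell instance segmentation.
* Alignment corrects translations only.
* The central slice must contain a single nuclear region; a cell whose
  nucleus is split at mid-height would need a manually chosen seed slice.
* Surface statistics are unweighted on the angular grid; high latitudes are
  over-represented relative to their solid angle.
* The NE is extracted as a 1 px inner boundary; envelope thickness is not
  estimated.
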