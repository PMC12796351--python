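# Methods

## Imaging model and what the simulator emulates

The analysis targets 2-D super-resolution (STED-like) images with pixels of
20–30 nm in which the outer mitochondrial membrane (OMM) carries the
fluorophore.  Because the label sits on a surface, a tubular mitochondrion
imaged in cross-section shows two intensity ridges separated by the tubule
width; a structure narrower than the resolution limit shows a single merged
peak.  The simulator reproduces exactly this appearance:

* Objects are capsules (stadium shapes) parameterized by length `L`
  (tip-to-tip, at the membrane centre), width `W` (diameter at the membrane
  centre) and orientation.  The membrane is a ring of configurable
  thickness (default 40 nm — fluorophore plus linker on both leaflets)
  centred on `W/2`, rendered at 4× supersampling, box-averaged to the pixel
  grid and convolved with an isotropic Gaussian PSF (default σ = 25 nm,
  ≈ 59 nm FWHM).
* Fields contain a central soma disk (radius 2 µm), piecewise-linear
  neurite paths radiating outwards carrying a faint membrane-label
  background (the signal the process-length stage uses), and objects placed
  along the paths with rejection sampling.  Objects never overlap; the
  clearance margin includes the PSF skirt so that neighbouring objects
  remain separable after thresholding.  Protrusions are the one allowed
  exception: they overlap their parent tubule only.
* Mitochondrial widths are drawn from a truncated normal (mean 160 nm,
  SD 35 nm, clipped to the configured range), giving the narrow, peaked
  width distribution seen in real neurons rather than a flat one.
  Sub-threshold structures (MDS) are sampled as vesicles (`L ≈ W`,
  90–250 nm) or sticks (`L ≈ 2.6–4 × W`, `W` 80–120 nm) with analytic area
  kept below 80% of `A_th`, so planted classes are unambiguous.
* Functional channels paint each object's filled footprint with a
  per-object level drawn from the two-component model the caller assumes:
  positives `Normal(200, 25)`, negatives `Exponential(scale 20)` (counts).
  Turnover channel pairs satisfy `new/(old+new) = r` exactly before noise,
  with `r` following a linear radial gradient from the soma (default 0.8 at
  the soma, −0.005 µm⁻¹, clipped to [0.02, 0.98]).
* Noise is Poisson on the expected counts followed by additive Gaussian
  read noise (σ = 3), clipped at zero.  Photon levels (peak 150 counts,
  background 5, neurite ribbon ≈ +6) are typical STED budgets; they are
  package defaults, not measured values.  For one configuration and seed
  the output is bit-identical across runs.

What the simulator does **not** emulate: cristae substructure, 3-D blur,
object curvature/branching, labelling heterogeneity along one membrane,
bleaching, drift, or vesicle motion.  Recovery tests on these synthetic
fields therefore validate the estimators' geometry and statistics, not
their robustness to every artefact of live-cell data.

## Segmentation

Two binarization variants feed the morphometry:

* **Global**: `img > threshold`, with `threshold="auto"` using the triangle
  rule.  The triangle histogram uses approximately unit-width bins (bin
  count clipped to [17, 257]) because photon-count images quantized on a
  fine 256-bin grid leave empty bins beside the background peak, collapsing
  the threshold onto the peak itself.  A constant image raises an error.
  Note that the triangle rule needs a noise-broadened histogram; on
  noise-free synthetic renders an explicit threshold should be passed.
* **Bernsen (local)**: per pixel, min/max over a disk (default radius 9 px)
  are taken; where the local range reaches the contrast threshold (default
  15 counts) the pixel is compared with the local midgray; low-contrast
  neighbourhoods are assigned by comparing the midgray with the global
  half-range, which sends them to background on dark-background
  fluorescence (switchable).  The min/max filters use edge-replicating
  boundaries, which is mathematically identical to clipping the disk at the
  image border.  An optional Gaussian pre-smooth (off by default) is the
  usual preparation when the input is raw rather than deconvolved.

Refinement applies an ordered list of morphological steps (erode, dilate,
open, close, fill holes, remove components below n px) with a 3×3 cross
element.  The pipeline default — fill holes, erode ×2, remove <8 px —
fills the hollow membrane interiors and shrinks the PSF skirt back to the
object footprint (measured mask area within ~2% of planted footprints at
default settings).  A soma mask, when present, is subtracted after
refinement so only neurite objects remain.

## Morphometry conventions

* Connectivity is 8-connected throughout.
* Coordinates: 0-based pixel indices; centroids reported in µm with the
  origin at the top-left pixel corner (pixel centres at half-pixel
  offsets).  Angles are CCW from +x with y up (image convention),
  in [−90°, 90°); a symmetric object gets angle 0 by the atan2 tie-break.
* The moment ellipse uses `major = 4√λ₁`, `minor = 4√λ₂` of the normalized
  second central moments, then scales both axes so the ellipse area equals
  the pixel area (particle-analysis convention).  Degenerate single-line
  components keep the unscaled moment axes.
* Skeleton length sums 8-neighbour steps (1 or √2 px) over the thinned
  component, counting each step once and skipping any diagonal step whose
  two pixels share an orthogonal skeleton neighbour (no double-counted
  corners).  A component with no 2×2 solid block is already one pixel wide
  and is used as its own skeleton — thinning algorithms would clip its
  corner pixels.  A single-pixel skeleton has length 0.
* Boundary conventions: `A = A_th` is a mitochondrion (MDS is strict `<`);
  `A = 0.2 µm²` uses the large-object length rule; `AR = 0.5` is a vesicle;
  `L = 2.1 µm` uses the 350-nm anchor rule; ring intervals are half-open
  `[k·w, (k+1)·w)`; axial fractions exactly 0.25/0.75 are tips.
* The aspect ratio is `W/L` with the fitted centre width `W_m` when an
  accepted fit exists and the ellipse minor axis otherwise; the source is
  recorded per object (`ar_width_source`).
* Compartment membership (dendrite, axon, transfected cell, ...) is a
  per-object Boolean obtained by testing the object's centre position
  against the supplied binary region image (`in_<region>` columns).

## Width fitting

Profiles are sampled at 1-px steps by bilinear interpolation, averaged over
5 parallel lines spaced 1 px along the axis, on the intensity image with
background zeroed outside a 3-px dilation of the mask.  Peak detection uses
prominence ≥ 10% of the profile's dynamic range and a minimum separation of
2 samples; adjacent maxima whose connecting valley is shallower than that
prominence are merged into one peak (two near-equal maxima from an
unresolved membrane pair would otherwise both survive a plain prominence
filter, which references the signal ends for equal heights).

Fits include a constant baseline (residual background survives masking) and
are initialized from the detected peak positions and heights; the double
Gaussian uses independent sigmas by default (a shared-sigma variant is
available).  Fits are accepted when R² ≥ 0.80 (configurable, reported per
fit).  On noise-free resolvable capsules the recovered peak distance equals
the planted width to sub-nanometre bias; below the merge limit the
single-Gaussian FWHM systematically overestimates the width — it is kept
anyway, as discarding unresolved objects would bias the cohort far more.
`W_o` near the capsule caps reads slightly below `W_m` because the membrane
curves inwards there; this is geometry, not a fitting error.

## Functional calling

Per-object means over the pixel set are histogrammed with Freedman–Diaconis
bins (floor of 12), and `f(x) = a·e^(−bx) + A·e^(−(x−µ)²/2σ²)` is fitted by
least squares on the bin counts.  Initialization: `b` from the
log-linear slope of the lower-quartile bins, `µ`/`σ` from the mean and SD
of the upper half of the means.  The threshold `t*` is the numeric argmin
of the fitted `f` on `(0, µ)` over a dense grid; the crossing point of the
two components is computed alongside and reported for comparison (the two
differ slightly; the argmin is authoritative here).  When the optimizer
fails or the fitted `f` has no interior minimum, the caller falls back to
Otsu's threshold on the means and flags the model.  Thresholds are strictly
per image; calls are `mean > t*`.  At the simulated mixture (70%
exponential background, 30% Gaussian positives, n = 500) the fitted valley
lands within a few counts of the analytic mixture valley, well within half
a histogram bin.

## Spatial statistics

* **Process map**: soma-zeroing → intensity cap at the 98th-percentile
  value (squashes the bright organelle signal so the faint neurite
  background dominates the histogram; the percentile must exceed the
  organelle pixel fraction, and 98% covers typical fields where organelles
  occupy ≲2% of pixels) → triangle threshold → remove <20 px → dilate ×20 →
  erode ×15 → keep the largest component → skeletonize; branch lengths sum
  to the process length.  Number density = object count / process length.
* **Radial rings**: object distance is the Euclidean distance from the
  centroid to the nearest soma pixel (distance transform), so ring 0 starts
  at the soma edge; centroids inside the soma are excluded.  Ring
  aggregation is object-averaged (pixel-weighted averaging would weight
  large mitochondria more; the object-level view matches per-organelle
  biology), separately for mitochondria and MDSs when classes are given,
  with optional normalization to the ring-0 mean.
* **Protrusions**: the anchor is projected onto the parent's major axis;
  axial fraction in the extremity quarters ([0, 0.25] ∪ [0.75, 1]) is a
  tip.  Marker positivity compares the mean over a small disk at the anchor
  with background mean + 2 SD (k configurable); the background reference is
  measured inside the filaments but outside any labelled structure.
* **Contact sites**: a punctum contacts a mitochondrion when it overlaps
  the mask or lies within the configured gap (default 0 nm, with pixel
  adjacency — a gap below one pixel diagonal — always counting as
  touching, since a zero threshold on a discrete grid would otherwise
  exclude genuinely abutting puncta).  Linear density = contacts / total
  selected length.

## Problem sizes used by the tests and the acceptance script

Synthetic fields of 1024² px (25.6 µm side) with 30 mitochondria + 20 MDSs
for end-to-end recovery; 512² fields for noisy segmentation checks; 50
replicates per width point (120/150/200/300 nm) and 20 replicates at 80 nm
for width recovery; 20 draws of n = 500 for threshold recovery.  These
sizes give binomial/SE margins comfortably inside the asserted tolerances
while a full run stays in the minutes range on one CPU.  Ring analyses in
tests use 3–4 µm rings on these 25-µm fields; the 30-µm default matches
full-cell fields.

## Known limitations

* Widths below the merge limit (~65 nm ridge separation at the default
  PSF and membrane thickness) are reported as single-Gaussian FWHM and are
  systematically high; no deconvolution-aware correction is attempted.
* The triangle auto-threshold assumes a noise-broadened histogram; on
  noise-free synthetic images an explicit threshold must be supplied.
* Ellipse length overestimates the length of strongly curved or branched
  objects; the skeleton term compensates only above 0.2 µm².
* The exponential+Gaussian threshold model needs ≥ ~30 objects per image;
  sparser images fall back to Otsu with a flag.
* Bernsen on raw (undeconvolved, unsmoothed) input is noise-dominated;
  use the pre-smoothing option or deconvolved input.
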