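# mitomorph

Nanoscale morphometry of mitochondria and mitochondria-derived structures
(MDS) in 2-D STED-like images of neurons.

Super-resolution imaging of the outer mitochondrial membrane (OMM) resolves
neuronal mitochondria as hollow tubules 100–300 nm across and reveals a
population of much smaller membrane-bound structures — vesicles and short
tubules ("sticks") budding from mitochondria — that confocal microscopy
cannot separate from their parents.  `mitomorph` quantifies both
populations from multi-channel images: it segments the OMM channel, measures
every object, classifies it, calls its functional state from companion
channels (membrane-potential or ROS dyes, lysosome or protein markers), and
computes spatial statistics (number density along neurites, radial
pulse-chase turnover, protrusion placement, contact-site density).  A
synthetic-image generator with planted ground truth drives the test bench.

## The measurements

For each 8-connected object of the binary OMM mask:

* **Area** `A` (µm²) — pixel count × pixel area.
* **Ellipse fit** — major axis `L_ell`, minor axis `W_ell`, orientation θ
  from normalized second central moments, axes scaled to the object's area.
* **Skeleton length** `L_skel` — summed Euclidean branch steps of the
  thinned object.
* **Selected length** `L` — `L_ell` when `A < 0.2 µm²` (skeletons
  under-cover small rounded objects), else `max(L_ell, L_skel)`.
* **Width** — line profiles 0.75 µm long, 5 px wide, perpendicular to θ at
  the centre and two near-end anchors (`L/6` and `5L/6` for `L < 2.1 µm`,
  350 nm from each end otherwise).  The number of detected profile peaks
  chooses the model: one peak → single Gaussian, width = FWHM; two peaks →
  double Gaussian, width = peak distance (the two membrane ridges); 3–4
  peaks → side-by-side objects, peak spacings only; more peaks or a poor
  fit (R² below threshold) → rejected.  `W_m` is the centre width, `W_o`
  the mean end width.
* **Class** — MDS iff `A < A_th = 0.086 µm²`; MDS shape from the aspect
  ratio `AR = W/L`: vesicle for `AR ∈ [0.5, 1]`, stick below.
* **Functional calls** — per image, the histogram of per-object mean
  intensities in a companion channel is fitted with
  `f(x) = a·exp(−b·x) + A·exp(−(x−µ)²/2σ²)` (exponential background +
  Gaussian signal); the local minimum of `f` between the modes is the
  calling threshold `t*`, and an object is positive iff its mean exceeds
  `t*`.
* **Turnover** — pulse-chase refreshment `R = Σ_new / (Σ_old + Σ_new)` per
  object, aggregated over concentric rings (default 30 µm) around the soma.

## Worked example

Simulate a noise-free field with known ground truth and run every stage:

```python
from mitomorph import io, simulate

cfg = simulate.SimConfig(image_size_px=(1024, 1024), n_mitochondria=30,
                         n_mds=20, seed=7, poisson_noise=False,
                         gaussian_read_sigma=0.0, n_protrusions=12)
field = simulate.generate_field(cfg)

channels = {
    "structural": io.ChannelImage(field.structural, cfg.pixel_size_nm),
    "functional": io.ChannelImage(field.channels["functional"],
                                  cfg.pixel_size_nm),
    "old": io.ChannelImage(field.channels["old"], cfg.pixel_size_nm),
    "new": io.ChannelImage(field.channels["new"], cfg.pixel_size_nm),
    "soma": io.ChannelImage(field.soma_mask, cfg.pixel_size_nm),
}
run = io.RunConfig(global_threshold=25.0, ring_width_um=3.0)
result = io.run_pipeline(channels, run)
```

which prints, via the summary fields:

```
objects: 50  (mitochondria 30, MDS 20)
MDS/mitochondria ratio: 0.67
median mitochondrial area: 0.407 um^2
median MDS area: 0.027 um^2
width histogram mode: 155 nm
functional positive fraction: 68%  (t* = 100.8 counts)
ring 0 turnover ratio: 0.77 +/- 0.00 (n=7)
```

All 50 planted objects are recovered and classified on the correct side of
`A_th`; the median MDS area (0.027 µm²) sits in the expected sub-threshold
range, the width mode reflects the planted width distribution, the called
positive fraction tracks the planted 70% (34/50 positive in this draw), and
the proximal turnover ratio matches the planted soma value 0.8 up to the
small background dilution.

The same stages are available from the shell:

```
mitomorph simulate --out sim --seed 7 --no-noise
mitomorph all --image sim/channels.tif --soma sim/soma.tif --out results
```

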