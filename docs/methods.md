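# Methods

`endothelix` quantifies images of the corneal endothelium — the monolayer of
roughly hexagonal cells on the inner cornea whose density indicates corneal
health — along two routes: a spectral estimate of cell density, and a full
cell segmentation from which density, polymegathism and pleomorphism are
measured. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic phantoms do and do not show.

## Spectral density estimation

A quasi-periodic mosaic of bright cells separated by dark lines produces a
ring in the magnitude of its 2-D Fourier transform. The ring radius — the
characteristic frequency `f*` in cycles per pixel — is the reciprocal of the
characteristic cell width, and the mean cell area is

    A = alpha / f*^2,     delta = f*^2 / alpha   (cells per px^2),

where `alpha` is a dimensionless shape factor: 1 for a square lattice,
`2/sqrt(3) ~ 1.155` for a perfect hexagonal one, and slightly below 1 for the
irregular mosaics of a real endothelium (hexagonal packing is the densest
possible). Density in mm^-2 follows from the lateral sampling density
(0.557 um/px for the instrument the defaults target).

The 2-D spectrum is projected onto radial frequency bins `{0, 1/N, ..., 1/2}`
(N the working-frame width; non-square inputs use the largest centered square
crop so the bins stay isotropic). Each 2-D sample is assigned to the nearest
bin; per-bin means (or maxima) give the radial profiles. Peaks are local
maxima of the profile excluding the DC bin, refined by a three-point parabola
and clamped to half a bin. Seven estimators are provided; the preferred one,
`modeRMrec`, first removes the central DC peak and its slowly decaying tail by
grayscale dilation-by-reconstruction: the DC sample is the seed, the magnitude
the mask, the structuring element the origin plus its four direct neighbors.
The reconstruction is the central peak with its radially non-increasing tail;
subtracting it leaves the ring. This acts as a high-pass filter constructed
for the image at hand and has no parameter — unlike the `meanPS`/`medianPS`
estimators, which need an explicit number of low-frequency bins to discard.

Numerical choices: no windowing before the FFT (frame-edge leakage ends up in
the DC tail, which `modeRMrec` removes); parabola fits on linear profile
values; plateaus break toward the lower frequency; for even N the DC sample
sits at index N/2 of the shifted grid. `meanPS`/`medianPS` interpret the
"mean/median of the profile" distributionally: the weighted mean / weighted
median frequency with the power profile as weights, after zeroing bins
`0..n_highpass-1`.

Bin quantization bounds the accuracy: on the 350-px hexagonal lattice phantom
the continuous ring sits at 16.17 bins but the detected peak is ~16.0, so the
derived shape factor is 1.13 rather than 1.155 (about -2%). This is a
resolution limit, not an estimator defect; the square lattice, whose ring
falls exactly on bin 14, yields alpha = 1.000.

Calibration of `alpha` against ground truth uses leave-one-out: per held-out
image, `alpha` is the arithmetic mean of `f*^2 / delta_gt` over the remaining
images. The arithmetic mean was chosen as the simplest unbiased aggregate; a
regression of `delta_gt` on `f*^2` through the origin is a reasonable
alternative. Without calibration data the default is `alpha = 1`.

## Stochastic-watershed segmentation

The watershed of the inverted image would segment cells perfectly if each
cell had exactly one minimum; noise gives it many. The stochastic watershed
runs `m` seeded watersheds with random seeds and noise and accumulates the
boundary pixels into a per-pixel occurrence count map (the "PDF"), in which
persistent cell boundaries accumulate high counts and spurious ones average
out.

Per repetition: the 8-bit image is inverted and promoted to float, i.i.d.
uniform noise in `[0, u]` is added (real-valued, unclipped — clipping at 255
would bias bright ridges), and seeds are placed on a hexagonal grid with edge
length `t = sqrt(2 A_I / (3 sqrt(3) n_seeds))` — one seed per hexagon, i.e. a
triangular lattice whose point density equals the estimated cell density —
randomly rotated (uniform in angle) and translated (uniform over one cell).
`n_seeds = A_I f*^2` with the shape factor taken as 1 at this stage; the
method is deliberately insensitive to the seed count, which the robustness
tests confirm. The seeded watershed imposes the seeds as the only minima and
produces one region per seed with 0-labeled lines (4-connected regions).

Extraction: the counts are smoothed with a Gaussian of `sigma_PDF =
k_sigma / f*`, minima shallower than `h = k_h m / sigma_PDF` are suppressed
(H-minima via grayscale reconstruction by erosion on the float raster — `h`
already carries the `m` scaling, so the counts are not renormalized), and the
classical watershed partitions the result. If the suppression flattens the
whole relief the output is a single region. Defaults `u = 30`, `k_sigma =
0.17`, `k_h = 0.002`, `m = 100` are the values found optimal by leave-one-out
training on clinical confocal images; `m` trades run time against run-to-run
variance without changing the mean quality.

Because the smoothing scale is the stage most sensitive to a wrong `f*`, the
pipeline re-estimates `f*` from the PDF itself (with `modeRMrec`) before
smoothing: the PDF is a clean line drawing of the boundaries, free of
illumination gradients and texture, so its ring is more reliable than the
image's. If no ring is found in the PDF the image estimate is kept and the
event logged.

Finally, because smoothing displaces ridges, boundaries are re-aligned to the
image: every region is shrunk to the pixels where `D_c/(D_c + D_b) < 0.8`
(`D_c` the Euclidean distance to the region's center of mass — or to the
nearest region pixel when the centroid falls outside a non-convex region —
and `D_b` the distance to its boundary; a 20% shrink), and the shrunken
regions seed a watershed of the inverted image smoothed with sigma 2. Marker
components keep their region's label, so the region count is preserved; an
empty shrunken marker falls back to the full region.

Reproducibility: one master seed spawns independent per-repetition RNG
streams (noise and grid placement), so a run is bit-reproducible from its
recorded configuration while repetitions stay independent.

## Morphometry

From a label map (0 = boundary lines): cell areas are the label supports
(excluding line pixels) times the squared sampling density; density is
`10^6 / mean area in um^2`; polymegathism is the coefficient of variation of
cell area in percent (population standard deviation — a definitional choice,
fixed and documented); pleomorphism is the percentage of cells with exactly
six neighbors, where two regions are neighbors iff some boundary pixel has
both labels in its 8-neighborhood (robust to 1-px lines). Regions touching
the image border are partially imaged and excluded from the measures — the
two outermost pixel rows/columns count as the border, since a clipped cell
can be separated from the frame by its own 1-px watershed line — but they
still count as neighbors of retained cells. No stereological counting frame
is applied; the resulting small bias toward higher densities (clipped large
cells are discarded more often) is accepted because the field of view holds
few cells.

## Evaluation and training

Ground truth is one marker per complete cell inside a hand-drawn evaluation
polygon. A segmented region is correct if it contains exactly one marker and
at least 85% of its pixel area lies inside the polygon (pixel membership by
the even-odd rule on pixel centers); regions not intersecting the polygon, or
overlapping it by less than a quarter of the average area of the intersecting
regions, are ignored. Precision, recall and F follow from the correct count,
the retained count, and the marker count. Parameter training grid-searches
`(u, k_sigma, k_h)`, segmenting each image once per triple with a fixed
per-triple seed (identical images therefore score identically), seeding from
the ground-truth density `n_eval/A_eval` so the spectral estimator cannot
influence the result, and picks per held-out image the triple maximizing the
mean F of the others.

## Synthetic phantoms

Lattice phantoms are binary square or flat-top hexagonal tilings (bright
cells, 2-px dark lines, axis-aligned, corner origin) low-pass filtered with a
hard isotropic cutoff at 3x the fundamental frequency, so only the ring
neighborhood survives; their `f*` and `alpha` are known exactly.

Mosaic phantoms are Voronoi tessellations of a hexagonal point process with
Gaussian jitter; the jitter amplitude realizing a requested area CV is
interpolated from a simulation-derived calibration table (large tessellations,
analytic polygon areas). The rendered image darkens pixels within half the
boundary width of a Voronoi edge (exact point-to-bisector distances), applies
one low-frequency multiplicative cosine illumination sheet (15% default
amplitude), and adds Gaussian noise (sd 10 gray levels by default, on a
140-level cell/boundary contrast). Truth labels use 1-px boundary lines (the
watershed-line convention); markers are the generators of the cells lying
entirely inside the frame inset by one lattice spacing, and the evaluation
polygon is the exact outline of the union of those cells — emulating an
expert who marks a set of complete cells and outlines them. Defaults (2000
cells/mm^2 at 0.557 um/px, 20% area CV) represent a healthy post-keratoplasty
endothelium.

The phantoms deliberately omit guttae, blur anisotropy, motion artifacts and
the gray-level histogram of real confocal images, and their boundary contrast
is cleaner than clinical data. Consequently the synthetic F-measures run
higher than the ~0.91 reported for patient images, and the sensitivity of the
segmentation to a mis-sized smoothing kernel is milder. Passing the synthetic
suites shows the machinery is implemented correctly and reproduces the
method's qualitative behavior (seed-count robustness, PDF-based rescue of a
corrupted `f*`, stochastic stability); it does not certify clinical accuracy.

## Problem sizes in the test suite

The validation experiments run on 500-px mosaics with ~155 cells (five
phantoms for the robustness/sensitivity experiments, twelve repeated runs for
the stochasticity experiment) and 350-px mosaics for the trainer, with the
trainer grid reduced to one `u`, five `k_sigma` and one `k_h` value at
`m = 25`; these sizes keep the full suite to minutes while leaving dozens of
cells per image, which is comparable to the clinical fields of view.

## Known limitations

- `modeRMrec` can fail when the reconstruction swallows most of a weak ring
  (observed on clinical data for very irregular mosaics); the error is
  signalled (`NoRingError`) rather than guessed around.
- Strongly anisotropic mosaics produce an elliptic ring whose radial
  projection is broad; no elliptic fit is attempted.
- Cell-size variability cannot be read off the spectrum's peak shape
  reliably, and no such estimator is provided.
- The segmentation's density estimate inherits a small positive bias from
  discarding border cells and from occasional fragmentation of partially
  imaged cells near the frame.
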