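# endothelix

Fully automatic quantification of corneal endothelium images from in vivo
confocal microscopy.

The corneal endothelium is a monolayer of roughly hexagonal cells whose
density decides whether a cornea stays transparent; clinics monitor it from
confocal images, mostly by tedious semi-automatic delineation. `endothelix`
implements two automatic routes:

1. **Spectral density estimation.** The quasi-periodic cell mosaic produces
   a ring in the 2-D Fourier spectrum at the characteristic frequency
   *f*\* (px⁻¹); the mean cell area is *A* = *α*/*f*\*² with the shape
   factor *α* (1 for square lattices, 2/√3 ≈ 1.15 for perfect hexagons,
   slightly below 1 for real endothelia), and density is δ = *f*\*²/*α*.
   Seven estimators of *f*\* are provided, including a parameter-free one
   (`modeRMrec`) that removes the DC peak's tail by grayscale
   dilation-by-reconstruction before taking the radial mean.
2. **Stochastic-watershed segmentation.** Repeated seeded watersheds with
   random hexagonal seed grids and added noise accumulate a boundary
   occurrence map; Gaussian smoothing (σ = *k*<sub>σ</sub>/*f*\*), an
   H-minima transform (*h* = *k*<sub>h</sub>·*m*/σ) and a classical
   watershed extract one region per cell, then boundaries are re-aligned to
   the unsmoothed image. From the label map the three clinical measures are
   computed: density (mm⁻²), polymegathism (CV of cell area, %) and
   pleomorphism (% cells with six neighbors).

A phantom generator (band-limited lattices with known *f*\* and *α*;
Voronoi mosaics with per-cell ground truth, markers and evaluation outline)
makes every stage testable without clinical data, and a marker-based
precision/recall/F scorer plus a leave-one-out parameter trainer reproduce
the method's evaluation machinery.

## Worked example

```python
from endothelix import GroundTruth, MosaicParams, make_mosaic, score, segment

phantom = make_mosaic(MosaicParams(density_mm2=2000, size_cv=20, rng_seed=7,
                                   shape=(350, 350)))
labels, info = segment(phantom.image, seed=42)
result = score(labels, GroundTruth(phantom.truth_markers, phantom.eval_polygon))
```

prints (see `examples/02_segment_mosaic.py`):

```
f* from image: 0.02571 px^-1, re-estimated from PDF: 0.02580 px^-1
89 regions segmented, 27 cells in the ground truth
precision = 1.000, recall = 1.000, F = 1.000
```

*f*\* ≈ 0.0257 px⁻¹ means a characteristic cell width of ~39 px (~22 µm at
0.557 µm/px, consistent with the phantom's 2000 cells/mm²); every one of the
27 ground-truth cells was recovered cell-for-cell (F = 1). Morphometry on
the same kind of phantom (`examples/03_morphometry.py`) reports density
2139.9 mm⁻², polymegathism 22.1% and pleomorphism 64.3% from the
segmentation, against 2154.9 mm⁻², 21.3% and 63.8% measured on the ground
truth labels.

The other example scripts cover spectral density estimation on the lattice
phantoms (`01`), and grid-search training of the three watershed parameters
with leave-one-out cross validation (`04`).

A thin CLI wraps the same functions:

```bash
endothelix phantom --pattern mosaic --size 350 --seed 7 --out work/
endothelix segment work/mosaic.png --seed 42 --out work/labels.tif
endothelix score work/labels.tif work/truth.txt
endothelix morpho work/labels.tif
```

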