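"""Fully automatic cell segmentation by a modified stochastic watershed.

The pipeline (all stages seeded and reproducible):

1. estimate the characteristic frequency ``f*`` of the image
   (ring-enhanced radial mean) and from it the expected cell count
   ``n_seeds = A_I f*^2`` (shape factor 1 at this stage);
2. repeat ``m`` times: add uniform noise in ``[0, u]`` to the inverted
   image, place seeds on a randomly rotated and translated hexagonal grid
   whose density matches the cell density, and run a seeded watershed;
   accumulate the watershed lines into a boundary-occurrence map (the PDF);
3. optionally re-estimate ``f*`` from the PDF (the PDF is a clean rendering
   of the boundaries, so this estimate is more reliable than one from the
   raw image) to size the smoothing;
4. Gaussian-smooth the PDF with ``sigma_PDF = k_sigma / f*``, suppress
   minima shallower than ``h = k_h m / sigma_PDF``, and run the classical
   watershed;
5. re-align the (smoothing-displaced) boundaries to the original image by
   shrinking every region 20% into a marker and running a final seeded
   watershed on the lightly smoothed inverted image.

Conventions fixed across the module: 4-connected regions, watershed lines
carry label 0, noise is real-valued (the 8-bit image is promoted to float,
no clipping), and one master seed spawns independent per-repetition RNG
streams.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import reconstruction
from skimage.segmentation import watershed

from endothelix.spectral import CharacteristicFrequency, NoRingError, estimate_f_star

__all__ = [
    "StoWaParams",
    "PDFMap",
    "LabelMap",
    "n_seeds_from_fstar",
    "hex_seed_grid",
    "seeded_watershed",
    "build_pdf",
    "pdf_to_labels",
    "refine_fstar_from_pdf",
    "correct_borders",
    "segment",
]

logger = logging.getLogger(__name__)

SQRT3 = np.sqrt(3.0)


@dataclass
class StoWaParams:
    """Stochastic-watershed parameters.

    ``u`` is the range of the uniform noise added at each repetition (gray
    levels); ``k_sigma = sigma_PDF * f*`` sizes the PDF smoothing relative
    to the cell size; ``k_h`` sets the H-minima depth ``h = k_h m /
    sigma_PDF``; ``m`` is the number of repetitions; ``alpha`` the shape
    factor used for seeding.  The defaults are the values found optimal by
    leave-one-out training on clinical confocal images.
    """

    u: float = 30.0
    k_sigma: float = 0.17
    k_h: float = 0.002
    m: int = 100
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.u < 0 or self.m < 1 or self.k_sigma <= 0 or self.k_h < 0:
            raise ValueError("invalid stochastic-watershed parameters")


@dataclass
class PDFMap:
    """Boundary-occurrence counts over ``m`` stochastic-watershed repetitions."""

    counts: np.ndarray  # integer, in [0, m]
    m: int


# a LabelMap is simply an integer raster: region ids >= 1, boundary pixels 0
LabelMap = np.ndarray


def n_seeds_from_fstar(image_area_px: float, f_star: float, alpha: float = 1.0) -> int:
    """Expected number of cells in the frame, ``A_I f*^2 / alpha`` (min 1)."""
    if image_area_px <= 0 or f_star <= 0 or alpha <= 0:
        raise ValueError("arguments must be positive")
    return max(1, int(round(image_area_px * f_star**2 / alpha)))


def hex_seed_grid(
    image_shape: tuple[int, int], n_seeds: int, rng: np.random.Generator
) -> np.ndarray:
    """Randomly placed hexagonal seed grid with cell-density point density.

    A hexagonal grid with edge length ``t = sqrt(2 A_I / (3 sqrt(3)
    n_seeds))`` carries one vertex per area ``A_I / n_seeds``; the grid gets
    a rotation uniform in ``[0, 2pi)`` and a translation uniform over one
    grid cell.  Returns the ``(x, y)`` seed positions falling inside the
    image (the count fluctuates around ``n_seeds``).
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    h, w = image_shape
    area = float(h) * float(w)
    t = np.sqrt(2.0 / (3.0 * SQRT3) * area / n_seeds)
    spacing = SQRT3 * t  # distance between adjacent grid points
    row_dy = spacing * SQRT3 / 2
    theta = rng.uniform(0.0, 2.0 * np.pi)
    tx = rng.uniform(0.0, spacing)
    ty = rng.uniform(0.0, row_dy)
    # generate an axis-aligned triangular lattice large enough to cover the
    # rotated frame, then rotate about the image center
    half_diag = 0.5 * np.hypot(h, w) + spacing
    nx = int(np.ceil(2 * half_diag / spacing)) + 2
    ny = int(np.ceil(2 * half_diag / row_dy)) + 2
    ix = np.arange(nx)
    iy = np.arange(ny)
    gx = -half_diag + ix[None, :] * spacing + (iy[:, None] % 2) * (spacing / 2) + tx
    gy = -half_diag + iy[:, None] * row_dy + 0 * ix[None, :] + ty
    pts = np.column_stack([gx.ravel(), np.broadcast_to(gy, gx.shape).ravel()])
    c, s = np.cos(theta), np.sin(theta)
    rot = pts @ np.array([[c, s], [-s, c]])
    rot += np.array([w / 2.0, h / 2.0])
    inside = (
        (rot[:, 0] >= 0) & (rot[:, 0] <= w - 1) & (rot[:, 1] >= 0) & (rot[:, 1] <= h - 1)
    )
    return rot[inside]


def _markers_from_points(shape: tuple[int, int], seeds: np.ndarray) -> np.ndarray:
    """Label image with one positive label per seed point (rounded to pixels).

    Seeds rounding to the same pixel collapse into one marker.
    """
    markers = np.zeros(shape, dtype=np.int32)
    cols = np.clip(np.rint(seeds[:, 0]).astype(int), 0, shape[1] - 1)
    rows = np.clip(np.rint(seeds[:, 1]).astype(int), 0, shape[0] - 1)
    markers[rows, cols] = 1
    lab, _ = ndimage.label(markers, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    return lab

def seeded_watershed(image: np.ndarray, seeds: np.ndarray) -> LabelMap:
    """Watershed of ``image`` flooded from the given seed points only.

    ``image`` must already have bright boundaries (i.e. be the inverted
    endothelium image); the seeds are imposed as the only minima, so the
    result has exactly one region per (distinct) seed, separated by
    0-labeled watershed lines.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.float64))
    if seeds.size == 0:
        raise ValueError("at least one seed is required")
    markers = _markers_from_points(image.shape, seeds)
    return watershed(image, markers=markers, connectivity=1, watershed_line=True)


def build_pdf(
    image: np.ndarray,
    params: StoWaParams,
    f_star: float,
    rng: np.random.Generator | int,
) -> PDFMap:
    """Accumulate watershed-line occurrences over ``m`` randomized repetitions.

    Each repetition inverts the image, adds i.i.d. uniform noise in
    ``[0, u]``, places a fresh random hexagonal seed grid with ``n_seeds =
    A_I f*^2 / alpha`` points, and runs the seeded watershed; the 0-labeled
    line pixels increment the counts.
    """
    img = np.asarray(image, dtype=np.float64)
    inverted = 255.0 - img
    h, w = img.shape
    n_seeds = n_seeds_from_fstar(h * w, f_star, params.alpha)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    streams = rng.spawn(params.m)
    counts = np.zeros(img.shape, dtype=np.int32)
    for stream in streams:
        noisy = inverted + stream.uniform(0.0, params.u, size=img.shape)
        seeds = hex_seed_grid((h, w), n_seeds, stream)
        if len(seeds) == 0:  # degenerate grid placement; recenter one seed
            seeds = np.array([[w / 2.0, h / 2.0]])
        labels = seeded_watershed(noisy, seeds)
        counts += labels == 0
    return PDFMap(counts=counts, m=params.m)


def pdf_to_labels(pdf: PDFMap, params: StoWaParams, f_star: float) -> LabelMap:
    """Extract the final segmentation from the boundary-occurrence map.

    The counts are smoothed with a Gaussian of ``sigma_PDF = k_sigma / f*``,
    local minima shallower than ``h = k_h m / sigma_PDF`` are suppressed
    (H-minima transform on the float raster), and the classical watershed
    partitions the result.
    """
    if f_star <= 0:
        raise ValueError("f_star must be positive")
    sigma = params.k_sigma / f_star
    h_depth = params.k_h * params.m / sigma
    smoothed = ndimage.gaussian_filter(pdf.counts.astype(np.float64), sigma)
    if h_depth > 0:
        filled = reconstruction(smoothed + h_depth, smoothed, method="erosion")
    else:
        filled = smoothed
    labels = watershed(filled, connectivity=1, watershed_line=True)
    if labels.max() == 0:  # fully suppressed relief: one region, no boundary
        labels = np.ones_like(labels)
    return labels


def refine_fstar_from_pdf(pdf: PDFMap) -> CharacteristicFrequency:
    """Re-estimate ``f*`` from the PDF with the ring-enhanced radial mean.

    The PDF shows the cell boundaries free of illumination gradients and
    texture, so its spectral ring is cleaner than the raw image's.  Raises
    :class:`~endothelix.spectral.NoRingError` when the PDF carries no ring
    (e.g. it is uniformly zero).
    """
    counts = pdf.counts
    if not np.any(counts):
        raise NoRingError("PDF is uniformly zero")
    return estimate_f_star(counts.astype(np.float64), method="modeRMrec")


def correct_borders(original_image: np.ndarray, labels: LabelMap) -> LabelMap:
    """Re-align smoothing-displaced boundaries to the original image.

    Every region is shrunk to the pixels where ``D_c/(D_c + D_b) < 0.8``
    (``D_c``: Euclidean distance to the region's center of mass, ``D_b``:
    to its boundary — a 20% shrink); the shrunken regions seed a watershed
    of the inverted original smoothed with a Gaussian of sigma 2.  The
    region count is preserved; a region whose shrunken marker would be empty
    keeps its original extent as marker (logged).
    """
    img = np.asarray(original_image, dtype=np.float64)
    markers = np.zeros_like(labels, dtype=np.int32)
    slices = ndimage.find_objects(labels)
    for lab, slc in enumerate(slices, start=1):
        if slc is None:
            continue
        mask = labels[slc] == lab
        if not mask.any():
            continue
        d_b = ndimage.distance_transform_edt(mask)
        ys, xs = np.nonzero(mask)
        cy, cx = ys.mean(), xs.mean()
        # for non-convex regions the centroid may fall outside; use the
        # nearest region pixel as the distance origin then
        iy, ix = int(round(cy)), int(round(cx))
        if not (0 <= iy < mask.shape[0] and 0 <= ix < mask.shape[1] and mask[iy, ix]):
            k = np.argmin((ys - cy) ** 2 + (xs - cx) ** 2)
            cy, cx = float(ys[k]), float(xs[k])
        yy, xx = np.indices(mask.shape)
        d_c = np.hypot(yy - cy, xx - cx)
        shrunk = mask & (d_c / (d_c + d_b) < 0.8)
        if not shrunk.any():
            logger.info("region %d: empty shrunken marker; keeping original extent", lab)
            shrunk = mask
        markers[slc][shrunk] = lab
    smoothed_inv = ndimage.gaussian_filter(255.0 - img, 2.0)
    return watershed(smoothed_inv, markers=markers, connectivity=1, watershed_line=True)


def segment(
    image: np.ndarray,
    params: StoWaParams | None = None,
    seed: int | np.random.Generator = 0,
    f_star: float | None = None,
    refine_fstar: bool = True,
    correct: bool = True,
) -> tuple[LabelMap, dict]:
    """Segment an endothelium image fully automatically.

    Runs the complete pipeline: spectral ``f*`` estimate (unless ``f_star``
    is supplied), PDF construction, optional ``f*`` re-estimation from the
    PDF, watershed extraction and boundary correction.  Returns the label
    map (0 = boundary) and a dict of intermediate artifacts (``pdf``,
    ``f_star_image``, ``f_star_pdf``, ``n_seeds``).
    """
    params = params or StoWaParams()
    img = np.asarray(image, dtype=np.float64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if f_star is None:
        f_star = estimate_f_star(img, method="modeRMrec").f_star
    info: dict = {"f_star_image": f_star}
    info["n_seeds"] = n_seeds_from_fstar(img.size, f_star, params.alpha)
    pdf = build_pdf(img, params, f_star, rng)
    info["pdf"] = pdf
    f_for_sigma = f_star
    if refine_fstar:
        try:
            f_for_sigma = refine_fstar_from_pdf(pdf).f_star
        except NoRingError:
            logger.warning("f* re-estimation from PDF failed; using image estimate")
    info["f_star_pdf"] = f_for_sigma
    labels = pdf_to_labels(pdf, params, f_for_sigma)
    if correct:
        labels = correct_borders(img, labels)
    return labels, info
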