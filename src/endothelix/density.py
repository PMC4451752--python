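"""Cell density from the characteristic frequency.

If ``f*`` is the characteristic frequency of the mosaic (cycles/px) then
``l = 1/f*`` is the most common cell width and the mean cell area is
``A = alpha / f*^2``, where the shape factor ``alpha`` depends on the cell
shape and packing regularity: 1 for a square lattice, ``2/sqrt(3) ~ 1.15``
for a perfect hexagonal one, and typically slightly below 1 for the
irregular mosaics of a real endothelium.  Cell density follows as
``delta = f*^2 / alpha`` (cells per px^2), converted to mm^-2 with the
lateral sampling density.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["DensityEstimate", "density_from_fstar", "calibrate_alpha"]


@dataclass
class DensityEstimate:
    """Cell area and density derived from a characteristic frequency."""

    f_star: float  # px^-1
    alpha: float
    sampling_um_per_px: float
    mean_cell_area_px2: float
    mean_cell_area_um2: float
    density_mm2: float


def density_from_fstar(
    f_star: float, alpha: float = 1.0, sampling_um_per_px: float = 0.557
) -> DensityEstimate:
    """Convert a characteristic frequency to mean cell area and density.

    ``density_mm2 = (f*^2 / alpha) * (1000 / sampling)^2``.
    """
    if not 0.0 < f_star <= 0.5:
        raise ValueError("f_star must lie in (0, 0.5] px^-1")
    if alpha <= 0 or sampling_um_per_px <= 0:
        raise ValueError("alpha and sampling must be positive")
    area_px2 = alpha / f_star**2
    area_um2 = area_px2 * sampling_um_per_px**2
    density = (f_star**2 / alpha) * (1000.0 / sampling_um_per_px) ** 2
    return DensityEstimate(
        f_star=f_star,
        alpha=alpha,
        sampling_um_per_px=sampling_um_per_px,
        mean_cell_area_px2=area_px2,
        mean_cell_area_um2=area_um2,
        density_mm2=density,
    )


def calibrate_alpha(
    f_stars: Sequence[float], densities_px2: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out calibration of the shape factor against ground truth.

    Parameters
    ----------
    f_stars
        Characteristic frequency estimate per training image (px^-1).
    densities_px2
        Ground-truth density per image in cells per px^2 (``n_eval/A_eval``).

    Returns
    -------
    alphas, rel_errors
        Per held-out image ``i``: ``alpha_i`` is the arithmetic mean of
        ``f*_j^2 / delta_j`` over the other images, and ``rel_errors[i]`` is
        the relative density error ``(delta_est - delta_gt) / delta_gt``
        with ``delta_est = f*_i^2 / alpha_i``.
    """
    f = np.asarray(f_stars, dtype=np.float64)
    d = np.asarray(densities_px2, dtype=np.float64)
    if f.shape != d.shape or f.ndim != 1 or f.size == 0:
        raise ValueError("f_stars and densities_px2 must be equal-length 1-D sequences")
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ValueError("all training images must have a valid f* estimate")
    per_image = f**2 / d
    n = f.size
    if n == 1:
        alphas = per_image.copy()  # degenerate: self-calibration
    else:
        total = per_image.sum()
        alphas = (total - per_image) / (n - 1)
    est = f**2 / alphas
    rel_errors = (est - d) / d
    return alphas, rel_errors
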