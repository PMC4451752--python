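"""Clinical morphometry from a cell segmentation.

Three quantities summarize the health of the endothelial layer:

* **cell density** — inverse of the mean cell area, in cells/mm^2;
* **polymegathism** — coefficient of variation of cell area, in percent
  (cell-size variability);
* **pleomorphism** — percentage of cells with exactly six neighbors
  (cell-shape regularity).

Regions touching the image border are partially imaged and are excluded
from the measurements, but still count as neighbors of the retained cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MorphometryReport", "measure"]


@dataclass
class MorphometryReport:
    n_cells_used: int
    density_mm2: float
    polymegathism_pct: float
    pleomorphism_pct: float
    cells: pd.DataFrame  # per retained cell: label, area_um2, n_neighbors

    def __str__(self) -> str:  # CLI-friendly summary
        return (
            f"cells used:      {self.n_cells_used}\n"
            f"density:         {self.density_mm2:.1f} mm^-2\n"
            f"polymegathism:   {self.polymegathism_pct:.1f} %\n"
            f"pleomorphism:    {self.pleomorphism_pct:.1f} %"
        )


def _neighbor_pairs(labels: np.ndarray) -> set[tuple[int, int]]:
    """Region adjacency: two regions are neighbors iff some boundary (0)
    pixel has both labels within its 8-neighborhood."""
    h, w = labels.shape
    by, bx = np.nonzero(labels == 0)
    offsets = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    cols = []
    for dy, dx in offsets:
        yy, xx = by + dy, bx + dx
        valid = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        col = np.zeros(by.size, dtype=labels.dtype)
        col[valid] = labels[yy[valid], xx[valid]]
        cols.append(col)
    neigh = np.column_stack(cols)  # (n_boundary, 8) labels around each line pixel
    pairs: set[tuple[int, int]] = set()
    for i in range(neigh.shape[1]):
        for j in range(i + 1, neigh.shape[1]):
            a, b = neigh[:, i], neigh[:, j]
            ok = (a > 0) & (b > 0) & (a != b)
            if ok.any():
                lo = np.minimum(a[ok], b[ok])
                hi = np.maximum(a[ok], b[ok])
                pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def measure(labels: np.ndarray, sampling_um_per_px: float = 0.557) -> MorphometryReport:
    """Compute density, polymegathism and pleomorphism from a label map.

    ``labels`` uses 0 for boundary pixels and ids >= 1 for cells; areas are
    the pixel counts of the label support, converted to um^2 by the squared
    sampling density.  The CV uses the population standard deviation.
    """
    labels = np.asarray(labels)
    if sampling_um_per_px <= 0:
        raise ValueError("sampling must be positive")
    ids, areas_px = np.unique(labels[labels > 0], return_counts=True)
    # a clipped cell may be separated from the frame edge only by the 1-px
    # watershed line running along the border, so "touching the border"
    # includes the two outermost rows/columns
    rim = np.concatenate(
        [labels[:2, :].ravel(), labels[-2:, :].ravel(),
         labels[:, :2].ravel(), labels[:, -2:].ravel()]
    )
    border = set(int(b) for b in np.unique(rim) if b > 0)
    keep = np.array([i not in border for i in ids])
    if keep.sum() < 2:
        raise ValueError("fewer than 2 usable (non-border) cells")
    pairs = _neighbor_pairs(labels)
    n_neighbors = {int(i): 0 for i in ids}
    for a, b in pairs:
        n_neighbors[a] += 1
        n_neighbors[b] += 1

    kept_ids = ids[keep]
    areas_um2 = areas_px[keep] * sampling_um_per_px**2
    mean_area = areas_um2.mean()
    density = 1e6 / mean_area
    cv = float(areas_um2.std() / mean_area * 100.0)  # population sd
    nb = np.array([n_neighbors[int(i)] for i in kept_ids])
    pleo = float((nb == 6).mean() * 100.0)
    cells = pd.DataFrame(
        {"label": kept_ids, "area_um2": areas_um2, "n_neighbors": nb}
    )
    return MorphometryReport(
        n_cells_used=int(keep.sum()),
        density_mm2=float(density),
        polymegathism_pct=cv,
        pleomorphism_pct=pleo,
        cells=cells,
    )
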