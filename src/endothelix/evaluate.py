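"""Segmentation scoring against marker ground truth, and parameter training.

The ground truth for an image is one marker point per complete cell inside
a hand-drawn evaluation polygon.  A segmented region counts as correct when
it contains exactly one marker and lies at least 85% inside the polygon;
regions entirely outside the polygon, or overlapping it by less than a
quarter of the average region size, are ignored.  Precision ``p =
n_corr/n_total``, recall ``r = n_corr/n_eval`` and their harmonic mean, the
F-measure, summarize the agreement.

Training evaluates the stochastic watershed over a grid of ``(u, k_sigma,
k_h)`` triples on a set of images with ground truth (seeding from the
ground-truth density so the spectral estimator does not influence the
result) and picks, per held-out image, the triple maximizing the mean F of
the remaining images (leave-one-out cross validation).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from endothelix.segment import StoWaParams, build_pdf, correct_borders, pdf_to_labels

__all__ = ["GroundTruth", "ScoreResult", "score", "train"]

logger = logging.getLogger(__name__)


@dataclass
class GroundTruth:
    """Marker-per-cell ground truth with its evaluation polygon."""

    markers: np.ndarray  # (n_eval, 2) float, (x, y) pixel coordinates
    eval_polygon: np.ndarray  # (k, 2) float, (x, y) vertices

    def __post_init__(self) -> None:
        self.markers = np.atleast_2d(np.asarray(self.markers, dtype=np.float64))
        self.eval_polygon = np.asarray(self.eval_polygon, dtype=np.float64)
        if self.markers.shape[0] < 1:
            raise ValueError("ground truth requires at least one marker")

    @property
    def n_eval(self) -> int:
        return self.markers.shape[0]

    def area_eval_px2(self) -> float:
        """Polygon area by the shoelace formula."""
        x, y = self.eval_polygon[:, 0], self.eval_polygon[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


@dataclass
class ScoreResult:
    n_total: int
    n_corr: int
    n_eval: int
    precision: float
    recall: float
    f_measure: float


def _polygon_mask(shape: tuple[int, int], polygon: np.ndarray) -> np.ndarray:
    """Pixels whose centers lie inside the polygon (even-odd rule)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = MplPath(polygon).contains_points(pts)
    return inside.reshape(h, w)


def score(labels: np.ndarray, truth: GroundTruth) -> ScoreResult:
    """Score a label map against marker ground truth (precision/recall/F)."""
    labels = np.asarray(labels)
    inside = _polygon_mask(labels.shape, truth.eval_polygon)

    ids, areas = np.unique(labels[labels > 0], return_counts=True)
    area_of = dict(zip(ids.tolist(), areas.tolist()))
    in_ids, in_areas = np.unique(labels[(labels > 0) & inside], return_counts=True)
    overlap_of = dict(zip(in_ids.tolist(), in_areas.tolist()))
    if len(in_ids) == 0:
        return ScoreResult(0, 0, truth.n_eval, 0.0, 0.0, 0.0)
    # average size over the regions intersecting the polygon
    avg_size = float(np.mean([area_of[i] for i in in_ids.tolist()]))

    # markers -> owning region (markers on a boundary pixel hit label 0 and
    # are not credited to any region)
    mcols = np.clip(np.rint(truth.markers[:, 0]).astype(int), 0, labels.shape[1] - 1)
    mrows = np.clip(np.rint(truth.markers[:, 1]).astype(int), 0, labels.shape[0] - 1)
    marker_labels = labels[mrows, mcols]
    marker_count: dict[int, int] = {}
    for lab in marker_labels[marker_labels > 0].tolist():
        marker_count[lab] = marker_count.get(lab, 0) + 1

    n_total = 0
    n_corr = 0
    for lab in in_ids.tolist():
        ov = overlap_of[lab]
        if ov < avg_size / 4.0:
            continue  # barely overlaps the evaluation region: ignored
        n_total += 1
        if marker_count.get(lab, 0) == 1 and ov / area_of[lab] >= 0.85:
            n_corr += 1
    p = n_corr / n_total if n_total else 0.0
    r = n_corr / truth.n_eval
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return ScoreResult(n_total, n_corr, truth.n_eval, p, r, f)


def _segment_fixed_seeding(
    image: np.ndarray,
    truth: GroundTruth,
    params: StoWaParams,
    seed: int,
) -> np.ndarray:
    """Segment with seeding and smoothing scale taken from the ground truth.

    ``n_seeds = A_I n_eval / A_eval`` and ``f* = sqrt(n_eval / A_eval)``
    (shape factor 1), so the trained parameters are independent of the
    spectral estimator.
    """
    img = np.asarray(image, dtype=np.float64)
    f_star = float(np.sqrt(truth.n_eval / truth.area_eval_px2()))
    rng = np.random.default_rng(seed)
    pdf = build_pdf(img, params, f_star, rng)
    labels = pdf_to_labels(pdf, params, f_star)
    return correct_borders(img, labels)


def train(
    image_set: Sequence[tuple[np.ndarray, GroundTruth]],
    u_values: Sequence[float],
    k_sigma_values: Sequence[float],
    k_h_values: Sequence[float],
    m: int = 100,
    base_seed: int = 0,
) -> tuple[list[tuple[float, float, float]], pd.DataFrame]:
    """Grid-search the stochastic-watershed parameters with leave-one-out CV.

    Every ``(u, k_sigma, k_h)`` triple is applied once to every image (with
    a fixed per-triple seed, so identical images score identically); the
    F-measure of each run goes into a long-format surface table.  For each
    image ``i`` the returned triple is the argmax of the mean F over the
    *other* images.

    Returns ``(per_image_params, surface)`` where ``surface`` has columns
    ``u, k_sigma, k_h, image, F``.
    """
    grid = list(itertools.product(u_values, k_sigma_values, k_h_values))
    if not grid or not image_set:
        raise ValueError("image set and parameter grid must be non-empty")
    records = []
    for g, (u, ks, kh) in enumerate(grid):
        params = StoWaParams(u=u, k_sigma=ks, k_h=kh, m=m)
        for i, (image, truth) in enumerate(image_set):
            seed = base_seed + 100003 * g  # fixed per triple
            try:
                labels = _segment_fixed_seeding(image, truth, params, seed)
                f = score(labels, truth).f_measure
            except Exception:  # a failed segmentation scores 0 for this cell
                logger.exception("segmentation failed for image %d, triple %s", i, (u, ks, kh))
                f = 0.0
            records.append({"u": u, "k_sigma": ks, "k_h": kh, "image": i, "F": f})
    surface = pd.DataFrame.from_records(records)

    per_image: list[tuple[float, float, float]] = []
    for i in range(len(image_set)):
        others = surface[surface["image"] != i]
        if others.empty:  # single-image set: self-training
            others = surface
        mean_f = others.groupby(["u", "k_sigma", "k_h"])["F"].mean()
        per_image.append(tuple(float(v) for v in mean_f.idxmax()))
    return per_image, surface
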