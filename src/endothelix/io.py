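"""Shared image and ground-truth I/O, and the end-to-end pipeline runner.

Images are 8-bit grayscale TIFF or PNG in; label maps and PDFs are written
as 16-bit TIFF.  Ground truth travels in a plain columnar text sidecar with
a marker section and a polygon section::

    # markers x y
    12.0 30.5
    ...
    # polygon x y
    5.0 5.0
    ...

Coordinates are 0-based pixel positions, origin at the top-left corner.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from endothelix import __version__
from endothelix.evaluate import GroundTruth
from endothelix.morphometry import MorphometryReport, measure
from endothelix.segment import StoWaParams, segment

__all__ = [
    "read_image",
    "write_image",
    "write_labels",
    "read_truth",
    "write_truth",
    "RunConfig",
    "run_pipeline",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale image (TIFF/PNG); RGB inputs are rejected."""
    img = iio.imread(path)
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel grayscale image")
    return np.asarray(img)


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    """Write a label map (or PDF counts) as 16-bit TIFF, 0 = boundary."""
    arr = np.asarray(labels)
    if arr.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
    tifffile.imwrite(str(path), arr.astype(np.uint16))


def write_truth(path: str | Path, truth: GroundTruth) -> None:
    lines = ["# markers x y"]
    lines += [f"{x:.3f} {y:.3f}" for x, y in truth.markers]
    lines.append("# polygon x y")
    lines += [f"{x:.3f} {y:.3f}" for x, y in truth.eval_polygon]
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path: str | Path) -> GroundTruth:
    markers: list[tuple[float, float]] = []
    polygon: list[tuple[float, float]] = []
    section: list[tuple[float, float]] | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "markers" in line:
                section = markers
            elif "polygon" in line:
                section = polygon
            else:
                raise ValueError(f"{path}: unknown section header {line!r}")
            continue
        if section is None:
            raise ValueError(f"{path}: data before any section header")
        x, y = line.split()
        section.append((float(x), float(y)))
    return GroundTruth(markers=np.array(markers), eval_polygon=np.array(polygon))


@dataclass
class RunConfig:
    """Configuration of a full quantification run.

    Defaults reproduce the trained configuration: ring-enhanced spectral
    estimate, u=30, k_sigma=0.17, k_h=0.002, m=100, shape factor 1 for
    seeding, with f* re-estimation from the PDF and border correction on.
    """

    input_path: str
    out_dir: str
    method: str = "modeRMrec"
    params: StoWaParams = field(default_factory=StoWaParams)
    sampling_um_per_px: float = 0.557
    master_seed: int = 0
    crop: tuple[int, int, int, int] | None = None  # (row0, col0, height, width)
    refine_fstar: bool = True
    correct_borders: bool = True
    write_pdf: bool = True


def run_pipeline(config: RunConfig) -> MorphometryReport:
    """Run segmentation + morphometry on one image and write all artifacts.

    Writes ``labels.tif`` (16-bit, 0 = boundary), optionally ``pdf.tif``,
    ``report.json`` and a reproducibility record ``run.json`` into
    ``config.out_dir``.
    """
    image = read_image(config.input_path)
    if config.crop is not None:
        r0, c0, ch, cw = config.crop
        image = image[r0 : r0 + ch, c0 : c0 + cw]
    labels, info = segment(
        image,
        params=config.params,
        seed=config.master_seed,
        refine_fstar=config.refine_fstar,
        correct=config.correct_borders,
    )
    report = measure(labels, config.sampling_um_per_px)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_labels(out / "labels.tif", labels)
    if config.write_pdf:
        write_labels(out / "pdf.tif", info["pdf"].counts)
    report_dict = {
        "n_cells_used": report.n_cells_used,
        "density_mm2": report.density_mm2,
        "polymegathism_pct": report.polymegathism_pct,
        "pleomorphism_pct": report.pleomorphism_pct,
        "f_star_image": info["f_star_image"],
        "f_star_pdf": info["f_star_pdf"],
        "n_seeds": info["n_seeds"],
    }
    (out / "report.json").write_text(json.dumps(report_dict, indent=2) + "\n")
    record = {
        "software": f"endothelix {__version__}",
        "input": str(config.input_path),
        "method": config.method,
        "params": asdict(config.params),
        "sampling_um_per_px": config.sampling_um_per_px,
        "master_seed": config.master_seed,
        "crop": config.crop,
        "refine_fstar": config.refine_fstar,
        "correct_borders": config.correct_borders,
    }
    (out / "run.json").write_text(json.dumps(record, indent=2) + "\n")
    report.cells.to_csv(out / "cells.csv", index=False)
    return report
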