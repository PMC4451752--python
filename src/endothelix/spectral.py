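"""Spectral estimation of the characteristic frequency of a cell mosaic.

A monolayer of roughly hexagonal cells produces a ring in the magnitude of
the 2-D Fourier transform of its image.  The radius of that ring, the
*characteristic frequency* ``f*`` (in cycles per pixel), is the reciprocal of
the characteristic cell width and, through a shape factor, determines the
cell density.  This module computes radial projections of the 2-D spectrum
and extracts ``f*`` with seven estimators, including the parameter-free
ring-enhancement variant ``modeRMrec`` in which the slowly decaying central
(DC) peak is removed by grayscale dilation-by-reconstruction before the
radial mean is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import reconstruction

__all__ = [
    "Spectrum2D",
    "RadialProfile",
    "CharacteristicFrequency",
    "NoRingError",
    "METHODS",
    "spectrum_of",
    "radial_project",
    "find_peaks",
    "enhance_ring",
    "estimate_f_star",
]

#: Estimator names accepted by :func:`estimate_f_star`.
METHODS = ("modeRM", "1stRM", "2ndRMAX", "modePS", "meanPS", "medianPS", "modeRMrec")


class NoRingError(RuntimeError):
    """Raised when no spectral ring (interior peak) can be detected."""


@dataclass
class Spectrum2D:
    """DC-centered magnitude of the 2-D discrete Fourier transform.

    For an even working-frame size ``N`` the DC sample sits at index
    ``(N//2, N//2)`` of the shifted grid.
    """

    magnitude: np.ndarray  # |F|, DC-centered, shape (N, N)
    image_size: int
    _power: np.ndarray | None = field(default=None, repr=False)

    @property
    def power(self) -> np.ndarray:
        if self._power is None:
            self._power = self.magnitude.astype(np.float64) ** 2
        return self._power

    @property
    def dc_index(self) -> tuple[int, int]:
        n = self.image_size
        return (n // 2, n // 2)


@dataclass
class RadialProfile:
    """1-D radial projection of a 2-D spectrum.

    ``bins`` are the frequencies ``{0, 1/N, 2/N, ..., 1/2}`` in px^-1;
    ``values`` hold the per-bin mean or maximum of the 2-D samples whose
    radial frequency rounds to that bin.
    """

    bins: np.ndarray
    values: np.ndarray
    aggregate_kind: str
    n: int  # working-frame width in px

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.values):
            raise ValueError("bins and values must have equal length")

    def save_txt(self, path) -> None:
        """Write the profile as two-column text (frequency px^-1, value)."""
        np.savetxt(path, np.column_stack([self.bins, self.values]),
                   header=f"frequency_px^-1 {self.aggregate_kind}")


@dataclass
class CharacteristicFrequency:
    """A detected characteristic frequency f* with provenance.

    ``f_star`` is sub-bin (parabola refined), in cycles per pixel of the
    working frame; ``lambda_px = 1/f_star`` is the characteristic cell width.
    """

    f_star: float
    bin_index: int
    method: str
    peak_value: float

    @property
    def lambda_px(self) -> float:
        return 1.0 / self.f_star


def _as_square(image: np.ndarray) -> np.ndarray:
    """Largest centered square crop (spectral bins assume a square frame)."""
    h, w = image.shape
    n = min(h, w)
    r0 = (h - n) // 2
    c0 = (w - n) // 2
    return image[r0 : r0 + n, c0 : c0 + n]


def spectrum_of(image: np.ndarray) -> Spectrum2D:
    """DC-centered magnitude spectrum of a (square-cropped) grayscale image."""
    img = _as_square(np.asarray(image, dtype=np.float64))
    mag = np.abs(np.fft.fftshift(np.fft.fft2(img)))
    return Spectrum2D(magnitude=mag, image_size=img.shape[0])


def _radial_bin_index(n: int) -> np.ndarray:
    """Per-sample bin index: radial frequency rounded to the nearest k/N.

    Corner samples whose radius exceeds 1/2 are assigned to the last bin so
    that the bins partition the 2-D samples.
    """
    f = np.fft.fftshift(np.fft.fftfreq(n))
    fx, fy = np.meshgrid(f, f)
    r = np.hypot(fx, fy)
    idx = np.rint(r * n).astype(np.intp)
    return np.minimum(idx, n // 2)


def radial_project(spectrum: Spectrum2D, aggregate_kind: str = "mean_magnitude") -> RadialProfile:
    """Project the 2-D spectrum onto radial frequency.

    Parameters
    ----------
    spectrum
        The 2-D spectrum to project.
    aggregate_kind
        ``mean_magnitude`` (radial mean of |F|), ``max_magnitude`` (radial
        maximum of |F|) or ``mean_power`` (radial mean of |F|^2).
    """
    n = spectrum.image_size
    if n == 0 or spectrum.magnitude.size == 0:
        raise ValueError("empty spectrum")
    if aggregate_kind == "mean_magnitude":
        data = spectrum.magnitude
    elif aggregate_kind == "max_magnitude":
        data = spectrum.magnitude
    elif aggregate_kind == "mean_power":
        data = spectrum.power
    else:
        raise ValueError(f"unknown aggregate_kind {aggregate_kind!r}")

    idx = _radial_bin_index(n).ravel()
    flat = data.ravel()
    nbins = n // 2 + 1
    if aggregate_kind == "max_magnitude":
        values = np.zeros(nbins)
        np.maximum.at(values, idx, flat)
    else:
        sums = np.bincount(idx, weights=flat, minlength=nbins)
        counts = np.bincount(idx, minlength=nbins)
        values = sums / counts
    bins = np.arange(nbins) / n
    return RadialProfile(bins=bins, values=values, aggregate_kind=aggregate_kind, n=n)


def _parabola_vertex(vm: float, v0: float, vp: float) -> tuple[float, float]:
    """Vertex offset (clamped to [-1/2, 1/2]) and height of the 3-point parabola."""
    denom = vm - 2.0 * v0 + vp
    if denom == 0.0:
        return 0.0, float(v0)
    dx = 0.5 * (vm - vp) / denom
    dx = float(np.clip(dx, -0.5, 0.5))
    height = v0 - 0.25 * (vm - vp) * dx
    return dx, float(height)


def find_peaks(profile: RadialProfile) -> list[tuple[float, float]]:
    """Local maxima of the profile, parabola-refined, excluding the DC bin.

    A bin ``i`` (``1 <= i <= len-2``) is a local maximum when
    ``values[i] > values[i-1]`` and ``values[i] >= values[i+1]`` (plateau
    ties resolve toward the lower frequency).  Each maximum is refined by the
    3-point parabola through its neighbors; the refined position is clamped
    to within half a bin.  Returns ``(refined_bin_position, refined_height)``
    pairs in increasing frequency order.
    """
    v = np.asarray(profile.values, dtype=np.float64)
    if v.size < 3:
        raise ValueError("profile must have at least 3 bins")
    peaks: list[tuple[float, float]] = []
    for i in range(1, v.size - 1):
        if v[i] > v[i - 1] and v[i] >= v[i + 1]:
            dx, height = _parabola_vertex(v[i - 1], v[i], v[i + 1])
            peaks.append((i + dx, height))
    if not peaks:
        raise NoRingError("no ring detected: profile has no interior local maximum")
    return peaks


def enhance_ring(spectrum: Spectrum2D) -> Spectrum2D:
    """Remove the central DC peak and its tail, keeping the ring.

    The DC sample of |F| is dilated by reconstruction under |F| with the
    4-connected elementary structuring element; the reconstruction H is the
    central peak with its radially non-increasing tail.  The returned
    spectrum holds ``F' = |F| - H``, which is zero at DC, nonnegative, and
    retains any ring that rises above the tail.  This acts as a parameter-free
    high-pass filter tailored to the image at hand.
    """
    mag = spectrum.magnitude.astype(np.float64)
    seed = np.zeros_like(mag)
    dc = spectrum.dc_index
    seed[dc] = mag[dc]
    footprint = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=np.uint8)
    h_inf = reconstruction(seed, mag, method="dilation", footprint=footprint)
    enhanced = mag - h_inf
    # guard against tiny negative rounding residue
    np.maximum(enhanced, 0.0, out=enhanced)
    return Spectrum2D(magnitude=enhanced, image_size=spectrum.image_size)


def _weighted_mean_bin(profile: RadialProfile, n_highpass: int) -> float:
    w = profile.values.astype(np.float64).copy()
    w[:n_highpass] = 0.0
    total = w.sum()
    if total <= 0:
        raise NoRingError("empty distribution after high-pass")
    return float(np.arange(w.size) @ w / total)

def _weighted_median_bin(profile: RadialProfile, n_highpass: int) -> float:
    w = profile.values.astype(np.float64).copy()
    w[:n_highpass] = 0.0
    total = w.sum()
    if total <= 0:
        raise NoRingError("empty distribution after high-pass")
    cdf = np.cumsum(w) / total
    return float(np.searchsorted(cdf, 0.5))


def estimate_f_star(
    image: np.ndarray,
    method: str = "modeRMrec",
    n_highpass: int | None = None,
) -> CharacteristicFrequency:
    """Estimate the characteristic frequency f* of a cell-mosaic image.

    Methods
    -------
    ``modeRM``
        Highest parabola-refined peak of the radial mean of |F|.
    ``1stRM``
        First (lowest-frequency) peak of the radial mean.
    ``2ndRMAX``
        Second peak of the radial maximum of |F|.
    ``modePS``
        Highest peak of the radial mean of the power spectrum (no smoothing).
    ``meanPS`` / ``medianPS``
        Weighted mean / median frequency of the radial power profile after
        zeroing its first ``n_highpass`` bins (high-pass filter).
    ``modeRMrec``
        Highest peak of the radial mean after ring enhancement
        (:func:`enhance_ring`); parameter-free.

    Returns the frequency in cycles per pixel of the (square-cropped)
    working frame.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if method in ("meanPS", "medianPS"):
        if n_highpass is None:
            raise ValueError(f"{method} requires n_highpass")
    elif n_highpass is not None:
        raise ValueError(f"n_highpass is only meaningful for meanPS/medianPS")

    spec = spectrum_of(image)
    n = spec.image_size

    if method == "modeRMrec":
        profile = radial_project(enhance_ring(spec), "mean_magnitude")
        pos, height = max(find_peaks(profile), key=lambda p: p[1])
    elif method == "modeRM":
        profile = radial_project(spec, "mean_magnitude")
        pos, height = max(find_peaks(profile), key=lambda p: p[1])
    elif method == "1stRM":
        profile = radial_project(spec, "mean_magnitude")
        pos, height = find_peaks(profile)[0]
    elif method == "2ndRMAX":
        profile = radial_project(spec, "max_magnitude")
        peaks = find_peaks(profile)
        if len(peaks) < 2:
            raise NoRingError("2ndRMAX requires at least two peaks")
        pos, height = peaks[1]
    elif method == "modePS":
        profile = radial_project(spec, "mean_power")
        pos, height = max(find_peaks(profile), key=lambda p: p[1])
    else:  # meanPS / medianPS
        profile = radial_project(spec, "mean_power")
        if method == "meanPS":
            pos = _weighted_mean_bin(profile, n_highpass)
        else:
            pos = _weighted_median_bin(profile, n_highpass)
        height = float(profile.values[int(round(pos))])

    f_star = pos / n
    if not 0.0 < f_star <= 0.5:
        raise NoRingError(f"estimated f*={f_star:.4g} px^-1 outside (0, 1/2]")
    return CharacteristicFrequency(
        f_star=float(f_star),
        bin_index=int(round(pos)),
        method=method if n_highpass is None else f"{method} {n_highpass}",
        peak_value=float(height),
    )
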