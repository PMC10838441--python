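"""Foreground segmentation, ROI spectrum extraction, scaling and augmentation.

The image-processing chain mirrors standard proximal-HSI practice: render an
8-bit RGB from three visible bands, score greenness, binarize with Otsu's
threshold, clean the mask morphologically, keep the largest connected blob,
then average the reflectance of foreground pixels per band.  Downstream
models consume the per-sample min-max scaled mean spectrum (or its first
derivative with respect to wavelength).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label
from skimage.morphology import closing, disk, opening

from .hsi_io import HyperCube, MeanSpectrum, WavelengthGrid

__all__ = [
    "ForegroundMask",
    "AugmentationConfig",
    "synthesize_rgb",
    "otsu_threshold",
    "segment_foreground",
    "mean_roi_spectrum",
    "minmax_scale",
    "first_derivative",
    "augment_spectrum",
]

#: default wavelengths (nm) used to synthesize the R, G, B channels
DEFAULT_RGB_NM = (660.0, 550.0, 470.0)


@dataclass
class ForegroundMask:
    """Binary foreground map plus the structuring-element radius used."""

    mask: np.ndarray
    selem_radius: int = 2

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("foreground mask is empty after cleanup")

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class AugmentationConfig:
    """Offset/slope jitter for spectral augmentation.

    The offset is drawn uniformly within +/- ``offset_factor`` times the
    spectrum's standard deviation; the multiplicative slope factor is drawn
    uniformly from [``slope_low``, ``slope_high``].
    """

    offset_factor: float = 0.10
    slope_low: float = 0.95
    slope_high: float = 1.05

    def __post_init__(self) -> None:
        if self.offset_factor < 0:
            raise ValueError("offset_factor must be >= 0")
        if not (0 < self.slope_low <= self.slope_high):
            raise ValueError("need 0 < slope_low <= slope_high")


def _channel_stretch(band: np.ndarray) -> np.ndarray:
    lo, hi = band.min(), band.max()
    if hi == lo:
        return np.zeros_like(band, dtype=float)
    return (band - lo) / (hi - lo)


def synthesize_rgb(cube: HyperCube, rgb_nm: tuple[float, float, float] = DEFAULT_RGB_NM) -> np.ndarray:
    """8-bit color image from the bands nearest the configured R/G/B wavelengths.

    Each channel is min-max stretched independently to 0-255.
    """
    wl = cube.grid.wavelengths_nm
    if wl[0] > min(rgb_nm) or wl[-1] < max(rgb_nm):
        raise ValueError(
            f"grid [{wl[0]:.0f}, {wl[-1]:.0f}] nm does not cover requested RGB bands {rgb_nm}"
        )
    channels = [
        np.round(255.0 * _channel_stretch(cube.values[..., cube.grid.nearest_band(nm)]))
        for nm in rgb_nm
    ]
    return np.stack(channels, axis=-1).astype(np.uint8)


def otsu_threshold(gray_values) -> float:
    """Threshold maximizing between-class variance over the value histogram.

    The scan is exhaustive over the unique observed values: for each
    candidate t the pixels are split into {v <= t} and {v > t} and the
    between-class variance ``w0 * w1 * (mu0 - mu1)**2`` is maximized.  On
    discrete (e.g. 8-bit) data this is exactly Otsu's method; on continuous
    data it is its natural generalization.  Returns the lowest maximizing
    candidate.  Foreground is conventionally ``values > threshold``.
    """
    values = np.asarray(gray_values, dtype=float).ravel()
    uniq, counts = np.unique(values, return_counts=True)
    if uniq.size < 2:
        raise ValueError("Otsu threshold undefined for constant input")
    # cumulative class statistics for the split {<= t} vs {> t}
    w0 = np.cumsum(counts)[:-1]
    w1 = values.size - w0
    csum = np.cumsum(uniq * counts)[:-1]
    mu0 = csum / w0
    mu1 = (csum[-1] + uniq[-1] * counts[-1] - csum) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(uniq[:-1][int(np.argmax(between))])


def segment_foreground(
    cube: HyperCube,
    selem_radius: int = 2,
    rgb_nm: tuple[float, float, float] = DEFAULT_RGB_NM,
) -> ForegroundMask:
    """Greenness score -> Otsu binarization -> morphology -> largest component.

    Greenness is excess green (2G - R - B) computed on the R/G/B reflectance
    bands after a joint (shared) max-normalization: normalizing the three
    channels together preserves the relative channel magnitudes that the
    excess-green index relies on (an independent per-channel stretch would
    cancel it) while making the segmentation invariant to a global positive
    gain on the cube.  The binary mask is cleaned by morphological opening
    then closing with a disk structuring element, and only the largest
    connected component is kept.
    """
    if cube.kind != "reflectance":
        raise ValueError("segment_foreground expects a calibrated (reflectance) cube")
    wl = cube.grid.wavelengths_nm
    if wl[0] > min(rgb_nm) or wl[-1] < max(rgb_nm):
        raise ValueError(
            f"grid [{wl[0]:.0f}, {wl[-1]:.0f}] nm does not cover requested RGB bands {rgb_nm}"
        )
    r, g, b = (cube.values[..., cube.grid.nearest_band(nm)].astype(float) for nm in rgb_nm)
    peak = max(r.max(), g.max(), b.max())
    if peak <= 0:
        raise ValueError("cube has no positive reflectance in the RGB bands")
    exg = (2.0 * g - r - b) / peak
    t = otsu_threshold(exg)
    mask = exg > t
    selem = disk(selem_radius)
    mask = opening(mask, selem)
    mask = closing(mask, selem)
    if not mask.any():
        raise ValueError("no foreground remains after morphological cleanup")
    labels = label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    return ForegroundMask(mask=labels == largest, selem_radius=selem_radius)


def mean_roi_spectrum(cube: HyperCube, mask: ForegroundMask | np.ndarray) -> MeanSpectrum:
    """Per-band arithmetic mean of the reflectance over foreground pixels only."""
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    if m.shape != cube.values.shape[:2]:
        raise ValueError("mask shape must match the cube's spatial shape")
    if not m.any():
        raise ValueError("mask selects no pixels")
    return MeanSpectrum(cube.values[m].mean(axis=0), cube.grid)


def _values_of(spectrum) -> np.ndarray:
    return spectrum.values if isinstance(spectrum, MeanSpectrum) else np.asarray(spectrum, dtype=float)


def minmax_scale(spectrum):
    """Rescale one spectrum to [0, 1]: ``(x - min) / (max - min)``.

    Applied per sample (each spectrum independently); constant input raises.
    """
    x = _values_of(spectrum)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("min-max scaling undefined for a constant spectrum")
    scaled = (x - lo) / (hi - lo)
    if isinstance(spectrum, MeanSpectrum):
        return MeanSpectrum(scaled, spectrum.grid, scaled=True)
    return scaled


def minmax_scale_dataset(X: np.ndarray, axis: int = 1) -> np.ndarray:
    """Min-max scale a spectra matrix; ``axis=1`` per sample, ``axis=0`` per band."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=axis, keepdims=True)
    hi = X.max(axis=axis, keepdims=True)
    span = hi - lo
    if np.any(span == 0):
        raise ValueError("min-max scaling undefined for a constant row/column")
    return (X - lo) / span


def first_derivative(spectrum, grid: WavelengthGrid | None = None) -> np.ndarray:
    """First derivative of reflectance with respect to wavelength (FDR).

    Central differences at interior bands, one-sided at the ends; the output
    has the same length as the input.
    """
    x = _values_of(spectrum)
    if grid is None:
        if not isinstance(spectrum, MeanSpectrum):
            raise ValueError("bare arrays require an explicit grid")
        grid = spectrum.grid
    wl = grid.wavelengths_nm
    if x.shape[-1] != wl.size:
        raise ValueError(f"spectrum length {x.shape[-1]} does not match grid length {wl.size}")
    if wl.size < 3:
        raise ValueError("first derivative needs at least 3 bands")
    return np.gradient(x, wl, axis=-1)


def augment_spectrum(
    spectrum,
    cfg: AugmentationConfig | None = None,
    seed=0,
    mode: str = "global",
):
    """Offset/slope jitter: ``a * x + b`` with a ~ U(slope_low, slope_high),
    b ~ U(-offset_factor * sd, +offset_factor * sd), sd the spectrum's own
    standard deviation.

    ``mode="global"`` applies one multiplicative factor to the whole
    spectrum (the standard chemometric multiplicative jitter);
    ``mode="tilt"`` instead applies a wavelength-linear slope ramping from 1
    at the first band to ``a`` at the last.
    """
    cfg = cfg or AugmentationConfig()
    x = _values_of(spectrum)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = rng.uniform(cfg.slope_low, cfg.slope_high)
    sd = x.std()
    b = rng.uniform(-cfg.offset_factor * sd, cfg.offset_factor * sd)
    if mode == "global":
        out = a * x + b
    elif mode == "tilt":
        ramp = np.linspace(1.0, a, x.shape[-1])
        out = ramp * x + b
    else:
        raise ValueError(f"unknown augmentation mode {mode!r}")
    if isinstance(spectrum, MeanSpectrum):
        return MeanSpectrum(out, spectrum.grid, scaled=spectrum.scaled)
    return out
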