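"""Chlorophyll-parameterized synthetic lettuce spectra, scenes and datasets.

The forward model is deliberately simple: a smooth baseline with a logistic
red-edge ramp up to an NIR plateau, minus Gaussian absorption dips centred
in the blue (~445 nm) and red (~662 nm) chlorophyll absorption regions,
whose depth grows with the SPAD label.  It is monotone in SPAD at the
absorption centers by construction, which is what the recovery tests need;
it makes no claim to radiative-transfer realism (no PROSPECT-style pigment
physics, no canopy BRDF).

Scenes place a lettuce-shaped bright blob (a union of random ellipses) on a
dark background and wrap the reflectance field into raw DN together with
white/dark reference frames, so the full calibrate -> segment -> extract
pipeline can be exercised end to end with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hsi_io import (
    HyperCube,
    MeanSpectrum,
    ReferenceFrames,
    WavelengthGrid,
    make_wavelength_grid,
)

__all__ = [
    "LeafSpectrumModel",
    "SyntheticScene",
    "LabeledDataset",
    "default_grid",
    "generate_spectrum",
    "generate_cube",
    "generate_dataset",
]

#: camera wavelength range and band count emulated by default
DEFAULT_RANGE_NM = (387.0, 1003.0)
DEFAULT_N_BANDS = 231

#: typical SPAD-502 readings for lettuce leaves
DEFAULT_SPAD_RANGE = (15.0, 50.0)

#: default dataset size (number of imaged plants in the emulated campaign)
DEFAULT_N_SAMPLES = 478


def default_grid() -> WavelengthGrid:
    """The 231-band grid spanning 387-1003 nm."""
    return make_wavelength_grid(*DEFAULT_RANGE_NM, DEFAULT_N_BANDS)


@dataclass(frozen=True)
class LeafSpectrumModel:
    """Forward model mapping a SPAD value to a leaf reflectance spectrum.

    Parameters
    ----------
    visible_reflectance, nir_reflectance
        Pigment-free baseline levels below and above the red edge.
    absorption_centers_nm, absorption_widths_nm, center_strengths
        Gaussian dip positions (blue and red chlorophyll absorption bands),
        their widths, and relative depths.
    depth_per_spad
        Absorption depth added per SPAD unit (reflectance units per SPAD).
    saturation_spad
        If set, depth saturates as ``d * s * (1 - exp(-spad/s))``; the
        default is the linear map, which keeps the label identifiable.
    red_edge_nm, red_edge_width_nm
        Center and scale of the logistic visible-to-NIR transition.
    noise_sd
        Additive Gaussian noise standard deviation (reflectance units),
        applied per band (and per pixel in scenes).
    """

    visible_reflectance: float = 0.50
    nir_reflectance: float = 0.62
    absorption_centers_nm: tuple[float, ...] = (445.0, 662.0)
    absorption_widths_nm: tuple[float, ...] = (30.0, 24.0)
    center_strengths: tuple[float, ...] = (0.65, 1.0)
    depth_per_spad: float = 0.0075
    saturation_spad: float | None = None
    red_edge_nm: float = 712.0
    red_edge_width_nm: float = 16.0
    noise_sd: float = 0.004

    def baseline_reflectance(self, grid: WavelengthGrid) -> np.ndarray:
        wl = grid.wavelengths_nm
        ramp = 1.0 / (1.0 + np.exp(-(wl - self.red_edge_nm) / self.red_edge_width_nm))
        return self.visible_reflectance + (self.nir_reflectance - self.visible_reflectance) * ramp

    def absorption_profile(self, grid: WavelengthGrid) -> np.ndarray:
        """Unit-depth dip shape (max value 1 at the strongest center)."""
        wl = grid.wavelengths_nm
        profile = np.zeros_like(wl)
        for c, w, s in zip(
            self.absorption_centers_nm, self.absorption_widths_nm, self.center_strengths
        ):
            profile += s * np.exp(-0.5 * ((wl - c) / w) ** 2)
        return profile

    def absorption_depth(self, spad: float) -> float:
        if self.saturation_spad is None:
            return self.depth_per_spad * spad
        s = self.saturation_spad
        return self.depth_per_spad * s * (1.0 - np.exp(-spad / s))

    def reflectance(self, spad: float, grid: WavelengthGrid) -> np.ndarray:
        """Noise-free spectrum for one SPAD value, clipped to [0, 1]."""
        r = self.baseline_reflectance(grid) - self.absorption_depth(spad) * self.absorption_profile(grid)
        return np.clip(r, 0.0, 1.0)

    def informative_window_nm(self) -> tuple[float, float]:
        """A window around the red absorption center where the label acts."""
        c = self.absorption_centers_nm[-1]
        w = self.absorption_widths_nm[-1]
        return (c - 1.5 * w, c + 1.5 * w)


@dataclass
class SyntheticScene:
    """A raw-DN hypercube with its references and ground truth."""

    cube: HyperCube
    white_ref: np.ndarray
    dark_ref: np.ndarray
    truth_mask: np.ndarray
    spad_value: float

    def __post_init__(self) -> None:
        if self.truth_mask.shape != self.cube.values.shape[:2]:
            raise ValueError("truth_mask spatial shape must match the cube")
        if not np.all(self.dark_ref < self.white_ref):
            raise ValueError("dark reference must be below white reference everywhere")

    @property
    def references(self) -> ReferenceFrames:
        return ReferenceFrames(white=self.white_ref, dark=self.dark_ref)


@dataclass
class LabeledDataset:
    """Mean spectra paired with SPAD labels (and optional fold assignment)."""

    X: np.ndarray  # (n_samples, n_bands)
    y: np.ndarray  # (n_samples,) SPAD
    grid: WavelengthGrid
    folds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X rows must align with y labels")
        if self.X.shape[1] != len(self.grid):
            raise ValueError("X columns must match the wavelength grid")

    def __len__(self) -> int:
        return int(self.y.size)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_spectrum(
    spad: float,
    grid: WavelengthGrid | None = None,
    model: LeafSpectrumModel | None = None,
    seed=0,
) -> MeanSpectrum:
    """One noisy leaf spectrum for a given SPAD value.

    Deterministic given ``seed``; with ``model.noise_sd == 0`` the output is
    an exact function of ``spad``.
    """
    if spad < 0:
        raise ValueError(f"SPAD must be non-negative; got {spad}")
    grid = grid or default_grid()
    model = model or LeafSpectrumModel()
    rng = _rng(seed)
    values = model.reflectance(spad, grid)
    if model.noise_sd > 0:
        values = values + rng.normal(0.0, model.noise_sd, size=values.shape)
    return MeanSpectrum(np.clip(values, 0.0, 1.0), grid)


def _ellipse_union_mask(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Lettuce-blob foreground: union of a few overlapping ellipses."""
    yy, xx = np.mgrid[0:height, 0:width]
    mask = np.zeros((height, width), dtype=bool)
    cy0, cx0 = height / 2, width / 2
    for _ in range(3):
        cy = cy0 + rng.uniform(-0.08, 0.08) * height
        cx = cx0 + rng.uniform(-0.08, 0.08) * width
        ay = rng.uniform(0.18, 0.30) * height
        ax = rng.uniform(0.18, 0.30) * width
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask |= (u / ay) ** 2 + (v / ax) ** 2 <= 1.0
    if not mask.any():  # degenerate tiny frame: force a center pixel
        mask[height // 2, width // 2] = True
    return mask


#: background reflectance of the dark imaging platform
_BACKGROUND_REFLECTANCE = 0.01
#: dark-current DN level and white-panel DN amplitude
_DARK_DN = 100.0
_WHITE_DN_AMPLITUDE = 3000.0


def generate_cube(
    spad: float,
    height: int = 64,
    width: int = 64,
    grid: WavelengthGrid | None = None,
    model: LeafSpectrumModel | None = None,
    seed=0,
) -> SyntheticScene:
    """A raw-DN scene: bright lettuce blob on a dark background, plus refs.

    Foreground pixels carry the model spectrum with independent per-pixel
    noise of standard deviation ``model.noise_sd``; the background sits near
    the dark level (reflectance ~0.01).  The white reference carries a
    smooth band-dependent lamp profile; references are noise-free so the
    scene calibrates exactly back to its reflectance field.
    """
    if height < 8 or width < 8:
        raise ValueError(f"scene must be at least 8 x 8 pixels; got {height} x {width}")
    if spad < 0:
        raise ValueError(f"SPAD must be non-negative; got {spad}")
    grid = grid or default_grid()
    model = model or LeafSpectrumModel()
    rng = _rng(seed)
    n_bands = len(grid)

    mask = _ellipse_union_mask(height, width, rng)
    truth = model.reflectance(spad, grid)

    refl = np.full((height, width, n_bands), _BACKGROUND_REFLECTANCE)
    refl[mask] = truth
    if model.noise_sd > 0:
        refl = refl + rng.normal(0.0, model.noise_sd, size=refl.shape)
    refl = np.clip(refl, 0.0, 1.5)

    # smooth halogen-lamp spectral profile for the white panel
    wl = grid.wavelengths_nm
    lamp = 0.6 + 0.4 * np.sin(np.pi * (wl - wl[0]) / (wl[-1] - wl[0]))
    white = np.broadcast_to(_DARK_DN + _WHITE_DN_AMPLITUDE * lamp, (height, width, n_bands)).copy()
    dark = np.full((height, width, n_bands), _DARK_DN)

    dn = dark + refl * (white - dark)
    cube = HyperCube(dn, grid, kind="raw_dn")
    return SyntheticScene(
        cube=cube, white_ref=white, dark_ref=dark, truth_mask=mask, spad_value=float(spad)
    )


def generate_dataset(
    n: int = DEFAULT_N_SAMPLES,
    seed=0,
    spad_range: tuple[float, float] = DEFAULT_SPAD_RANGE,
    grid: WavelengthGrid | None = None,
    model: LeafSpectrumModel | None = None,
    k_folds: int = 5,
) -> LabeledDataset:
    """``n`` labeled mean spectra with SPAD labels uniform over ``spad_range``."""
    if n < k_folds:
        raise ValueError(f"need at least {k_folds} samples for {k_folds}-fold CV; got {n}")
    lo, hi = spad_range
    if not (0 <= lo < hi):
        raise ValueError(f"spad_range must be a positive interval; got {spad_range}")
    grid = grid or default_grid()
    model = model or LeafSpectrumModel()
    rng = _rng(seed)
    y = rng.uniform(lo, hi, size=n)
    X = np.empty((n, len(grid)))
    for i, spad in enumerate(y):
        X[i] = generate_spectrum(spad, grid, model, seed=rng).values
    return LabeledDataset(X=X, y=y, grid=grid)
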