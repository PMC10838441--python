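"""Hypercube containers, radiometric calibration, band trimming and ENVI I/O.

A line-scan Vis-NIR camera records a hypercube of raw digital numbers (DN)
with shape ``height x width x bands``.  Raw DN are converted to reflectance
with white/dark reference frames::

    reflectance = (I_raw - I_dark) / (I_white - I_dark)

Reflectance is deliberately *not* clipped to [0, 1] here: sensor noise can
push individual pixels slightly past the white reference, and clipping is a
preprocessing decision, not a calibration one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "HyperCube",
    "ReferenceFrames",
    "MeanSpectrum",
    "make_wavelength_grid",
    "calibrate_reflectance",
    "trim_to_range",
    "read_cube",
    "write_cube",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid needs at least 2 band centers")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        wl = wl.copy()
        wl.flags.writeable = False
        object.__setattr__(self, "wavelengths_nm", wl)

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.wavelengths_nm, other.wavelengths_nm)

    def nearest_band(self, nm: float) -> int:
        """Index of the band center closest to ``nm``."""
        return int(np.argmin(np.abs(self.wavelengths_nm - nm)))


@dataclass
class HyperCube:
    """``height x width x bands`` array of raw DN or reflectance values.

    ``kind`` is ``"raw_dn"`` or ``"reflectance"``.
    """

    values: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw_dn"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"cube must be 3-D (h, w, bands); got shape {self.values.shape}")
        if self.values.shape[2] != len(self.grid):
            raise ValueError(
                f"bands dimension {self.values.shape[2]} does not match "
                f"grid length {len(self.grid)}"
            )
        if self.kind not in ("raw_dn", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")
        if self.kind == "reflectance" and not np.all(np.isfinite(self.values)):
            raise ValueError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class ReferenceFrames:
    """White and dark reference frames.

    Each frame is either full-frame ``(h, w, bands)`` or a line reference
    ``(1, w, bands)`` (line-scan hardware records one reference line per
    spatial column); line references broadcast along the scan axis.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        for name, frame in (("white", self.white), ("dark", self.dark)):
            if frame.ndim != 3:
                raise ValueError(f"{name} reference must be 3-D; got shape {frame.shape}")


@dataclass
class MeanSpectrum:
    """Per-band ROI-averaged reflectance, optionally min-max scaled to [0, 1]."""

    values: np.ndarray
    grid: WavelengthGrid
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.grid):
            raise ValueError(
                f"spectrum length {self.values.size} does not match grid length {len(self.grid)}"
            )

    def __len__(self) -> int:
        return int(self.values.size)


def make_wavelength_grid(start_nm: float, stop_nm: float, n_bands: int) -> WavelengthGrid:
    """Equally spaced band centers, endpoints inclusive.

    The default camera configuration is 231 bands spanning 387-1003 nm.
    """
    if stop_nm <= start_nm:
        raise ValueError(f"need start < stop; got [{start_nm}, {stop_nm}]")
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    return WavelengthGrid(np.linspace(start_nm, stop_nm, n_bands))


def calibrate_reflectance(raw: HyperCube, refs: ReferenceFrames) -> HyperCube:
    """Convert raw DN to reflectance: ``(I_raw - I_d) / (I_w - I_d)``.

    Raises if the white-dark denominator vanishes anywhere, naming the first
    offending band and pixel.  No clipping is applied.
    """
    if raw.kind != "raw_dn":
        raise ValueError("cube is already calibrated (kind != 'raw_dn')")
    white = np.broadcast_to(refs.white, raw.values.shape)
    dark = np.broadcast_to(refs.dark, raw.values.shape)
    denom = white - dark
    bad = denom == 0
    if np.any(bad):
        h, w, b = np.argwhere(bad)[0]
        raise ZeroDivisionError(
            f"white - dark is zero at pixel ({h}, {w}), band index {b} "
            f"({raw.grid.wavelengths_nm[b]:.1f} nm)"
        )
    refl = (raw.values.astype(float) - dark) / denom
    return HyperCube(refl, raw.grid, kind="reflectance")


def trim_to_range(cube_or_spectrum, grid=None, lo_nm: float = None, hi_nm: float = None):
    """Keep the bands with ``lo_nm <= wavelength <= hi_nm`` (closed interval).

    Accepts a :class:`HyperCube`, a :class:`MeanSpectrum`, or a bare array
    whose last axis is bands together with its grid.  Returns the trimmed
    object of the same type; for bare arrays, a ``(values, grid)`` pair.

    The closed interval matters: the inclusive 231-point grid over
    387-1003 nm trimmed to [437, 919] nm keeps exactly 180 bands.
    """
    if isinstance(cube_or_spectrum, (HyperCube, MeanSpectrum)):
        if hi_nm is None and grid is not None and lo_nm is not None:
            # trim_to_range(cube, lo, hi) call shape: grid slot holds lo
            grid, lo_nm, hi_nm = None, float(grid), float(lo_nm)
        obj_grid = cube_or_spectrum.grid
        values = cube_or_spectrum.values
    else:
        if grid is None:
            raise ValueError("bare arrays require an explicit grid")
        obj_grid = grid
        values = np.asarray(cube_or_spectrum)
    if lo_nm is None or hi_nm is None:
        raise ValueError("lo_nm and hi_nm are required")
    if hi_nm < lo_nm:
        raise ValueError(f"need lo <= hi; got [{lo_nm}, {hi_nm}]")
    wl = obj_grid.wavelengths_nm
    keep = (wl >= lo_nm) & (wl <= hi_nm)
    if not np.any(keep):
        raise ValueError(f"no bands inside [{lo_nm}, {hi_nm}] nm")
    if keep.sum() < 2:
        # single-band selections cannot form a WavelengthGrid; return values + raw wavelengths
        new_wl = wl[keep]
        return values[..., keep], new_wl
    new_grid = WavelengthGrid(wl[keep])
    if isinstance(cube_or_spectrum, HyperCube):
        return HyperCube(values[..., keep], new_grid, kind=cube_or_spectrum.kind)
    if isinstance(cube_or_spectrum, MeanSpectrum):
        return MeanSpectrum(values[keep], new_grid, scaled=cube_or_spectrum.scaled)
    return values[..., keep], new_grid


# --- ENVI header + binary I/O ---------------------------------------------

_DTYPE_TO_ENVI = {
    np.dtype("uint8"): 1,
    np.dtype("int16"): 2,
    np.dtype("int32"): 3,
    np.dtype("float32"): 4,
    np.dtype("float64"): 5,
    np.dtype("uint16"): 12,
}
_ENVI_TO_DTYPE = {v: k for k, v in _DTYPE_TO_ENVI.items()}

_REQUIRED_KEYS = ("samples", "lines", "bands", "interleave", "data type", "wavelength")


def write_cube(cube: HyperCube, path, interleave: str = "bsq") -> None:
    """Write an ENVI header (.hdr) plus raw binary (.img) pair.

    ``path`` is the basename; ``path.hdr`` and ``path.img`` are created.
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    path = Path(path)
    values = cube.values
    dtype = values.dtype if values.dtype in _DTYPE_TO_ENVI else np.dtype("float64")
    values = values.astype(dtype, copy=False)
    h, w, b = values.shape
    if interleave == "bsq":
        ordered = values.transpose(2, 0, 1)  # bands, lines, samples
    elif interleave == "bil":
        ordered = values.transpose(0, 2, 1)  # lines, bands, samples
    else:
        ordered = values  # lines, samples, bands
    wl = ", ".join(f"{x:.6f}" for x in cube.grid.wavelengths_nm)
    header = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_TO_ENVI[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"cube kind = {cube.kind}\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(".hdr").write_text(header)
    ordered.tofile(path.with_suffix(".img"))


def _parse_envi_header(text: str) -> dict:
    # collapse { ... } blocks (may span lines) before splitting on key = value
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def read_cube(path) -> HyperCube:
    """Read an ENVI header/binary pair written by :func:`write_cube`.

    Raises ``KeyError`` naming any missing required header field.
    """
    path = Path(path)
    hdr = _parse_envi_header(path.with_suffix(".hdr").read_text())
    for key in _REQUIRED_KEYS:
        if key not in hdr:
            raise KeyError(f"ENVI header missing required field {key!r}")
    w = int(hdr["samples"])
    h = int(hdr["lines"])
    b = int(hdr["bands"])
    interleave = hdr["interleave"].lower()
    dtype = _ENVI_TO_DTYPE[int(hdr["data type"])]
    raw = np.fromfile(path.with_suffix(".img"), dtype=dtype)
    if raw.size != h * w * b:
        raise ValueError(f"binary size {raw.size} does not match header {h}x{w}x{b}")
    if interleave == "bsq":
        values = raw.reshape(b, h, w).transpose(1, 2, 0)
    elif interleave == "bil":
        values = raw.reshape(h, b, w).transpose(0, 2, 1)
    elif interleave == "bip":
        values = raw.reshape(h, w, b)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    wl_text = hdr["wavelength"].strip().strip("{}")
    wavelengths = np.array([float(x) for x in wl_text.split(",") if x.strip()])
    kind = hdr.get("cube kind", "raw_dn")
    return HyperCube(values.copy(), WavelengthGrid(wavelengths), kind=kind)
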