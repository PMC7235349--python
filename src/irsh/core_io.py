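"""Core data model and file I/O for hyperspectral absorbance images.

The central object is :class:`SpectralImage`: a ``rows x cols x n_wavenumbers``
absorbance cube on a strictly monotonic wavenumber axis (cm^-1), with a boolean
tissue mask and free-form string metadata.  Images are stored in a small HDF5
container (datasets ``/axis``, ``/cube``, ``/mask``; attributes
``pixel_size_um``; string attributes under ``/meta``).  Reference spectra
travel as two-column delimited text; segmentation label maps render to 8-bit
RGB PNG.

By convention cubes are stored with a descending axis (4000 -> 750 cm^-1, the
usual FTIR presentation), but every operation accepts either orientation and
preserves it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
from PIL import Image

from .errors import FormatError, ParseError, SpectralRangeError

__all__ = [
    "WavenumberAxis",
    "Spectrum",
    "SpectralImage",
    "LabelMap",
    "load_image",
    "save_image",
    "read_spectrum_table",
    "crop_spectral_range",
    "resample_to_axis",
    "render_label_map",
]


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly monotonic wavenumber grid in cm^-1 (ascending or descending)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1 or v.size < 2:
            raise FormatError("axis must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(v)):
            raise FormatError("axis contains non-finite values")
        if np.any(v <= 0):
            raise FormatError("wavenumbers must be positive")
        d = np.diff(v)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise FormatError("axis must be strictly monotonic")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def orientation(self) -> str:
        return "ascending" if self.values[1] > self.values[0] else "descending"

    @property
    def lo(self) -> float:
        return float(self.values.min())

    @property
    def hi(self) -> float:
        return float(self.values.max())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberAxis):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __len__(self) -> int:
        return self.n


@dataclass
class Spectrum:
    """A single absorbance spectrum (AU) on a :class:`WavenumberAxis`."""

    axis: WavenumberAxis
    absorbance: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=np.float64)
        if a.ndim != 1 or a.size != self.axis.n:
            raise FormatError(
                f"absorbance length {a.size} != axis length {self.axis.n}"
            )
        if not np.all(np.isfinite(a)):
            raise FormatError("absorbance contains non-finite values")
        self.absorbance = a


@dataclass
class SpectralImage:
    """Hyperspectral absorbance cube with tissue mask and metadata.

    ``cube`` has shape ``(rows, cols, n)`` with ``n == len(axis)``; ``mask`` is
    boolean ``(rows, cols)`` with True marking tissue pixels.
    """

    axis: WavenumberAxis
    cube: np.ndarray
    pixel_size_um: float = 6.25
    mask: np.ndarray | None = None
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cube = np.asarray(self.cube, dtype=np.float64)
        if cube.ndim != 3:
            raise FormatError("cube must be rows x cols x n_wavenumbers")
        if cube.shape[2] != self.axis.n:
            raise FormatError(
                f"cube has {cube.shape[2]} channels but axis has {self.axis.n}"
            )
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")
        if self.mask is None:
            mask = np.ones(cube.shape[:2], dtype=bool)
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != cube.shape[:2]:
                raise FormatError(
                    f"mask shape {mask.shape} != image shape {cube.shape[:2]}"
                )
        self.cube = cube
        self.mask = mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    def pixel(self, row: int, col: int, name: str = "") -> Spectrum:
        return Spectrum(self.axis, self.cube[row, col], name=name)


@dataclass
class LabelMap:
    """Integer segmentation map: -1 = background, 0..k-1 = cluster ids."""

    labels: np.ndarray
    k: int
    color_table: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.ndim != 2:
            raise FormatError("labels must be a 2-D array")
        if self.k < 1:
            raise FormatError("k must be positive")
        if labels.min(initial=0) < -1 or labels.max(initial=-1) >= self.k:
            raise FormatError("labels must lie in {-1, 0..k-1}")
        if len(self.color_table) != self.k:
            raise FormatError(
                f"color_table has {len(self.color_table)} entries for k={self.k}"
            )
        self.labels = labels
        self.color_table = [tuple(int(c) for c in rgb) for rgb in self.color_table]

    @property
    def tissue_count(self) -> int:
        return int(np.count_nonzero(self.labels >= 0))


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def save_image(img: SpectralImage, path: str | Path, overwrite: bool = False) -> None:
    """Write ``img`` to the HDF5 container; refuses to clobber unless asked."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as f:
        f.create_dataset("axis", data=img.axis.values)
        f.create_dataset("cube", data=img.cube)
        f.create_dataset("mask", data=img.mask.astype(np.uint8))
        f.attrs["pixel_size_um"] = float(img.pixel_size_um)
        meta = f.create_group("meta")
        for key, value in img.meta.items():
            meta.attrs[str(key)] = str(value)


def load_image(path: str | Path) -> SpectralImage:
    """Read a :class:`SpectralImage` back from the HDF5 container."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in ("axis", "cube", "mask"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset '/{name}'")
        axis = WavenumberAxis(f["axis"][()])
        cube = f["cube"][()]
        mask = f["mask"][()].astype(bool)
        pixel_size = float(f.attrs.get("pixel_size_um", 6.25))
        meta: dict[str, str] = {}
        if "meta" in f:
            meta = {k: str(v) for k, v in f["meta"].attrs.items()}
    return SpectralImage(axis, cube, pixel_size_um=pixel_size, mask=mask, meta=meta)


# ---------------------------------------------------------------------------
# Reference-spectrum tables
# ---------------------------------------------------------------------------

_SPLIT = re.compile(r"[,\s]+")


def read_spectrum_table(path: str | Path) -> Spectrum:
    """Parse a two-column (wavenumber, absorbance) text file.

    Comma or whitespace delimited; lines starting with ``#`` are comments.  If
    the rows are not monotonic they are sorted ascending, keeping each
    (wavenumber, absorbance) pair intact; already-descending files keep their
    descending orientation.
    """
    path = Path(path)
    wn: list[float] = []
    ab: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p for p in _SPLIT.split(line) if p]
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                w, a = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell") from exc
            if w in wn:
                raise ParseError(
                    f"{path}:{lineno}: duplicate wavenumber {w:g}"
                )
            wn.append(w)
            ab.append(a)
    if len(wn) < 2:
        raise ParseError(f"{path}: fewer than 2 data rows")
    w_arr = np.array(wn)
    a_arr = np.array(ab)
    d = np.diff(w_arr)
    if not (np.all(d > 0) or np.all(d < 0)):
        order = np.argsort(w_arr)
        w_arr, a_arr = w_arr[order], a_arr[order]
    return Spectrum(WavenumberAxis(w_arr), a_arr, name=path.stem)


# ---------------------------------------------------------------------------
# Spectral-range operations
# ---------------------------------------------------------------------------

def crop_spectral_range(obj: Spectrum | SpectralImage, lo_cm1: float, hi_cm1: float):
    """Keep exactly the channels with ``lo <= nu <= hi`` (closed interval)."""
    if not lo_cm1 < hi_cm1:
        raise SpectralRangeError(f"need lo < hi, got [{lo_cm1}, {hi_cm1}]")
    keep = (obj.axis.values >= lo_cm1) & (obj.axis.values <= hi_cm1)
    n_keep = int(keep.sum())
    if n_keep == 0:
        raise SpectralRangeError(
            f"no channel in [{lo_cm1}, {hi_cm1}] on axis "
            f"[{obj.axis.lo}, {obj.axis.hi}]"
        )
    if n_keep < 2:
        raise SpectralRangeError(
            f"range [{lo_cm1}, {hi_cm1}] keeps a single channel; need >= 2"
        )
    axis = WavenumberAxis(obj.axis.values[keep])
    if isinstance(obj, Spectrum):
        return Spectrum(axis, obj.absorbance[keep], name=obj.name)
    return SpectralImage(
        axis,
        obj.cube[:, :, keep],
        pixel_size_um=obj.pixel_size_um,
        mask=obj.mask.copy(),
        meta=dict(obj.meta),
    )


def resample_to_axis(spec: Spectrum, target: WavenumberAxis) -> Spectrum:
    """Piecewise-linear resampling of ``spec`` onto ``target`` (no extrapolation)."""
    if target.lo < spec.axis.lo or target.hi > spec.axis.hi:
        raise SpectralRangeError(
            f"target range [{target.lo}, {target.hi}] extends beyond the "
            f"spectrum range [{spec.axis.lo}, {spec.axis.hi}]"
        )
    if target == spec.axis:
        return Spectrum(target, spec.absorbance.copy(), name=spec.name)
    x = spec.axis.values
    y = spec.absorbance
    if x[0] > x[-1]:  # np.interp wants ascending abscissae
        x, y = x[::-1], y[::-1]
    values = np.interp(target.values, x, y)
    return Spectrum(target, values, name=spec.name)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_label_map(lm: LabelMap, path: str | Path) -> None:
    """Write a false-color PNG: background (-1) black, label j -> color_table[j]."""
    rgb = np.zeros(lm.labels.shape + (3,), dtype=np.uint8)
    for j, color in enumerate(lm.color_table):
        rgb[lm.labels == j] = color
    Image.fromarray(rgb, mode="RGB").save(Path(path), format="PNG")


def distinct_colors(k: int) -> list[tuple[int, int, int]]:
    """Deterministic palette of ``k`` well-separated RGB colors (golden-angle hues)."""
    import colorsys

    colors = []
    for i in range(k):
        h = (i * 0.6180339887498949) % 1.0
        r, g, b = colorsys.hsv_to_rgb(h, 0.85, 0.95 if i % 2 == 0 else 0.70)
        colors.append((int(round(r * 255)), int(round(g * 255)), int(round(b * 255))))
    if len(set(colors)) != k:  # pragma: no cover - palette collision guard
        raise ValueError(f"palette collision at k={k}")
    return colors
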