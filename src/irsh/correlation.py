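"""Pixel-by-pixel Pearson correlation with a reference spectrum.

Used to map the type I collagen signature across a tissue section: every
pixel spectrum is correlated with the collagen reference over a chosen
wavenumber window and the coefficient is rendered on the conventional 0
(dark) to 1 (white) scale.  Negative correlations are kept in ``r_raw`` but
clipped to 0 for display.  The correlation can be computed against the raw
(paraffin-containing) image with a paraffin-containing reference, or against
the dewaxed image with the clean reference; the mode is recorded on the map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .core_io import SpectralImage, Spectrum, crop_spectral_range, resample_to_axis
from .errors import ConstantSpectrumError, DataError

__all__ = ["CorrelationMap", "pearson", "correlate_image", "render_correlation"]


@dataclass
class CorrelationMap:
    """Per-pixel correlation with a reference; NaN marks masked/undefined pixels."""

    r_raw: np.ndarray
    r_display: np.ndarray
    range_cm1: tuple[float, float]
    mode: str = "raw"

    def __post_init__(self) -> None:
        finite = np.isfinite(self.r_raw)
        if np.any(np.abs(self.r_raw[finite]) > 1.0 + 1e-12):
            raise DataError("correlation values outside [-1, 1]")
        expected = np.clip(self.r_raw, 0.0, 1.0)
        if not np.allclose(
            self.r_display[finite], expected[finite], rtol=0, atol=1e-12
        ):
            raise DataError("r_display must equal max(r_raw, 0)")


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or x.shape != y.shape:
        raise DataError("pearson needs two equal-length vectors")
    if x.size < 2:
        raise DataError("pearson needs length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(np.sqrt(np.sum(xc * xc)))
    ny = float(np.sqrt(np.sum(yc * yc)))
    if nx == 0.0 or ny == 0.0:
        raise ConstantSpectrumError("correlation undefined for a constant vector")
    r = float(np.dot(xc, yc) / (nx * ny))
    return min(1.0, max(-1.0, r))


def correlate_image(
    img: SpectralImage,
    ref: Spectrum,
    lo_cm1: float | None = None,
    hi_cm1: float | None = None,
    mode: str = "raw",
) -> CorrelationMap:
    """Pearson correlation of every unmasked pixel with ``ref``.

    Both image and reference are cropped to ``[lo, hi]`` (defaults: the full
    image axis) and the reference is linearly resampled onto the image grid.
    Constant pixels are recorded as NaN alongside masked ones.
    """
    lo = img.axis.lo if lo_cm1 is None else float(lo_cm1)
    hi = img.axis.hi if hi_cm1 is None else float(hi_cm1)
    sub = crop_spectral_range(img, lo, hi)
    ref_rs = resample_to_axis(
        crop_spectral_range(ref, lo, hi) if (ref.axis.lo < lo or ref.axis.hi > hi) else ref,
        sub.axis,
    )
    y = ref_rs.absorbance
    yc = y - y.mean()
    ny = float(np.sqrt(np.sum(yc * yc)))
    if ny == 0.0:
        raise ConstantSpectrumError("reference spectrum is constant on this range")

    r_raw = np.full(sub.shape, np.nan)
    pixels = sub.cube[sub.mask]
    if pixels.size:
        xc = pixels - pixels.mean(axis=1, keepdims=True)
        nx = np.sqrt(np.sum(xc * xc, axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc @ yc) / (nx * ny)
        r[nx == 0.0] = np.nan
        r_raw[sub.mask] = np.clip(r, -1.0, 1.0)
    return CorrelationMap(
        r_raw=r_raw,
        r_display=np.clip(r_raw, 0.0, 1.0),
        range_cm1=(lo, hi),
        mode=mode,
    )


def render_correlation(cmap: CorrelationMap, path: str | Path) -> None:
    """Grayscale PNG: value = round(255 * r_display); masked pixels black."""
    vals = np.where(np.isfinite(cmap.r_display), cmap.r_display, 0.0)
    gray = np.round(255.0 * vals).astype(np.uint8)
    Image.fromarray(gray, mode="L").save(Path(path), format="PNG")
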