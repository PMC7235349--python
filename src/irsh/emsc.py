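"""Extended multiplicative signal correction (EMSC) digital dewaxing.

Each pixel spectrum ``s`` is decomposed by ordinary least squares as

    s  ~=  c * m  +  sum_i b_i * p_i  +  sum_j d_j * x^j

with ``m`` a reference tissue spectrum (the EMSC target), ``p_i`` paraffin
interference components (mean paraffin spectrum plus principal-component
loadings of a pure-paraffin calibration image), and powers of the wavenumber
axis rescaled to [-1, 1] as a smooth baseline.  The corrected spectrum

    (s - sum b_i p_i - sum d_j x^j) / c

removes the paraffin contribution and baseline and rescales away section
thickness; the least-squares residual, which carries the tissue-specific
deviation from the target, is retained.  Pixels whose fitted scale ``|c|``
falls below a threshold (background, pure paraffin) are masked out instead of
corrected.

The solver is QR-based; rank-deficient designs raise a
:class:`~irsh.errors.CollinearityError` naming the offending columns rather
than falling back to a pseudo-inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .core_io import SpectralImage, Spectrum, WavenumberAxis, crop_spectral_range, resample_to_axis
from .errors import CollinearityError, DataError, DegeneratePixelError, RankError, SpectralRangeError

__all__ = [
    "EMSCBasis",
    "EMSCFit",
    "EMSCMaps",
    "MaskRule",
    "build_paraffin_basis",
    "fit_emsc",
    "correct_spectrum",
    "dewax_image",
    "choose_target",
]

_RANK_RTOL = 1e-10


@dataclass
class MaskRule:
    """Pixel rejection rule applied after the EMSC fit."""

    c_min: float = 0.2
    residual_max: float | None = None

    def __post_init__(self) -> None:
        if self.c_min <= 0:
            raise ValueError("c_min must be positive")


@dataclass
class EMSCBasis:
    """Target + interference + polynomial design shared by all pixels."""

    target: Spectrum
    interference: list[Spectrum]
    poly_order: int
    axis: WavenumberAxis = field(init=False)

    def __post_init__(self) -> None:
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        self.axis = self.target.axis
        for s in self.interference:
            if s.axis != self.axis:
                raise SpectralRangeError(
                    f"interference spectrum '{s.name}' is not on the target axis"
                )
        self._check_rank()

    @property
    def column_names(self) -> list[str]:
        names = ["target"]
        names += [s.name or f"interference_{i}" for i, s in enumerate(self.interference)]
        names += [f"poly{j}" for j in range(self.poly_order + 1)]
        return names

    def design_matrix(self) -> np.ndarray:
        """Columns: [m | p_1..p_q | x^0..x^order] with x scaled to [-1, 1]."""
        nu = self.axis.values
        x = 2.0 * (nu - nu.min()) / (nu.max() - nu.min()) - 1.0
        cols = [self.target.absorbance]
        cols += [s.absorbance for s in self.interference]
        cols += [x**j for j in range(self.poly_order + 1)]
        return np.column_stack(cols)

    def _check_rank(self) -> None:
        X = self.design_matrix()
        if X.shape[0] < X.shape[1]:
            raise CollinearityError(
                f"design has {X.shape[1]} columns but only {X.shape[0]} channels"
            )
        _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * _RANK_RTOL * max(X.shape)
        bad = diag <= tol
        if bad.any():
            names = self.column_names
            culprits = sorted(names[piv[i]] for i in np.nonzero(bad)[0])
            raise CollinearityError(
                f"EMSC design matrix is rank deficient; culprit columns: {culprits}"
            )


@dataclass
class EMSCFit:
    """Per-spectrum EMSC coefficients."""

    c: float
    b: np.ndarray
    d: np.ndarray
    residual_rms: float


@dataclass
class EMSCMaps:
    """Per-pixel coefficient maps returned by :func:`dewax_image`."""

    c: np.ndarray
    b: np.ndarray  # rows x cols x n_interference
    d: np.ndarray  # rows x cols x (poly_order + 1)
    residual_rms: np.ndarray


def build_paraffin_basis(
    paraffin_img: SpectralImage,
    n_components: int,
    poly_order: int,
    target: Spectrum,
) -> EMSCBasis:
    """Basis with interference = mean paraffin spectrum + its first PCs.

    The principal-component loadings of the mean-centered paraffin pixel
    spectra are ordered by decreasing explained variance; each loading is
    sign-fixed so its largest-magnitude element is positive.
    """
    if n_components < 0:
        raise ValueError("n_components must be >= 0")
    if target.axis != paraffin_img.axis:
        target = resample_to_axis(target, paraffin_img.axis)
    pixels = paraffin_img.cube[paraffin_img.mask]
    n_pix = pixels.shape[0]
    if n_pix == 0:
        raise DataError("paraffin image has no unmasked pixels")
    if n_components >= n_pix:
        raise RankError(
            f"requested {n_components} components from {n_pix} paraffin pixels"
        )
    mean = pixels.mean(axis=0)
    interference = [Spectrum(paraffin_img.axis, mean, name="paraffin_mean")]
    if n_components > 0:
        centered = pixels - mean
        _, svals, vt = np.linalg.svd(centered, full_matrices=False)
        n_usable = int(np.sum(svals > svals[0] * 1e-9)) if svals[0] > 0 else 0
        if n_components > n_usable:
            raise RankError(
                f"paraffin image supports only {n_usable} components "
                f"({n_components} requested): insufficient spectral variance"
            )
        for i in range(n_components):
            loading = vt[i]
            if loading[np.argmax(np.abs(loading))] < 0:
                loading = -loading
            interference.append(
                Spectrum(paraffin_img.axis, loading, name=f"paraffin_pc{i + 1}")
            )
    return EMSCBasis(target=target, interference=interference, poly_order=poly_order)


def fit_emsc(s: Spectrum, basis: EMSCBasis) -> EMSCFit:
    """Ordinary-least-squares EMSC fit of one spectrum."""
    if s.axis != basis.axis:
        raise SpectralRangeError("spectrum is not on the basis axis")
    y = s.absorbance
    if not np.all(np.isfinite(y)):
        raise DataError("spectrum contains non-finite values")
    X = basis.design_matrix()
    coef = _qr_solve(X, y[:, None])[:, 0]
    nq = len(basis.interference)
    resid = y - X @ coef
    return EMSCFit(
        c=float(coef[0]),
        b=coef[1 : 1 + nq].copy(),
        d=coef[1 + nq :].copy(),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def _qr_solve(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(X)
    return scipy.linalg.solve_triangular(r, q.T @ Y)


def correct_spectrum(
    s: Spectrum, fit: EMSCFit, basis: EMSCBasis, rule: MaskRule | None = None
) -> Spectrum:
    """Remove interference and baseline, rescale to unit thickness.

    Raises :class:`DegeneratePixelError` when ``|c|`` is below the mask rule's
    threshold; callers treat such pixels as background.
    """
    rule = rule or MaskRule()
    if abs(fit.c) < rule.c_min:
        raise DegeneratePixelError(
            f"fitted scale c={fit.c:.4g} below c_min={rule.c_min}"
        )
    X = basis.design_matrix()
    nq = len(basis.interference)
    removed = X[:, 1 : 1 + nq] @ fit.b + X[:, 1 + nq :] @ fit.d
    return Spectrum(basis.axis, (s.absorbance - removed) / fit.c, name=s.name)


def choose_target(img: SpectralImage) -> Spectrum:
    """Default EMSC target policy: mean spectrum over unmasked pixels."""
    if not img.mask.any():
        raise DataError("cannot choose a target from an empty mask")
    mean = img.cube[img.mask].mean(axis=0)
    return Spectrum(img.axis, mean, name="mean_tissue")


def _align_to_basis(img: SpectralImage, basis: EMSCBasis) -> SpectralImage:
    if img.axis == basis.axis:
        return img
    cropped = crop_spectral_range(img, basis.axis.lo, basis.axis.hi)
    if cropped.axis == basis.axis:
        return cropped
    # channel-wise linear interpolation onto the basis grid
    x = cropped.axis.values
    cube = cropped.cube
    if x[0] > x[-1]:
        x = x[::-1]
        cube = cube[:, :, ::-1]
    tgt = basis.axis.values
    idx = np.clip(np.searchsorted(x, tgt, side="right") - 1, 0, x.size - 2)
    w = (tgt - x[idx]) / (x[idx + 1] - x[idx])
    new_cube = (1.0 - w) * cube[:, :, idx] + w * cube[:, :, idx + 1]
    return SpectralImage(
        basis.axis, new_cube, pixel_size_um=img.pixel_size_um,
        mask=img.mask.copy(), meta=dict(img.meta),
    )


def dewax_image(
    img: SpectralImage, basis: EMSCBasis, rule: MaskRule | None = None
) -> tuple[SpectralImage, EMSCMaps]:
    """EMSC-correct every unmasked pixel; mask pixels failing the rule.

    Returns the corrected image (on the basis axis) and the per-pixel maps of
    ``c``, each interference coefficient, the baseline coefficients and the
    fit residual RMS.  An image whose mask empties out is returned with an
    ``all-background`` warning rather than an exception.
    """
    rule = rule or MaskRule()
    img = _align_to_basis(img, basis)
    rows, cols, n = img.cube.shape
    if not np.all(np.isfinite(img.cube)):
        raise DataError("image cube contains non-finite values")
    X = basis.design_matrix()
    nq = len(basis.interference)
    S = img.cube.reshape(rows * cols, n).T  # channels x pixels
    coef = _qr_solve(X, S)  # p x pixels
    resid = S - X @ coef
    residual_rms = np.sqrt(np.mean(resid**2, axis=0)).reshape(rows, cols)
    c = coef[0].reshape(rows, cols)
    b = coef[1 : 1 + nq].T.reshape(rows, cols, nq)
    d = coef[1 + nq :].T.reshape(rows, cols, -1)

    ok = img.mask & (np.abs(c) >= rule.c_min)
    if rule.residual_max is not None:
        ok &= residual_rms <= rule.residual_max

    removed = X[:, 1 : 1 + nq] @ coef[1 : 1 + nq] + X[:, 1 + nq :] @ coef[1 + nq :]
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = (S - removed) / coef[0]
    corrected = corrected.T.reshape(rows, cols, n)
    corrected[~ok] = 0.0

    if not ok.any():
        import warnings

        warnings.warn("all pixels masked after EMSC (all-background image)", stacklevel=2)
    out = SpectralImage(
        basis.axis, corrected, pixel_size_um=img.pixel_size_um, mask=ok,
        meta={**img.meta, "dewaxed": "true"},
    )
    return out, EMSCMaps(c=c, b=b, d=d, residual_rms=residual_rms)


def save_fit_maps(path, maps: EMSCMaps) -> None:
    """Append the EMSC coefficient maps to an existing image container under /emsc."""
    import h5py

    with h5py.File(path, "a") as f:
        if "emsc" in f:
            del f["emsc"]
        g = f.create_group("emsc")
        g.create_dataset("c", data=maps.c)
        g.create_dataset("b", data=maps.b)
        g.create_dataset("d", data=maps.d)
        g.create_dataset("residual_rms", data=maps.residual_rms)
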