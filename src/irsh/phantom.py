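"""Synthetic FTIR skin-section phantoms with known ground truth.

The generator emulates a transmission FTIR image of a paraffin-embedded mouse
skin section: horizontal anatomical layers (epidermis, dermis with elliptical
hair bulbs, hypodermis, muscle, subcutaneous fat), a per-pixel section
thickness factor, an additive paraffin contribution, a smooth polynomial
baseline and i.i.d. Gaussian noise:

    cube[r, c, :] = t(r,c) * E_label(nu) + a(r,c) * P(nu) + B(r,c, nu) + eps

where ``E`` are class endmember spectra built from Gaussian/Lorentzian bands
at standard protein and lipid assignments (the collagenous dermis carries the
amide A band near 3300 cm^-1, amide I/II near 1660/1550 cm^-1 and the amide
III triplet at 1330, 1280 and 1204 cm^-1), and ``P`` is a paraffin spectrum
with the CH2 scissoring doublet at 1462/1472 cm^-1, the 1378 cm^-1 CH3 band
and the CH stretches at 2920/2850 cm^-1.

A knockout-like group ("KO") gets a dermis thickened by a configurable factor
(default 2x) at fixed total image height, mimicking the loss of dermal matrix
compaction seen when collagen fibrillogenesis is deregulated.  Every random
field draws from its own seeded substream, so phantoms and cohorts are exact
functions of their configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .core_io import LabelMap, SpectralImage, Spectrum, WavenumberAxis, distinct_colors
from .errors import ConfigurationError

__all__ = [
    "Band",
    "TissueEndmember",
    "PhantomConfig",
    "PhantomImage",
    "CLASS_NAMES",
    "LAYER_ORDER",
    "build_endmember",
    "default_endmembers",
    "paraffin_endmember",
    "default_axis",
    "generate_layout",
    "generate_phantom",
    "generate_cohort",
    "generate_paraffin_image",
    "collagen_reference",
    "save_truth",
    "load_truth",
]

# tissue classes, in truth-label order; the first five are the stacked layers
CLASS_NAMES = (
    "epidermis",
    "dermis",
    "hypodermis",
    "muscle",
    "subcutaneous_fat",
    "hair_bulb",
)
LAYER_ORDER = CLASS_NAMES[:5]

# total hair-bulb footprint as a fraction of the dermis band area; scaling the
# bulbs with dermis thickness keeps the realized dermis-area ratio at the
# configured KO:WT contrast
_BULB_AREA_FRACTION = 0.08


@dataclass(frozen=True)
class Band:
    """A single absorption band."""

    center_cm1: float
    fwhm_cm1: float
    amplitude: float
    shape: Literal["gaussian", "lorentzian"] = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm_cm1 <= 0:
            raise ConfigurationError("band fwhm must be positive")

    def profile(self, nu: np.ndarray) -> np.ndarray:
        u = (nu - self.center_cm1) / self.fwhm_cm1
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-4.0 * math.log(2.0) * u * u)
        return self.amplitude / (1.0 + 4.0 * u * u)


@dataclass(frozen=True)
class TissueEndmember:
    """Named band model for one tissue class."""

    name: str
    bands: tuple[Band, ...]
    offset: float = 0.0

    def __post_init__(self) -> None:
        if len(self.bands) == 0:
            raise ConfigurationError(f"endmember '{self.name}' needs >= 1 band")


def build_endmember(em: TissueEndmember, axis: WavenumberAxis) -> Spectrum:
    """Evaluate ``offset + sum of band profiles`` on ``axis``."""
    nu = axis.values
    total = np.full(nu.shape, float(em.offset))
    for band in em.bands:
        total += band.profile(nu)
    return Spectrum(axis, total, name=em.name)


def _g(center: float, fwhm: float, amp: float) -> Band:
    return Band(center, fwhm, amp, "gaussian")


def default_endmembers() -> dict[str, TissueEndmember]:
    """Band library for the six tissue classes.

    Band centers are generic mid-IR protein/lipid assignments: amide A ~3300,
    amide I ~1660, amide II ~1550, the collagen amide III triplet at
    1330/1280/1204, the ester carbonyl at 1745 and CH2/CH3 deformations near
    1465/1378 cm^-1.  Amplitudes are free choices that give distinct,
    plausible class signatures; they are not measurements.
    """
    return {
        "epidermis": TissueEndmember(
            "epidermis",
            (
                _g(3290, 160, 0.50),
                _g(1655, 50, 0.90),
                _g(1545, 45, 0.55),
                _g(1745, 30, 0.08),
                _g(1240, 60, 0.15),
                _g(1080, 60, 0.12),
            ),
        ),
        "dermis": TissueEndmember(
            "dermis",
            (
                _g(3300, 150, 0.55),
                _g(1660, 50, 1.00),
                _g(1550, 50, 0.60),
                _g(1330, 25, 0.25),
                _g(1280, 25, 0.22),
                _g(1204, 25, 0.18),
                _g(1080, 70, 0.08),
            ),
        ),
        "hypodermis": TissueEndmember(
            "hypodermis",
            (
                _g(2925, 60, 0.70),
                _g(2853, 40, 0.40),
                _g(1745, 35, 0.90),
                _g(1655, 50, 0.25),
                _g(1545, 45, 0.12),
                _g(1465, 30, 0.45),
                _g(1160, 60, 0.30),
            ),
        ),
        "muscle": TissueEndmember(
            "muscle",
            (
                _g(3295, 150, 0.50),
                _g(1652, 45, 1.00),
                _g(1548, 45, 0.75),
                _g(1398, 40, 0.20),
                _g(1080, 60, 0.15),
            ),
        ),
        "subcutaneous_fat": TissueEndmember(
            "subcutaneous_fat",
            (
                _g(2925, 60, 0.90),
                _g(2853, 40, 0.55),
                _g(1745, 35, 1.00),
                # adipose tissue retains protein signal from septa/stroma
                _g(1655, 50, 0.20),
                _g(1545, 45, 0.12),
                _g(1465, 30, 0.50),
                _g(1377, 25, 0.15),
                _g(1160, 65, 0.35),
            ),
        ),
        "hair_bulb": TissueEndmember(
            "hair_bulb",
            (
                _g(3290, 160, 0.50),
                _g(1658, 50, 0.85),
                _g(1548, 48, 0.50),
                _g(1040, 90, 0.45),
            ),
        ),
    }


def paraffin_endmember() -> TissueEndmember:
    """Paraffin band model: CH2 scissoring doublet, CH3 bend, CH stretches."""
    return TissueEndmember(
        "paraffin",
        (
            Band(2920, 25, 1.60, "gaussian"),
            Band(2850, 20, 1.10, "gaussian"),
            Band(1472, 10, 0.70, "lorentzian"),
            Band(1462, 12, 1.00, "lorentzian"),
            Band(1378, 12, 0.35, "gaussian"),
        ),
    )


def _paraffin_variation() -> TissueEndmember:
    # crystallinity-like variation: doublet intensity swap
    return TissueEndmember(
        "paraffin_variation",
        (
            Band(1472, 10, 0.30, "lorentzian"),
            Band(1462, 12, -0.30, "lorentzian"),
        ),
    )


class PhantomConfig(BaseModel):
    """Full description of one phantom; the generator is a pure function of it."""

    model_config = ConfigDict(extra="forbid")

    rows: int = Field(default=64, gt=0)
    cols: int = Field(default=64, gt=0)
    pixel_size_um: float = Field(default=6.25, gt=0)
    axis_start_cm1: float = 4000.0
    axis_end_cm1: float = 750.0
    axis_step_cm1: float = Field(default=2.0, gt=0)
    group: Literal["WT", "KO"] = "WT"
    dermis_thickness_ratio: float = Field(default=2.0, gt=0)
    layer_fractions_wt: dict[str, float] = Field(
        default_factory=lambda: {
            "epidermis": 0.10,
            "dermis": 0.15,
            "hypodermis": 0.25,
            "muscle": 0.25,
            "subcutaneous_fat": 0.25,
        }
    )
    n_hair_bulbs: int = Field(default=3, ge=0)
    paraffin_amplitude_mean: float = 0.5
    paraffin_amplitude_sd: float = Field(default=0.15, ge=0)
    baseline_order: int = Field(default=2, ge=0)
    baseline_amplitude: float = Field(default=0.02, ge=0)
    thickness_mean: float = Field(default=1.0, gt=0)
    thickness_sd: float = Field(default=0.10, ge=0)
    noise_sd: float = Field(default=0.005, ge=0)
    seed: int = Field(default=0, ge=0)

    @field_validator("layer_fractions_wt")
    @classmethod
    def _check_fractions(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(LAYER_ORDER):
            raise ValueError(f"layer_fractions_wt keys must be {sorted(LAYER_ORDER)}")
        if any(f <= 0 for f in v.values()):
            raise ValueError("layer fractions must be positive")
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("WT layer fractions must sum to 1")
        return v

    @model_validator(mode="after")
    def _check_axis(self) -> "PhantomConfig":
        if self.axis_start_cm1 <= self.axis_end_cm1:
            raise ValueError("axis_start_cm1 must exceed axis_end_cm1 (descending axis)")
        if self.axis_end_cm1 <= 0:
            raise ValueError("axis endpoints must be positive")
        return self


@dataclass
class PhantomImage:
    """A phantom plus its generation ground truth."""

    image: SpectralImage
    truth: LabelMap
    true_thickness: np.ndarray
    true_paraffin: np.ndarray
    config: PhantomConfig


def default_axis(cfg: PhantomConfig) -> WavenumberAxis:
    """Descending acquisition axis from the config (default 4000->750, step 2)."""
    values = np.arange(
        cfg.axis_start_cm1, cfg.axis_end_cm1 - 0.5 * cfg.axis_step_cm1, -cfg.axis_step_cm1
    )
    return WavenumberAxis(values)


def _substream(seed: int, field_id: int) -> np.random.Generator:
    # fixed per-field offsets: one master seed, independent streams
    return np.random.default_rng([int(seed), int(field_id)])


def _layer_fractions(cfg: PhantomConfig) -> list[float]:
    fracs = [cfg.layer_fractions_wt[name] for name in LAYER_ORDER]
    if cfg.group == "KO":
        f_d = fracs[1] * cfg.dermis_thickness_ratio
        if f_d >= 1.0:
            raise ConfigurationError(
                f"KO dermis fraction {f_d:.3f} >= 1; reduce the WT dermis "
                "fraction or the thickness ratio"
            )
        scale = (1.0 - f_d) / (1.0 - fracs[1])
        fracs = [f * scale for f in fracs]
        fracs[1] = f_d
    return fracs


def generate_layout(cfg: PhantomConfig) -> LabelMap:
    """Stacked-layer label map with hair bulbs carved into the dermis.

    Layers run top to bottom in anatomical order with row counts proportional
    to the (group-adjusted) fractions; for KO the dermis row count is scaled
    by ``dermis_thickness_ratio`` and the other layers shrink to keep the
    total height fixed.  Bulbs are non-overlapping ellipses fully inside the
    dermis band, with total footprint ~8% of the dermis area (scaled with
    dermis thickness) and integer centers drawn from a seeded substream.
    """
    fracs = _layer_fractions(cfg)
    bounds = np.rint(np.cumsum(fracs) * cfg.rows).astype(int)
    bounds[-1] = cfg.rows
    starts = np.concatenate([[0], bounds[:-1]])
    if np.any(bounds - starts < 1):
        raise ConfigurationError(
            f"layer too thin at rows={cfg.rows}: row counts {list(bounds - starts)}"
        )
    labels = np.empty((cfg.rows, cfg.cols), dtype=np.int64)
    for idx in range(5):
        labels[starts[idx] : bounds[idx], :] = idx

    if cfg.n_hair_bulbs > 0:
        d0, d1 = int(starts[1]), int(bounds[1])
        dermis_rows = d1 - d0
        ry = max(2, int(round(0.2 * dermis_rows)))
        if 2 * ry + 3 > dermis_rows:
            raise ConfigurationError(
                f"dermis band of {dermis_rows} rows is too thin for hair bulbs"
            )
        area = _BULB_AREA_FRACTION * dermis_rows * cfg.cols / cfg.n_hair_bulbs
        rx = max(2, int(round(area / (math.pi * ry))))
        if 2 * rx + 3 > cfg.cols:
            raise ConfigurationError("image too narrow for hair bulbs")
        rng = _substream(cfg.seed, 17)
        placed: list[tuple[int, int]] = []
        rr, cc = np.mgrid[0 : cfg.rows, 0 : cfg.cols]
        for _ in range(cfg.n_hair_bulbs):
            for _attempt in range(500):
                r0 = int(rng.integers(d0 + ry + 1, d1 - ry - 1))
                c0 = int(rng.integers(rx + 1, cfg.cols - rx - 1))
                if all(
                    abs(r0 - pr) > 2 * ry + 1 or abs(c0 - pc) > 2 * rx + 1
                    for pr, pc in placed
                ):
                    placed.append((r0, c0))
                    break
            else:
                raise ConfigurationError(
                    "could not place non-overlapping hair bulbs; reduce "
                    "n_hair_bulbs or enlarge the dermis"
                )
            inside = ((rr - r0) / ry) ** 2 + ((cc - c0) / rx) ** 2 <= 1.0
            labels[inside] = 5
    return LabelMap(labels, k=len(CLASS_NAMES), color_table=distinct_colors(6))


def generate_phantom(cfg: PhantomConfig) -> PhantomImage:
    """Generate one phantom from its config (bit-reproducible)."""
    axis = default_axis(cfg)
    layout = generate_layout(cfg)
    nu = axis.values
    endmembers = default_endmembers()
    E = np.stack([build_endmember(endmembers[n], axis).absorbance for n in CLASS_NAMES])
    P = build_endmember(paraffin_endmember(), axis).absorbance

    shape = (cfg.rows, cfg.cols)
    t = _truncated_normal(_substream(cfg.seed, 1), cfg.thickness_mean, cfg.thickness_sd, shape, lo=0.0, strict=True)
    a = _truncated_normal(_substream(cfg.seed, 2), cfg.paraffin_amplitude_mean, cfg.paraffin_amplitude_sd, shape, lo=0.0, strict=False)
    coeffs = _substream(cfg.seed, 3).normal(0.0, 1.0, shape + (cfg.baseline_order + 1,))
    coeffs *= cfg.baseline_amplitude
    x = 2.0 * (nu - nu.min()) / (nu.max() - nu.min()) - 1.0
    powers = np.stack([x**j for j in range(cfg.baseline_order + 1)])
    baseline = np.einsum("rcj,jn->rcn", coeffs, powers)
    noise = _substream(cfg.seed, 4).normal(0.0, cfg.noise_sd, shape + (axis.n,)) if cfg.noise_sd > 0 else 0.0

    cube = t[:, :, None] * E[layout.labels] + a[:, :, None] * P + baseline + noise
    image = SpectralImage(
        axis,
        cube,
        pixel_size_um=cfg.pixel_size_um,
        mask=np.ones(shape, dtype=bool),
        meta={"group": cfg.group, "seed": str(cfg.seed), "kind": "phantom"},
    )
    return PhantomImage(image, layout, t, a, cfg)


def _truncated_normal(rng, mean, sd, shape, lo, strict):
    values = rng.normal(mean, sd, shape)
    for _ in range(1000):
        bad = (values <= lo) if strict else (values < lo)
        if not bad.any():
            return values
        values[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ConfigurationError("truncated-normal rejection failed; check mean/sd")


def _derive_seed(master: int, index: int) -> int:
    return (1000003 * int(master) + 10007 * int(index) + 12345) % (2**31)


def generate_cohort(
    cfg_wt: PhantomConfig, cfg_ko: PhantomConfig, n_per_group: int, seed: int
) -> list[PhantomImage]:
    """n WT phantoms then n KO phantoms, each with its own derived seed."""
    if n_per_group < 1:
        raise ConfigurationError("n_per_group must be >= 1")
    phantoms: list[PhantomImage] = []
    for g, cfg in (("WT", cfg_wt), ("KO", cfg_ko)):
        base = 0 if g == "WT" else n_per_group
        for i in range(n_per_group):
            sub = cfg.model_copy(
                update={"seed": _derive_seed(seed, base + i), "group": g}
            )
            ph = generate_phantom(sub)
            ph.image.meta["sample_id"] = f"{g}_{i + 1}"
            phantoms.append(ph)
    return phantoms


def generate_paraffin_image(
    cfg: PhantomConfig, rows: int = 16, cols: int = 16, variation_sd: float = 0.1
) -> SpectralImage:
    """Pure-paraffin calibration image acquired 'under the same conditions'.

    Pixel spectra are ``a * (P + g * P_var) + noise`` where ``P_var`` swaps
    intensity inside the 1462/1472 doublet (a crystallinity-like degree of
    freedom), so the image has genuine spectral variability for the
    interference PCA to capture.
    """
    axis = default_axis(cfg)
    P = build_endmember(paraffin_endmember(), axis).absorbance
    V = build_endmember(_paraffin_variation(), axis).absorbance
    rng = _substream(cfg.seed, 23)
    a = _truncated_normal(
        rng, cfg.paraffin_amplitude_mean if cfg.paraffin_amplitude_mean > 0 else 1.0,
        cfg.paraffin_amplitude_sd, (rows, cols), lo=0.0, strict=True,
    )
    g = rng.normal(0.0, variation_sd, (rows, cols))
    cube = a[:, :, None] * (P[None, None, :] + g[:, :, None] * V[None, None, :])
    if cfg.noise_sd > 0:
        cube = cube + rng.normal(0.0, cfg.noise_sd, cube.shape)
    return SpectralImage(
        axis, cube, pixel_size_um=cfg.pixel_size_um,
        meta={"kind": "paraffin", "seed": str(cfg.seed)},
    )


def collagen_reference(axis: WavenumberAxis, paraffin_amplitude: float = 0.5) -> Spectrum:
    """Synthetic type I collagen reference: dermis band model (+ paraffin).

    Emulates a reference recorded from a paraffin-embedded tendon section;
    with ``paraffin_amplitude=0`` it is the clean collagen endmember.
    """
    em = build_endmember(default_endmembers()["dermis"], axis).absorbance
    if paraffin_amplitude != 0.0:
        em = em + paraffin_amplitude * build_endmember(paraffin_endmember(), axis).absorbance
    return Spectrum(axis, em, name="type_I_collagen")


# ---------------------------------------------------------------------------
# Ground-truth container
# ---------------------------------------------------------------------------

def save_truth(ph: PhantomImage, path, overwrite: bool = False) -> None:
    """Write truth labels, thickness and paraffin maps to a sibling HDF5 file."""
    import h5py
    from pathlib import Path

    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=ph.truth.labels)
        f.create_dataset("thickness", data=ph.true_thickness)
        f.create_dataset("paraffin", data=ph.true_paraffin)
        f.attrs["k"] = ph.truth.k
        f.attrs["class_names"] = ",".join(CLASS_NAMES)
        f.attrs["group"] = ph.config.group
        f.attrs["seed"] = int(ph.config.seed)


def load_truth(path) -> tuple[LabelMap, np.ndarray, np.ndarray, dict[str, str]]:
    import h5py

    with h5py.File(path, "r") as f:
        labels = f["labels"][()]
        thickness = f["thickness"][()]
        paraffin = f["paraffin"][()]
        k = int(f.attrs["k"])
        meta = {
            "class_names": str(f.attrs.get("class_names", "")),
            "group": str(f.attrs.get("group", "")),
            "seed": str(f.attrs.get("seed", "")),
        }
    return LabelMap(labels, k=k, color_table=distinct_colors(k)), thickness, paraffin, meta
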