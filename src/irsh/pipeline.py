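"""End-to-end pipeline: simulate -> dewax -> cluster -> compare -> correlate.

One :class:`PipelineConfig` (YAML, schema-checked by pydantic) drives the
whole run; every random choice derives from ``master_seed``, so a rerun with
the same config is byte-identical.  Outputs land in one directory per run:
stage subdirectories, CSV tables, PNG maps, HDF5 cubes, and a Markdown report
with per-stage provenance (parameters, seeds, output SHA-256 hashes).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import clustering as cl
from . import correlation as corr
from . import emsc
from . import phantom as ph
from . import stats as st
from .core_io import (
    SpectralImage,
    crop_spectral_range,
    render_label_map,
    save_image,
)
from .errors import ConfigurationError

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]


class EMSCConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_components: int = Field(default=8, ge=0)
    poly_order: int = Field(default=2, ge=0, le=4)
    c_min: float = Field(default=0.2, gt=0)
    range_lo_cm1: float = 800.0
    range_hi_cm1: float = 1800.0


class ClusteringConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k_list: list[int] = Field(default_factory=lambda: [5, 10])
    n_init: int = Field(default=20, ge=1)

    @field_validator("k_list")
    @classmethod
    def _check_k(cls, v: list[int]) -> list[int]:
        if not v:
            raise ValueError("k_list must be non-empty")
        if any(k < 2 for k in v):
            raise ValueError("every k must be >= 2")
        return v


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(default=0.01, gt=0, lt=1)


class CorrelationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    range_lo_cm1: float | None = None  # None = full acquired axis
    range_hi_cm1: float | None = None
    mode: Literal["raw", "dewaxed"] = "raw"


class PipelineConfig(BaseModel):
    """Nested configuration for a full run."""

    model_config = ConfigDict(extra="forbid")

    phantom: ph.PhantomConfig = Field(default_factory=ph.PhantomConfig)
    n_per_group: int = Field(default=3, ge=1)
    emsc: EMSCConfig = Field(default_factory=EMSCConfig)
    clustering: ClusteringConfig = Field(default_factory=ClusteringConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    correlation: CorrelationConfig = Field(default_factory=CorrelationConfig)
    master_seed: int = Field(default=0, ge=0)
    output_dir: str = "irsh_run"


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse + schema-check a YAML config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config root must be a mapping")
    try:
        return PipelineConfig(**data)
    except ValidationError as exc:
        raise ConfigurationError(f"{path}: {exc}") from exc


@dataclass
class RunReport:
    """Provenance + result tables for one pipeline run."""

    output_dir: Path
    stages: list[dict] = field(default_factory=list)
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    figures: list[Path] = field(default_factory=list)

    def add_stage(self, name: str, params: dict, outputs: list[Path]) -> None:
        self.stages.append(
            {
                "name": name,
                "params": params,
                "outputs": [
                    {"path": str(p.relative_to(self.output_dir)), "sha256": _sha256(p)}
                    for p in outputs
                ],
            }
        )

    def write_markdown(self, path: Path) -> None:
        for stage in self.stages:
            for out in stage["outputs"]:
                p = self.output_dir / out["path"]
                if not p.exists():
                    raise FileNotFoundError(f"report references missing file {p}")
        # cross-stage consistency: abundances must re-sum to 100% per image
        for name, table in self.tables.items():
            if name.startswith("abundance"):
                sums = table.groupby("image_id")["percent"].sum()
                if not np.allclose(sums.to_numpy(), 100.0, rtol=0, atol=1e-9):
                    raise AssertionError(f"{name}: percentages do not sum to 100")
        lines = ["# IRSH run report", ""]
        for stage in self.stages:
            lines.append(f"## Stage: {stage['name']}")
            lines.append("")
            for key, value in stage["params"].items():
                lines.append(f"- {key}: {value}")
            lines.append("")
            lines.append("| output | sha256 |")
            lines.append("| --- | --- |")
            for out in stage["outputs"]:
                lines.append(f"| {out['path']} | {out['sha256'][:16]} |")
            lines.append("")
        for name, table in self.tables.items():
            lines.append(f"## Table: {name}")
            lines.append("")
            lines.append(table.to_markdown(index=False))
            lines.append("")
        if self.figures:
            lines.append("## Figures")
            lines.append("")
            for fig in self.figures:
                lines.append(f"- {fig.relative_to(self.output_dir)}")
            lines.append("")
        path.write_text("\n".join(lines))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _cohort_target(images: list[SpectralImage]) -> "ph.Spectrum":
    # pooled mean over all unmasked pixels of all images: one common EMSC
    # target keeps the corrected feature space comparable across groups
    total = np.zeros(images[0].axis.n)
    count = 0
    for img in images:
        total += img.cube[img.mask].sum(axis=0)
        count += int(img.mask.sum())
    from .core_io import Spectrum

    return Spectrum(images[0].axis, total / count, name="cohort_mean")


def run_pipeline(cfg: PipelineConfig, output_dir: str | Path | None = None) -> RunReport:
    """Execute the full pipeline for every k in the configured k-list."""
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(output_dir=out)

    # --- simulate ---------------------------------------------------------
    phantom_dir = out / "phantoms"
    phantom_dir.mkdir(exist_ok=True)
    cfg_wt = cfg.phantom.model_copy(update={"group": "WT"})
    cfg_ko = cfg.phantom.model_copy(update={"group": "KO"})
    cohort = ph.generate_cohort(cfg_wt, cfg_ko, cfg.n_per_group, cfg.master_seed)
    manifest_rows = []
    sim_outputs = []
    for p in cohort:
        sid = p.image.meta["sample_id"]
        img_path = phantom_dir / f"{sid}.h5"
        truth_path = phantom_dir / f"{sid}_truth.h5"
        save_image(p.image, img_path, overwrite=True)
        ph.save_truth(p, truth_path, overwrite=True)
        manifest_rows.append(
            (sid, p.config.group, p.config.seed, str(img_path.relative_to(out)),
             str(truth_path.relative_to(out)))
        )
        sim_outputs += [img_path, truth_path]
    manifest = pd.DataFrame(
        manifest_rows, columns=["image_id", "group", "seed", "path", "truth_path"]
    )
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    paraffin_cfg = cfg.phantom.model_copy(
        update={"seed": (cfg.master_seed + 777) % (2**31)}
    )
    paraffin_img = ph.generate_paraffin_image(paraffin_cfg)
    paraffin_path = phantom_dir / "paraffin.h5"
    save_image(paraffin_img, paraffin_path, overwrite=True)
    report.add_stage(
        "simulate",
        {"n_per_group": cfg.n_per_group, "master_seed": cfg.master_seed,
         "rows": cfg.phantom.rows, "cols": cfg.phantom.cols,
         "dermis_thickness_ratio": cfg.phantom.dermis_thickness_ratio},
        sim_outputs + [manifest_path, paraffin_path],
    )

    # --- dewax ------------------------------------------------------------
    dewax_dir = out / "dewaxed"
    dewax_dir.mkdir(exist_ok=True)
    lo, hi = cfg.emsc.range_lo_cm1, cfg.emsc.range_hi_cm1
    raw_cropped = [crop_spectral_range(p.image, lo, hi) for p in cohort]
    paraffin_cropped = crop_spectral_range(paraffin_img, lo, hi)
    target = _cohort_target(raw_cropped)
    basis = emsc.build_paraffin_basis(
        paraffin_cropped, cfg.emsc.n_components, cfg.emsc.poly_order, target
    )
    rule = emsc.MaskRule(c_min=cfg.emsc.c_min)
    dewaxed: list[SpectralImage] = []
    dewax_outputs = []
    for p, raw in zip(cohort, raw_cropped):
        corrected, maps = emsc.dewax_image(raw, basis, rule)
        dewaxed.append(corrected)
        path = dewax_dir / f"{p.image.meta['sample_id']}.h5"
        save_image(corrected, path, overwrite=True)
        emsc.save_fit_maps(path, maps)
        dewax_outputs.append(path)
    report.add_stage(
        "dewax",
        {"n_components": cfg.emsc.n_components, "poly_order": cfg.emsc.poly_order,
         "c_min": cfg.emsc.c_min, "range_cm1": [lo, hi]},
        dewax_outputs,
    )

    # --- cluster + compare, per k ----------------------------------------
    for k in cfg.clustering.k_list:
        kdir = out / f"cluster_k{k}"
        kdir.mkdir(exist_ok=True)
        seed_k = (cfg.master_seed * 131 + k) % (2**31)
        model, label_maps = cl.common_kmeans(
            dewaxed, k, seed=seed_k, n_init=cfg.clustering.n_init
        )
        outputs = []
        ids = [p.image.meta["sample_id"] for p in cohort]
        groups = [p.config.group for p in cohort]
        agreement_rows = []
        for p, lm, sid in zip(cohort, label_maps, ids):
            png = kdir / f"labels_{sid}.png"
            render_label_map(lm, png)
            outputs.append(png)
            report.figures.append(png)
            _, agreement = cl.match_clusters_to_truth(lm, p.truth)
            agreement_rows.append((sid, p.config.group, agreement))
        abundance = cl.abundance_table(label_maps, ids, groups)
        abundance_path = kdir / "abundance.csv"
        abundance.to_csv(abundance_path, index=False)
        comparisons = st.comparisons_frame(
            st.compare_all(abundance, alpha=cfg.stats.alpha)
        )
        comparisons_path = kdir / "comparisons.csv"
        comparisons.to_csv(comparisons_path, index=False)
        agreement_df = pd.DataFrame(
            agreement_rows, columns=["image_id", "group", "truth_agreement"]
        )
        agreement_path = kdir / "truth_agreement.csv"
        agreement_df.to_csv(agreement_path, index=False)
        outputs += [abundance_path, comparisons_path, agreement_path]
        report.tables[f"abundance_k{k}"] = abundance
        report.tables[f"comparisons_k{k}"] = comparisons
        report.add_stage(
            f"cluster_k{k}",
            {"k": k, "seed": seed_k, "n_init": cfg.clustering.n_init,
             "inertia": model.inertia, "alpha": cfg.stats.alpha},
            outputs,
        )

    # --- correlate --------------------------------------------------------
    corr_dir = out / "correlation"
    corr_dir.mkdir(exist_ok=True)
    mode = cfg.correlation.mode
    corr_images = dewaxed if mode == "dewaxed" else [p.image for p in cohort]
    ref_axis = corr_images[0].axis
    ref = ph.collagen_reference(
        ref_axis,
        paraffin_amplitude=0.0 if mode == "dewaxed" else cfg.phantom.paraffin_amplitude_mean,
    )
    ref_path = corr_dir / "collagen_reference.csv"
    pd.DataFrame(
        {"wavenumber_cm1": ref.axis.values, "absorbance": ref.absorbance}
    ).to_csv(ref_path, index=False)
    corr_rows = []
    corr_outputs = [ref_path]
    for p, img in zip(cohort, corr_images):
        sid = p.image.meta["sample_id"]
        cmap = corr.correlate_image(
            img, ref, cfg.correlation.range_lo_cm1, cfg.correlation.range_hi_cm1,
            mode=mode,
        )
        png = corr_dir / f"corr_{sid}.png"
        corr.render_correlation(cmap, png)
        corr_outputs.append(png)
        report.figures.append(png)
        dermis = p.truth.labels == ph.CLASS_NAMES.index("dermis")
        finite = np.isfinite(cmap.r_raw)
        corr_rows.append(
            (sid, p.config.group,
             float(np.median(cmap.r_raw[finite])),
             float(np.median(cmap.r_raw[dermis & finite])))
        )
    corr_summary = pd.DataFrame(
        corr_rows, columns=["image_id", "group", "median_r_tissue", "median_r_dermis"]
    )
    corr_summary_path = corr_dir / "correlation_summary.csv"
    corr_summary.to_csv(corr_summary_path, index=False)
    corr_outputs.append(corr_summary_path)
    report.tables["correlation_summary"] = corr_summary
    report.add_stage(
        "correlate",
        {"mode": mode,
         "range_cm1": [cfg.correlation.range_lo_cm1, cfg.correlation.range_hi_cm1]},
        corr_outputs,
    )

    report.write_markdown(out / "report.md")
    return report
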