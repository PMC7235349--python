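# irsh — label-free infrared spectral histology

`irsh` is a tested, reproducible pipeline for analyzing mid-infrared (FTIR)
hyperspectral images of paraffin-embedded tissue sections without any
staining.  It was built around a concrete biological question — how loss of
lumican, a small leucine-rich proteoglycan that regulates collagen
fibrillogenesis, remodels the mouse skin dermis — but every stage is generic
infrared spectral histology:

1. **Digital dewaxing (EMSC).**  Each pixel spectrum `s(ν)` is decomposed by
   ordinary least squares as

   `s(ν) ≈ c·m(ν) + Σᵢ bᵢ·pᵢ(ν) + Σⱼ dⱼ·xʲ`

   where `m` is a reference tissue spectrum, the `pᵢ` are the mean spectrum
   and principal-component loadings of a pure-paraffin calibration image,
   and the `xʲ` are polynomial baseline terms on the wavenumber axis scaled
   to [−1, 1].  The corrected spectrum `(s − Σbᵢpᵢ − Σdⱼxʲ)/c` removes the
   paraffin contribution and baseline and rescales away section thickness;
   pixels with `|c|` below a threshold (background, pure wax) are masked.
2. **Common K-means segmentation.**  Pixels pooled from all images of a
   cohort are clustered by one seeded multi-restart k-means++/Lloyd model,
   so cluster identities and false colors are comparable across animals and
   groups.  Label maps render as PNG.
3. **Cluster-abundance statistics.**  Per-image cluster percentages, group
   means ± SEM, KO/WT fold change, and a two-sided pooled-variance Student
   t-test per cluster (significance at p < 0.01 by default).
4. **Collagen correlation mapping.**  Pixel-by-pixel Pearson correlation
   with a type I collagen reference spectrum, rendered on a 0 (black) to 1
   (white) scale.

Because no raw images from the original experiment are distributable, the
package ships a first-class synthetic-phantom generator
(`irsh.phantom`): layered skin anatomy (epidermis, dermis with hair bulbs,
hypodermis, muscle, subcutaneous fat) at 6.25 µm/pixel over 4000–750 cm⁻¹,
with per-pixel thickness variation, paraffin contamination, polynomial
baselines, noise, and a configurable KO:WT dermis-thickness contrast
(default 2×).  Every phantom carries its ground truth, so the whole pipeline
is quantitatively testable.

## Worked example

Run the full default pipeline — a cohort of 3 wild-type + 3 knockout-like
64×64 phantoms, dewaxing with 8 paraffin components and a quadratic
baseline over 1800–800 cm⁻¹, common k-means at k ∈ {5, 10}, group
statistics and correlation maps:

```sh
irsh run --seed 1 --out run1
```

or from Python:

```python
from irsh.pipeline import PipelineConfig, run_pipeline
report = run_pipeline(PipelineConfig(master_seed=1), output_dir="run1")
print(report.tables["comparisons_k10"][
    ["cluster_id", "mean_wt", "mean_ko", "fold_change", "p_value", "significant"]
])
```

which prints (cluster 1 is the dermis cluster in this run):

```
 cluster_id   mean_wt   mean_ko  fold_change  p_value  significant
          0  6.901042  5.826823     0.844340 0.016849        False
          1 14.233398 27.124023     1.905660 0.000000         True
          2 25.000000 20.312500     0.812500 0.000000         True
          3  8.715820  7.478841     0.858077 0.005740         True
          4  1.391602  2.563477     1.842105 0.000000         True
          5  9.375000  7.812500     0.833333 0.000000         True
          6 11.515299  8.862305     0.769611 0.000179         True
          7  9.147135  8.203125     0.896797 0.003868         True
          8  6.583659  5.623372     0.854141 0.002548         True
          9  7.137044  6.193034     0.867731 0.028235        False
```

Reading this: the dermis cluster occupies 14.2 % of the tissue pixels in
wild-type images and 27.1 % in the knockout group — a 1.91-fold increase,
recovering the 2× dermis-thickness contrast the generator was configured
with (hair-bulb carving accounts for the small deficit).  Because the
knockout dermis grows at fixed section height, the other layers' shares
shrink correspondingly.  The run directory contains the phantom and dewaxed
cubes (HDF5), false-color label maps and correlation maps (PNG), abundance
and comparison tables (CSV), and a Markdown provenance report with
parameters, seeds and output hashes.

The pipeline stages are also exposed individually:
`irsh simulate | dewax | cluster | compare | correlate`.

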