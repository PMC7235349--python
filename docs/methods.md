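# Methods

## Scope and data model

`irsh` analyzes mid-infrared hyperspectral absorbance images of
formalin-fixed paraffin-embedded (FFPE) tissue sections.  The central object
is a `SpectralImage`: a `rows × cols × n_wavenumbers` cube of absorbance
(AU) on a strictly monotonic wavenumber axis (cm⁻¹), a boolean tissue mask
and string metadata, stored in a small HDF5 container (`/axis`, `/cube`,
`/mask`, `pixel_size_um`, `/meta`).  The canonical storage orientation is
descending (4000 → 750 cm⁻¹), the usual FTIR presentation; all operations
accept either orientation and preserve it.  Spectral-range cropping is
inclusive at both endpoints; reference spectra travel as two-column
delimited text and are resampled between grids by piecewise-linear
interpolation only (no extrapolation, no splines — resolution changes are
out of scope).

## Synthetic skin phantoms

Real FFPE images from the motivating experiment are not distributable, so
the generator produces phantoms with known ground truth.  Per pixel with
tissue class ℓ:

    cube[r,c,:] = t(r,c)·E_ℓ(ν) + a(r,c)·P(ν) + B(r,c,ν) + ε

- **Geometry.**  Five horizontal layers, top to bottom: epidermis, dermis,
  hypodermis, muscle, subcutaneous fat (default WT fractions 0.10 / 0.15 /
  0.25 / 0.25 / 0.25 of the image height), with elliptical hair bulbs
  carved into the dermis.  The knockout-like group multiplies the dermis
  row count by `dermis_thickness_ratio` (default 2.0) at fixed total
  height, rescaling the other layers — mimicking dermal expansion from
  deregulated collagen fibrillogenesis.  The WT dermis fraction is kept at
  0.15 so contrasts beyond 5× remain geometrically feasible.  Total bulb
  footprint is ≈8 % of the dermis band area and scales with dermis
  thickness (anatomically, follicles span the dermis), which keeps the
  realized dermis-area ratio at the configured contrast; bulb centers are
  integers, so bulb pixel counts are placement-invariant and a null
  contrast (ratio 1.0) yields exactly equal per-image dermis percentages.
- **Endmembers `E_ℓ`.**  Sums of Gaussian/Lorentzian bands at generic
  protein and lipid assignments: amide A ≈ 3300, amide I ≈ 1660, amide II
  ≈ 1550 cm⁻¹; the collagenous dermis additionally carries the amide III
  triplet at 1330/1280/1204 cm⁻¹; lipid-rich layers carry the 1745 cm⁻¹
  ester carbonyl and 1465 cm⁻¹ CH₂ bands; hair bulbs a broad 1040 cm⁻¹
  band.  Amplitudes are plausibility choices, not measurements.  All soft
  tissues retain some amide signal — adipose tissue includes amide I/II at
  0.20/0.12 AU for its septal/stromal protein; a purely lipidic endmember
  would be unphysical and would be rejected as background by the masking
  rule (§ EMSC) because it shares no component with a tissue target.
- **Paraffin `P`.**  CH₂ scissoring doublet at 1462/1472 cm⁻¹ (Lorentzian),
  CH₃ bend at 1378 cm⁻¹, CH stretches at 2920/2850 cm⁻¹.  Per-pixel
  amplitude `a ~ N(0.5, 0.15)` truncated at 0.  The paraffin calibration
  image adds a crystallinity-like doublet-swap component so its pixel
  spectra have genuine multivariate variability for the interference PCA.
- **Thickness `t ~ N(1.0, 0.1)` truncated > 0**, emulating section
  thickness and contact variation.
- **Baseline `B`**: per-pixel random polynomial (default order 2, amplitude
  0.02 AU) in the axis coordinate scaled to [−1, 1] for conditioning.
- **Noise ε**: i.i.d. Gaussian, default sd 0.005 AU — a conservative
  mid-range SNR for bench FTIR imaging; no instrument stated figures, so it
  is a declared choice and configurable.
- **Determinism.**  One master seed; every random field (thickness,
  paraffin, baseline, noise, bulb placement) draws from its own fixed
  substream, and cohort members get derived seeds, so adding a phantom
  never perturbs earlier ones and everything is bit-reproducible.

Default acquisition grid: 4000 → 750 cm⁻¹ in 2 cm⁻¹ steps (1626 points) at
6.25 µm/pixel.  A nominal spectral resolution of 4 cm⁻¹ is compatible with
2 cm⁻¹ point spacing; the spacing is a declared choice and configurable.

What the phantoms do **not** emulate: resonant-Mie scattering, detector
noise structure, atmospheric water-vapor lines, dermal texture, partial-
volume mixing at layer boundaries.  Passing tests therefore demonstrate the
pipeline's algorithmic correctness and its behavior under the modeled
artifacts, not robustness to every artifact of real micro-spectroscopy.

## EMSC digital dewaxing

Each pixel is fit by ordinary least squares against the design
`[m | p₁..p_q | x⁰..x^order]`: a tissue target `m`, interference components
(mean paraffin spectrum plus the first `n_components` principal-component
loadings of the mean-centered paraffin calibration pixels, ordered by
explained variance, each sign-fixed so its largest-magnitude element is
positive), and polynomial baseline terms.  Defaults: 8 components,
quadratic baseline, both configurable — the component count follows
published EMSC-dewaxing practice of capturing paraffin crystallinity and
thickness variability.  The corrected spectrum `(s − Σbᵢpᵢ − Σdⱼxʲ)/c`
retains the least-squares residual: the tissue-specific deviation from the
target is exactly what downstream clustering consumes.  All processing
after dewaxing operates on the 1800–800 cm⁻¹ fingerprint crop.

Numerics: the solver is QR-based and must agree with explicit normal
equations to 1e-8 on well-conditioned designs (tested).  Rank-deficient
designs raise a collinearity error naming the offending columns — never a
silent pseudo-inverse.  A noiseless paraffin image has low-rank spectral
variation, so requesting more components than that rank is an error by
design.  Pixels with fitted `|c| < c_min` (default 0.2) are masked as
background/pure wax; an image whose mask empties out warns rather than
raises.  An optional residual ceiling can mask outlier pixels.  Atmospheric
gas interference can be emulated by appending CO₂/water-vapor proxy spectra
to the interference list; within the fingerprint crop this is largely moot.

Target choice: the default policy is the mean spectrum over unmasked
pixels.  The pipeline builds **one** basis per cohort with the pooled mean
of all images as target, so the corrected feature space — and therefore
cluster identities — is common across groups.  With a shared target the
corrected spectrum equals `m + residual/c`; it removes paraffin, baseline
and thickness exactly (to rounding) only for pixels whose tissue spectrum
lies in the span of the target, which is why the exactness tests set the
target to the pixel's own class endmember.  With the shared cohort target
the class-discriminating information survives intact in the retained
residual, which is sufficient — and verified — for segmentation and
abundance recovery.

## Common K-means

Pixels from all dewaxed images are pooled and clustered by one model, so a
cluster means the same structure in every image.  The solver is Lloyd's
algorithm with squared Euclidean distance on the EMSC-corrected absorbance
(no further normalization — the division by `c` already removed thickness
scaling), k-means++ initialization, `n_init = 20` seeded restarts with the
lowest inertia winning, convergence at max centroid displacement < 1e-6 or
300 iterations, assignment ties broken toward the lowest cluster id, and
empty clusters re-seeded to the point farthest from its current centroid.
Inertia is asserted non-increasing across iterations.  The pooled matrix is
canonicalized by a lexicographic row sort before fitting, making the fit
exactly insensitive to image order.  The solver is validated against
exhaustive partition enumeration (n ≤ 10, k ≤ 3) and cross-checked against
scikit-learn.  False-color palettes are deterministic (golden-angle hues),
so reruns produce identical maps.

For validation against phantom ground truth, cluster↔class matching is the
exact rectangular assignment maximizing the confusion-matrix diagonal
(Hungarian method); agreement is matched pixels over tissue pixels.

## Group statistics

Per cluster: group means ± SEM (sample sd / √n), fold change defined
KO/WT, and a two-sided pooled-variance Student t-test with
`df = n_WT + n_KO − 2`; p-values come from the regularized incomplete beta
function and are verified against direct quadrature of the t density to
1e-10.  Degenerate zero-variance inputs return p = 1 for equal means and
p = 0 (with a warning) otherwise — with near-perfect segmentation of
identical geometry, within-group variance can be exactly zero.  No
multiple-testing correction is applied, matching the conventional analysis
of such designs; a Welch variant sits behind a flag.  Significance default:
alpha = 0.01.

## Correlation mapping

Pixel-by-pixel Pearson correlation with a reference spectrum over a chosen
window, defaulting to the full acquired axis.  The default mode correlates
the **raw** (non-dewaxed) image against a reference that itself contains
paraffin — emulating the practice of recording the collagen reference from
a paraffin-embedded tendon section — and a `dewaxed` mode correlates
corrected spectra against the clean collagen endmember; the mode and window
are recorded on the map.  Negative correlations are preserved in `r_raw`
but clipped to 0 for display on the conventional 0 (black) – 1 (white)
scale; constant pixels are undefined and rendered as masked.  The shipped
collagen reference is synthetic (dermis band model ± paraffin); no measured
tendon spectrum is distributed.  A normalized-dot-product variant would
behave almost identically for these strongly correlated spectra; Pearson is
what is implemented.

## Pipeline and provenance

`run_pipeline` executes simulate → dewax → cluster (per k in the k-list,
default {5, 10}) → compare → correlate from a single YAML-validated config
(pydantic schema, unknown keys rejected).  Every stage seed derives from
`master_seed`; two runs with the same config are byte-identical in all CSV
outputs.  The Markdown report embeds the abundance and comparison tables,
records parameters, seeds and SHA-256 hashes of every output, verifies at
write time that referenced files exist, and re-checks that abundances sum
to 100 % per image.

## Problem sizes used in validation

Phantoms are 64×64 pixels (4096 spectra of 501 fingerprint channels) with
cohorts of 3 + 3, chosen as the smallest geometry in which all six tissue
classes are well populated and hair bulbs fit the dermis band; the
exhaustive k-means oracle runs at n ≤ 10, k ≤ 3 where full enumeration is
exact.  Fold-change recovery is validated at configured dermis contrasts
of 2.0 and 5.3 against a null cohort at 1.0.

## Known limitations

- Hard class labels: no partial-volume mixing at layer boundaries, so
  phantom segmentation is easier than real tissue.
- The shared-target EMSC leaks a thickness-scaled fraction of each class
  endmember into the interference coefficients (the per-pixel paraffin
  estimate is `a + t·β` within a class); abundance estimates are unaffected
  but raw coefficient maps should be read with this in mind.
- At extreme contrasts a small number of thin lipid pixels can still fall
  below `c_min` and be masked (<1 % in the validated configurations).
- k-means at k equal to the number of structures can split large
  homogeneous regions before separating small ones in unfavorable draws;
  the usual remedy of a larger k (e.g. 10) is supported throughout.
- n = 3 per group with a pooled t-test mirrors the conventional analysis;
  its statistical adequacy is not this package's concern.
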