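# Methods

## Spectra and preprocessing

A `Spectrum` is one subsample measurement: absorbance on a strictly
monotonic wavenumber grid (canonical internal order is ascending; instrument
exports in descending order are flipped on read). Region bounds are always
given as (high, low) cm⁻¹ pairs. Because the source instrument's data-point
spacing is not fixed by its 4 cm⁻¹ optical resolution, the grid spacing is
configurable; the default is 2 cm⁻¹ (typical for 4 cm⁻¹-resolution
exports), and `align_to_grid` linearly interpolates a cohort onto one shared
grid so that Euclidean distances between spectra are defined.

**Normalization.** Default `minmax`: the spectrum is affinely mapped to
[0, 1] over its full recorded range, removing the absorbance-scale
variation caused by uneven sample contact/thickness on the ATR crystal. An
`offset` variant (minimum subtraction only) and `none` are provided for
comparison. Whether heights should be read from normalized spectra is a
convention; here they are, which puts all features on the normalized
absorbance scale.

**Second derivative.** Savitzky–Golay, default window 9 points, polynomial
order 3 — a standard band-resolution setting at 2 cm⁻¹ spacing. The filter
is linear and exact for polynomials up to its order, so straight baselines
vanish identically; absorption bands appear as minima. Note that smoothing
attenuates derivative *amplitudes* (about 20% for an 8 cm⁻¹-wide band at the
default window); band *positions*, which are what the pipeline uses, are
unaffected. Gentler settings (e.g. window 7, order 5) recover amplitudes to
within 1% when they matter.

## Region scheme and feature extraction

The `RegionScheme` is a declarative table of baseline regions, nominal peak
positions, area splits and ratios; the shipped default encodes the standard
forage mid-IR assignments (9 regions, 18 bands, 6 region areas, the amide
split at 1575 cm⁻¹, 4 protein ratios). Peaks known to overlap their
neighbours — the 1074/1104 cm⁻¹ carbohydrate pair, amide I/II when merged,
and the α-helix (1653) / β-sheet (1629) sub-bands — default to
second-derivative localization; isolated bands to apex search. The search
window is nominal ± 8 cm⁻¹ (half the band spacing in the congested
1026/1074/1104 triplet); with no interior extremum the nominal position is
used, and ties break toward it.

All quantities are measured against a region's two-point baseline (the line
joining the spectrum at the grid nodes nearest the region endpoints):

- corrected height = spectrum − baseline at the located peak node. Heights
  are read at located, not nominal, positions by default (configurable),
  because nominal positions are only approximate band centers.
- corrected area = trapezoidal integral of spectrum − baseline over the
  region. Negative lobes are signed, never clipped — clipping would bias the
  downstream SEMs.
- the amide split cuts the region at the node nearest 1575 cm⁻¹ with both
  parts measured against the single parent baseline, so AIA + AIIA = AA
  holds to machine precision.
- ratios are computed per subsample spectrum *before* any averaging
  (mean-of-ratios), matching the observation-level statistical model. This
  is why a table's ratio row need not equal the ratio of its printed means.
- α-helix and β-sheet heights are measured against the common amide
  baseline (1710–1484 cm⁻¹), the only baseline defined for that region.

Both corrected heights and areas are exactly invariant to adding any
straight line to a spectrum, and positively homogeneous: scaling a
zero-baseline spectrum by k scales every height and area by k.

## Univariate model

Per feature,

    Y_ijk = μ + geno_i + sample(geno)_ij + ε_ijk,   sample ~ N(0, σ²_s), ε ~ N(0, σ²_e).

Estimation and testing operate on per-sample means: with b subsamples a
sample mean has variance σ²_s + σ²_e/b, so when subsample counts are
balanced (the design: b = 5) the one-way analysis of sample means is
*exactly* the REML mixed-model test for the genotype effect, with
denominator df = (total samples − genotypes). After outlier removal the
subsample counts can become mildly unbalanced, where this analysis remains
valid but is no longer minimum-variance; given ≤ a few removals per feature
out of 100 observations, the difference is negligible. (A REML fit via
statsmodels MixedLM is used as an independent cross-check in the tests, not
as the implementation.)

- **Outlier screen**: single pass, before fitting. The residual of an
  observation is its deviation from its own sample mean; the scale estimate
  is leave-one-out (externally studentized); |t| > 2.5 removes the
  observation. One pass, because iterating the screen to convergence on
  clean Gaussian data removes ever more points.
- **Tukey–Kramer**: studentized-range p-values with the unequal-n SE,
  summarized as compact letters (maximal cliques of the
  not-significantly-different graph, 'a' = highest mean). Letters derive
  from the adjusted pairwise p-values and the p column from the F-test, so
  they may disagree near α — that is expected behaviour, not a bug.
- **Contrast**: wild type vs the unweighted mean of the transgenic LS means,
  t-test on the sample stratum.
- **SEM**: reported as the largest LS-mean standard error, i.e. that of the
  smallest group (`sqrt(MSE/min nᵢ)`) — the conservative convention common
  in forage/animal-science tables, and the convention used to invert
  published SEMs into generator noise (below).
- **Normality**: Shapiro–Wilk on within-sample residuals, reported only;
  it never switches methods.
- Degenerate inputs (a constant feature, or one observation per sample
  everywhere) are flagged and their p-values reported as missing.

`subset_rerun` repeats the whole pipeline on a named subset of biological
samples; its intended use is the two-per-genotype re-analysis demonstrating
the power cost of small populations.

## Multivariate

HCA: per-sample mean spectra restricted to a region; pairwise Euclidean
distances, squared; Ward linkage by the classical (non-square-rooted)
Lance–Williams update, i.e. merge heights on the squared-distance scale,
matching R's `hclust(dist(x)^2, method="ward.D")`. Implementation note:
scipy's Ward heights on raw Euclidean distances equal the square roots of
that recursion's heights, so squaring them reproduces it exactly (verified
against an R oracle in the tests). Dendrograms export to Newick with branch
lengths on the height scale.

PCA: observations are all subsample spectra by default (per-sample means
optional) — the per-sample clouds are what group ellipses are drawn from;
HCA uses sample means to keep dendrograms legible. Columns are centered and
scaled to unit (n−1) variance; zero-variance columns cannot be scaled and
are dropped with a warning rather than aborting a batch. Components are
computed by SVD; count = min(observations − 1, variables); signs are fixed
deterministically by making each component's largest-magnitude loading
positive.

## Synthetic-data generator

The generator emulates the reference experiment: three genotypes (WT n=4,
TT8i n=5, HB12i n=11 biological samples), five subsample spectra each, grid
4000–700 cm⁻¹ at 2 cm⁻¹. Each spectrum is a sum of Gaussian bands:

- the 18 scheme bands, base amplitudes equal to the published WT group
  means; widths σ = 12 cm⁻¹, narrowed to 8 cm⁻¹ in the congested
  1026/1074/1104 triplet so that its members genuinely merge and must be
  resolved on the second derivative (likewise the amide I/α-helix/β-sheet
  complex);
- a broad O–H stretch (3350 cm⁻¹, σ = 150, amplitude 0.9), the dominant
  feature of real dried-plant ATR spectra, which anchors min–max
  normalization to a genotype-invariant maximum;
- a broad carbohydrate continuum (1160 cm⁻¹, σ = 200, amplitude 0.35)
  under the sharp CHO bands.

Genotype effects are multiplicative on band amplitudes. Sharp-band
multipliers are the ratios of published group means to WT wherever the
genotype does not share a Tukey letter with WT (rows without letters, and
'ab'-overlaps, get multiplier 1). The continuum carries a *shared*
transgenic multiplier of 1.10 (same order as the shared 1074/1104 band
effects): published data show the two silenced lines moving coherently
across the whole carbohydrate region — their PC1 loadings have one sign
almost everywhere and clustering cannot separate the two transgenic lines —
and without a shared continuum effect the sharp-band table alone places
TT8i midway between WT and HB12i, a geometry in which Ward clustering would
merge WT with TT8i instead of isolating WT.

Noise has the nested structure the model assumes: a per-sample, per-band
multiplicative random effect with relative SD 2·SEM/mean inverted from each
band's published SEM (under the SEM convention above, SD of a sample mean =
2·SEM), giving feature SEMs of the published order (≈0.003–0.01 on
normalized heights); per-subsample white noise of 5·10⁻⁴ absorbance units
(a realistic RMS for a 128-scan ATR acquisition); and a small fixed
quadratic baseline with per-subsample amplitude jitter. With all SDs zero
and unit multipliers the output is deterministic and identical across
spectra.

What the generator does **not** emulate: ATR penetration-depth wavelength
dependence, water-vapor/CO₂ lines, scattering artifacts, band-shape changes
(only amplitudes move), and any genotype effect outside the declared bands.
Passing tests therefore demonstrate the pipeline's correctness and
sensitivity under the published design and effect sizes — not instrument
robustness on raw field data. Because the generator has no path-length
artifact, the multivariate stage runs on raw aligned spectra; normalization
remains available for real data.

## Numerical and degenerate-input choices

- Region endpoints snap to the nearest grid node (bounds may fall up to one
  spacing outside the recorded range); "ca." positions likewise.
- Ratio denominators with |d| ≤ 1e−12 yield missing values with a warning.
- A failing spectrum in batch extraction is reported with its identity and
  skipped; the batch continues.
- Constant spectra cannot be min–max normalized and are rejected.
- Tukey p-values at zero MSE degenerate to 0/1 by mean equality; the
  F statistic is reported as +∞ when between-group variance is positive and
  within-group variance is numerically zero.

## Known limitations

- Exact p-values can differ in the third decimal from commercial mixed-model
  software (denominator-df conventions after unbalanced outlier removal).
- The amide I and α-helix bands (1649/1653 cm⁻¹) are 4 cm⁻¹ apart; in the
  synthetic spectra they merge into one envelope, so their measured heights
  coincide — real spectra separate them only marginally better.
- The small-population rerun reliably *reduces* the number of detected
  effects, but with effects and noise at the published scale roughly half
  of the planted effects remain detectable even at two samples per
  genotype; a stronger "most effects vanish" outcome would require weaker
  effects or noisier samples than the published tables imply.
- The published per-feature means, SEMs and PCA variance percentages are
  properties of undeposited raw spectra and are not reproduction targets;
  the pipeline reproduces the design, the directions and orders of
  magnitude of the effects, and the qualitative multivariate geometry.
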