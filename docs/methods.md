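# Methods

This note documents the models, parameter choices and numerical decisions
behind `msiregion`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Data model

A sample is one tissue section's set of pixel spectra with 1-based imzML
coordinates. Acquisition order is taken to be the imzML spectrum storage
order — the only ordering observable in the format, and the order
line-scanning instruments write. All drift modelling is a function of this
acquisition index. Intensities are read at stored precision (32-bit floats
are common) and processed in 64-bit.

Lipid identities use shorthand nomenclature: `PC 32:0` is total carbons :
total double bonds; chain-resolved names like `PE 18:0/22:6` are summed over
chains (40:6). Names that do not follow the grammar keep their free-text
name and take the class from the library's explicit class column. Library
m/z values are those of the observed species — the LC-MS/MS table already
encodes the adduct, so the package performs no adduct enumeration.

## Peak processing

Peak detection on profile spectra is local-maximum picking with noise
estimated as 1.4826 x the median absolute deviation of the spectrum and an
SNR threshold of 3. Centroided input degenerates to thresholding: every
stored non-zero point is a peak (a centroid spectrum carries no baseline
from which to estimate noise). Cross-sample alignment pools apex m/z from
every pixel of every sample and performs a single greedy left-to-right merge
at 5 ppm: a value joins the open bin if its ppm distance to the running bin
mean is within tolerance, otherwise it opens a new bin; a final pass merges
any residual centers closer than the tolerance so bins never overlap. A
single global pass guarantees one feature list shared by all samples (the
alignment contract); matrices from one call always have identical columns.

## Annotation

Features are matched to the library at a fixed 10 mDa tolerance (a Da
tolerance, not ppm, matching the accuracy regime of TOF data across the
300–1300 m/z range); the smallest absolute error wins, exact ties are kept
and flagged ambiguous. Positive-mode annotations to PI and PS are removed —
these classes ionize efficiently only in negative mode, so a positive-mode
accurate-mass hit is almost certainly a different species. Manual exclusion
windows (default ±5 ppm) remove known noisy or background images; every
removal is logged with counts so filtering is auditable. Saturation splits
use total double bonds with a configurable threshold, default ≤ 1
("saturated" groups mono-unsaturated with fully saturated species; the
boundary is a documented choice, not a community standard).

## Sparse LOESS normalization

Ion-count drift is multiplicative, so the trend is fitted to log intensity:
for each (sample, feature) pair, a local polynomial regression (degree 2,
tricube weights) of log intensity on acquisition index over the non-zero
pixels only. The local window covers `span x n_pixels` points (default span
0.10, counting all pixels of the sample, not only tissue pixels), clamped to
at least degree + 2 points; for speed the trend is evaluated on up to 100
quantile points of the support and linearly interpolated, which is far
denser than the smoothing bandwidth. Fitting in log space keeps the trend
positive everywhere — direct-space quadratics can dip below zero where
tissue transitions to the off-tissue margin, and clamping such values would
amplify noise catastrophically. An epsilon guard (1e-8 x reference) remains
as a safety net.

Normalization divides each non-zero intensity by the *shape* of its trend
(the fit normalized to its own geometric mean). The feature's per-sample
abundance level is deliberately not forced to a global reference: rescaling
every feature to the pooled median would erase genuine between-sample
biology (a planted log2 effect of -1.0 was recovered at about -0.6 under
that scheme). Instead, samples are aligned by one robust technical scale
factor each — the median over features of the sample's non-zero-median
intensity relative to the pooled per-feature reference median. A group
effect on a handful of lipids cannot move the median of a hundred level
ratios, so scale correction and biology preservation coexist. Zero pixels
are never modified in either direction (the "sparse" contract): the
correction cannot invent signal off tissue or erase a compound's spatial
pattern. Features with fewer non-zero pixels than the minimum window pass
through unchanged and are logged.

The drift report quantifies residual technical variance identically for any
processing stage: per sample, the OLS slope of per-pixel TIC (sum over the
annotated features; non-zero pixels only) against acquisition index, plus a
scale-free relative slope (slope / median TIC) so stages that rescale the
data are comparable; across samples, the relative range (max - min)/median
of the per-sample median TICs.

## Segmentation

Each sample is segmented independently (no cross-sample embedding):
log(1 + x), per-feature z-scoring clipped at ±10, PCA to 10 components, a
k = 20 Euclidean nearest-neighbour graph (self included) reweighted by the
Jaccard overlap of neighbour sets, pruning below 1/15, and Leiden community
detection on the resolution-parametrized modularity objective (resolution
0.9, seeded). These defaults reconstruct the conventions of the single-cell
clustering toolkits this approach is borrowed from; all are overridable.
Labels are relabelled by decreasing cluster size from 1 and are
deterministic given input and seed. Off-tissue pixels are kept by default —
they form their own clusters — and a tissue mask can exclude them.

Cluster-defining lipids are ranked per cluster by mean median-scaled
intensity (each feature scaled by the global median of its non-zero pixels);
the top 5 are reported with mean log2 per-pixel intensity. Clusters are
mapped to morphological regions through a curated YAML table; unmapped
clusters become `unassigned`, and `unassigned`/`off_tissue` never enter
group statistics. On synthetic data the mapping can be derived from the
planted truth by majority vote, standing in for the histology-guided manual
assignment used with real sections.

## Region statistics

The per-sample, per-region, per-lipid summary is the mean over *all* pixels
of the region (zeros included) — the quantity a region integrates — and is
log2-transformed for approximate normality at the replicate level.
Differential testing is a one-way ANOVA over the sex x treatment cells
(cells with fewer than 2 replicates are dropped; lipids with fewer than 2
usable cells are skipped with a logged reason) followed by Tukey HSD; each
pairwise contrast is reported in both orientations with anti-symmetric
log2 fold change and the Tukey-adjusted p. The volcano rule flags
significance at adjusted p < 0.05 and high effect at |log2 FC| > 0.5
(strict inequality at the boundary). No additional across-lipid FDR is
applied to the volcano by default.

Class enrichment compares the fold changes of a lipid set (class x
saturation, e.g. "PE (Unsat.)", minimum 3 members) against all non-member
lipids with a one-sided two-sample Kolmogorov–Smirnov statistic
D+ = sup [F_background - F_members], run in both directions ("increase",
"decrease"), with Benjamini–Hochberg FDR across all set x direction tests
within a region/contrast. When the number of equal-size subsets C(N, m) is
at most 100,000 the p-value is the exact permutation tail probability by
enumeration; otherwise scipy's one-sided two-sample KS p is used. The
Monte-Carlo benchmark confirms the large-set path holds its nominal type-I
error (~5% at alpha = 0.05 for 10-of-100 sets); note the statistic is
discrete for small sets, so null p-values are calibrated at nominal levels
rather than continuously uniform.

## Synthetic data generator

The generator emulates the structure of a replicated lung MSI study: a
120x120 raster with an off-tissue margin (width 10), one airway — lumen disk
(radius 14), epithelium ring (thickness 7), optional basement-membrane
ring — in an alveolar field; 100 annotatable lipid channels spread over the
scan range plus 30 matrix-background channels; 15 designated marker lipids
per region elevated 8-fold over a lognormal baseline, with mild (~25%
lognormal) region variation on all other channels. Intensities follow
`region mean x group effect x sample scale x drift(acquisition index) x
lognormal noise (sigma 0.35)`, acquisition row-major, fully reproducible
from one seed.

Key emulation choices:

* **Zero inflation is abundance-dependent.** The per-channel dropout
  probability (default 0.20) is scaled inversely with the channel's
  pre-effect regional abundance, capped at 0.95 — ion-count zeros concentrate
  in weak signals, and a marker lipid in its home region essentially never
  drops out. Dropout is kept independent of the planted group effects so the
  effect table is the exact ground truth of the measured per-pixel means.
* **Drift and scale.** Multiplicative linear drift of amplitude 0.5 across
  the acquisition (sinusoidal available); per-sample scale ladders with a
  2x max/min spread, randomly permuted across samples because acquisition
  order is randomized in the emulated study design. Matrix-background
  channels carry their own independent scale ladder and attenuated drift
  (factor 0.3) — matrix deposition varies per slide and its ion background
  does not follow tissue-lipid drift. This is what makes plain TIC
  normalization (computed over the full spectrum, reported over annotated
  lipids) correct within-run drift only partially and inter-sample spread
  poorly, while sparse LOESS corrects both.
* **Effects.** The default template plants decreases in the exposed female
  group's alveolar region: -1.0 log2 on ten polyunsaturated PE lipids and
  -0.7 on six PG lipids, with three replicates per sex x treatment cell.

What the generator does not emulate: isotope envelopes and peak shapes,
chemically structured matrix-cluster noise, spatial autocorrelation of noise
within regions (pixels are conditionally independent), partial-volume mixing
at region boundaries, and section-to-section morphological variability.
Passing benchmarks on this generator therefore demonstrates correctness of
the algorithms under the stated noise model, not performance on real tissue,
where boundary mixing and correlated noise will lower segmentation accuracy
and inflate replicate variance.

## Benchmarks and problem sizes

The standardized benchmarks (also run by `scripts/acceptance.py`) use: one
120x120 section for segmentation recovery (scored as ARI after merging
clusters to regions by majority truth label, the analogue of manual region
assignment); six 100x100 samples for drift correction; 1000 null simulations
for KS calibration; and twelve 60x60 sections (2 treatments x 2 sexes x 3
replicates) for end-to-end effect recovery. These sizes keep the full run
around a minute on one CPU while leaving all statistical conclusions stable
across seeds.

## Known limitations

* Per-feature trend fitting absorbs any biology that varies smoothly along
  acquisition order *within* a sample; region contrasts survive because
  raster rows interleave regions at a scale far below the LOESS span.
* Tukey HSD assumes homoscedastic cells; with n = 3 per cell the test is
  valid but underpowered, and single-replicate cells are dropped rather
  than modelled.
* The KS enrichment statistic treats lipids as exchangeable; correlated
  fold changes within a class make the test anti-conservative in principle
  (shared-variance effects are not modelled).
* Mass recalibration, isotope deconvolution and MS/MS-based identification
  are out of scope; the annotation step trusts the LC-MS/MS library.
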