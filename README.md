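# msiregion

Region-resolved statistics for multi-replicate MALDI mass spectrometry
imaging (MSI) lipidomics.

MSI acquires a full mass spectrum at every pixel of a tissue raster, but
comparing lipid abundance *across biological replicates* is hard: detector
response drifts over the hours of a raster run, absolute signal levels differ
between slides, and morphological regions (airway epithelium, alveolar
parenchyma, ...) sit at different places in every section. `msiregion`
implements a complete workflow for lung-section lipid imaging built around
three ideas:

1. **Sparse LOESS normalization.** For each annotated lipid and each sample,
   a locally weighted polynomial regression of log intensity against
   acquisition index is fitted on the non-zero pixels only, with the local
   window sized to ~10% of the sample's pixel count. Dividing by the shape of
   this trend removes within-run drift; one robust per-sample scale factor
   (the median over lipids of the sample's level relative to the pooled
   reference median) aligns samples without erasing genuine biological
   differences in individual lipids. Zero pixels are never touched.
2. **Unsupervised segmentation into tissue regions.** Pixels are clustered
   per sample from annotated-lipid intensities: log(1+x), per-feature
   z-scoring, PCA, a k-nearest-neighbour graph reweighted by shared-neighbour
   (Jaccard) overlap, and modularity community detection (Leiden, resolution
   0.9). Clusters are mapped to morphological regions via a curated
   cluster-to-region table, the digital analogue of comparing against
   H&E-stained serial sections.
3. **Region-level statistics.** Per sample, region and lipid, the per-pixel
   mean abundance is log2-transformed; treatments are compared by one-way
   ANOVA over the sex x treatment cells with Tukey HSD contrasts and a
   volcano rule (p < 0.05, |log2 FC| > 0.5), and coordinated class-level
   shifts are tested by a one-sided two-sample Kolmogorov–Smirnov statistic
   on fold changes (lipid class x saturation sets vs all other lipids) with
   Benjamini–Hochberg FDR.

Upstream, the package reads imzML/ibd images (continuous and processed mode),
detects and bins peaks at 5 ppm into one feature list shared by all samples,
and annotates features against an LC-MS/MS-validated lipid library at a
10 mDa tolerance with ionization-mode filtering (no PI/PS in positive mode)
and manual exclusion windows.

A first-class synthetic-data generator plants lung-like region geometry,
per-region lipid profiles, acquisition drift, slide-to-slide scale
differences, matrix-background channels, zero inflation and group x sex
effect sizes — with exact ground truth — so every stage of the workflow is
verifiable end to end.

## Worked example

Six synthetic 100x100-pixel lung sections with linear acquisition drift and a
2x slide-to-slide scale spread; normalize, quantify residual technical
variance, and segment one section:

```python
import numpy as np
from msiregion import (
    SyntheticConfig, generate_feature_matrices,
    sparse_loess_normalize, drift_report,
    segment_sample, evaluate_segmentation,
)

cfg = SyntheticConfig(width=100, height=100, groups=("control",),
                      sexes=("F", "M"), n_samples_per_cell=3, seed=2)
matrices, truth = generate_feature_matrices(cfg)
lipids = np.flatnonzero(~truth.background_features)
raw = [m.subset_features(lipids) for m in matrices]

normalized, fits = sparse_loess_normalize(raw, span_fraction=0.10)
report = drift_report({"raw": raw, "loess": normalized})
print(report.per_stage.to_string(index=False))

result = segment_sample(normalized[0], resolution=0.9, k=20, seed=42)
scores = evaluate_segmentation(result.labels, truth.region_labels[result.sample_id])
print(f"clusters: {result.n_clusters}, region ARI after merge: {scores['merged_ari']:.3f}")
```

Output:

```
stage  median_tic_rel_range
  raw              0.704292
loess              0.004107
clusters: 17, region ARI after merge: 1.000
```

The raw sections' median total ion currents span a 70% relative range
(slide-to-slide scale differences); after sparse LOESS the spread is 0.4%.
Community detection finds 17 pixel clusters; merging clusters to their
majority planted region recovers the airway lumen, airway epithelium,
alveolar field and off-tissue margin with an adjusted Rand index of 1.0.

## Command line

```bash
msiregion simulate --config synth.yaml --out data/      # imzML + truth tables
msiregion run --config pipeline.yaml                    # full pipeline
msiregion annotate --library lib.csv --peaks peaks.csv --mode positive --out ann.csv
```

`msiregion run` orchestrates import/simulate -> peak alignment -> annotation
-> normalization -> segmentation -> statistics from one YAML config, writing
per-stage outputs and a provenance manifest (SHA-256 hashes, seed, version)
so a rerun with the same config and seed reproduces identical outputs.

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults, the
synthetic generator's scope, numerical choices and known limitations.
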