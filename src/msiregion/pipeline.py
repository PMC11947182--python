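"""End-to-end orchestration: import/simulate -> peaks -> annotate ->
normalize -> segment -> stats, driven by one validated config.

Every stage writes its outputs under the run directory and registers them in
a JSON manifest with SHA-256 hashes, package versions and the seed, so a
rerun with the same config and seed reproduces identical hashes for the
deterministic stages.  The single global seed is fanned out to per-stage
seeds through ``numpy.random.SeedSequence([seed, stage_index])`` so stages
are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .annotate import annotate_features, annotation_table, summarize_annotation_classes
from .io import (
    load_annotation_library,
    load_exclusion_list,
    load_region_map,
    load_sample_metadata,
    read_imzml,
)
from .normalize import drift_report, sparse_loess_normalize, tic_normalize
from .peaks import align_samples, build_feature_matrix
from .segment import assign_regions, export_label_raster, segment_sample, top_cluster_lipids
from .stats import (
    build_lipid_sets,
    classify_volcano,
    differential_anova,
    ks_class_enrichment,
    summarize_regions,
)
from .synthetic import SyntheticConfig, evaluate_segmentation, generate_dataset, majority_region_map

logger = logging.getLogger("msiregion")

_STAGES = ("simulate", "import", "peaks", "annotate", "normalize", "segment", "stats")

_REQUIRED_KEYS = {
    "out_dir": None,
    "seed": None,
    "ppm": 5.0,
    "snr": 3.0,
    "tol_mda": 10.0,
    "span": 0.10,
    "k": 20,
    "prune": 1 / 15,
    "pca_dims": 10,
    "resolution": 0.9,
    "p_cut": 0.05,
    "lfc_cut": 0.5,
    "saturated_max_db": 1,
}


@dataclass
class PipelineConfig:
    """Validated stage parameters for one pipeline run."""

    out_dir: Path
    seed: int
    ppm: float = 5.0
    snr: float = 3.0
    tol_mda: float = 10.0
    span: float = 0.10
    k: int = 20
    prune: float = 1 / 15
    pca_dims: int = 10
    resolution: float = 0.9
    p_cut: float = 0.05
    lfc_cut: float = 0.5
    saturated_max_db: int = 1
    centroided: bool = True
    # inputs: either a simulate config or an imzML manifest + library
    simulate: Optional[SyntheticConfig] = None
    imzml_manifest: Optional[Path] = None  # CSV: sample_id, path, mode, group, sex, run_order
    library_path: Optional[Path] = None
    exclusion_path: Optional[Path] = None
    region_map_path: Optional[Path] = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not (0 < self.span <= 1):
            raise ValueError("span must be in (0, 1]")
        if self.ppm <= 0 or self.snr <= 0 or self.tol_mda < 0:
            raise ValueError("ppm and snr must be positive; tol_mda non-negative")
        if self.k <= 0 or self.pca_dims < 1:
            raise ValueError("k and pca_dims must be positive")
        if self.simulate is None and self.imzml_manifest is None:
            raise ValueError("config must provide either a simulate block or an imzml manifest")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        for key, default in _REQUIRED_KEYS.items():
            if key not in raw:
                if default is None:
                    raise KeyError(f"pipeline config missing required key {key!r}")
                raw[key] = default
        sim = raw.pop("simulate", None)
        known = {f for f in cls.__dataclass_fields__}
        extra = set(raw) - known
        if extra:
            raise KeyError(f"unknown pipeline config key(s): {sorted(extra)}")
        if sim is not None:
            effects = sim.pop("effects", None)
            sim = SyntheticConfig(**sim)
            if effects is not None:
                from .synthetic import Effect

                sim.effects = [Effect(**e) for e in effects]
        return cls(simulate=sim, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _stage_seed(seed: int, stage: str) -> int:
    idx = _STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return the provenance manifest."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "outputs": {},
    }

    def register(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    def fail(stage: str, exc: Exception) -> Exception:
        return RuntimeError(f"pipeline stage {stage!r} failed: {exc}")

    # --- simulate / import -------------------------------------------------
    truth = None
    try:
        if config.simulate is not None:
            sim = config.simulate
            sim = SyntheticConfig(**{**sim.__dict__, "seed": _stage_seed(config.seed, "simulate")})
            sim.effects = config.simulate.effects
            samples, truth = generate_dataset(sim)
            library = truth.library
            truth.effect_table.to_csv(out / "truth_effects.csv", index=False)
            register("truth_effects", out / "truth_effects.csv")
            manifest["stages"]["simulate"] = {"n_samples": len(samples), "seed": sim.seed}
        else:
            meta = load_sample_metadata(config.imzml_manifest)
            samples = [
                read_imzml(
                    row["path"],
                    sample_id=row["sample_id"],
                    ionization_mode=row["ionization_mode"],
                    group=row["group"],
                    sex=row["sex"],
                    run_order=int(row["run_order"]),
                )
                for _, row in meta.iterrows()
            ]
            library = load_annotation_library(config.library_path)
            manifest["stages"]["import"] = {"n_samples": len(samples)}
    except Exception as exc:  # noqa: BLE001 - stage-tagged propagation
        raise fail("simulate/import", exc) from exc

    # --- peaks -------------------------------------------------------------
    try:
        bins = align_samples(samples, config.ppm, config.snr, config.centroided)
        matrices = build_feature_matrix(samples, bins, config.snr, config.centroided)
        manifest["stages"]["peaks"] = {"n_bins": len(bins)}
    except Exception as exc:
        raise fail("peaks", exc) from exc

    # --- annotate ----------------------------------------------------------
    try:
        exclusions = (
            load_exclusion_list(config.exclusion_path) if config.exclusion_path else ()
        )
        mode = samples[0].ionization_mode
        annotations = annotate_features(
            bins, library, mode, config.tol_mda * 1e-3, exclusions, config.saturated_max_db
        )
        ann_df = annotation_table(annotations)
        ann_df.to_csv(out / "annotations.csv", index=False)
        register("annotations", out / "annotations.csv")
        summarize_annotation_classes(annotations).to_csv(
            out / "annotation_summary.csv", index=False
        )
        register("annotation_summary", out / "annotation_summary.csv")
        manifest["stages"]["annotate"] = {"n_annotations": len(annotations)}
    except Exception as exc:
        raise fail("annotate", exc) from exc

    # --- normalize ---------------------------------------------------------
    try:
        ann_cols = sorted(
            {int(np.argmin(np.abs(bins.centers - a.feature_mz))) for a in annotations}
        )
        ann_mask = np.zeros(len(bins), dtype=bool)
        ann_mask[ann_cols] = True
        tic = [tic_normalize(m) for m in matrices]
        annotated = [m.subset_features(np.asarray(ann_cols)) for m in matrices]
        loess, _fits = sparse_loess_normalize(annotated, span_fraction=config.span)
        report = drift_report(
            {
                "raw": [m.subset_features(np.asarray(ann_cols)) for m in matrices],
                "tic": [m.subset_features(np.asarray(ann_cols)) for m in tic],
                "loess": loess,
            }
        )
        report.per_sample.to_csv(out / "drift_per_sample.csv", index=False)
        report.per_stage.to_csv(out / "drift_per_stage.csv", index=False)
        register("drift_per_sample", out / "drift_per_sample.csv")
        register("drift_per_stage", out / "drift_per_stage.csv")
        manifest["stages"]["normalize"] = {"n_annotated_features": len(ann_cols)}
    except Exception as exc:
        raise fail("normalize", exc) from exc

    # --- segment -----------------------------------------------------------
    try:
        seg_seed = _stage_seed(config.seed, "segment")
        region_map = (
            load_region_map(config.region_map_path) if config.region_map_path else None
        )
        region_labels = {}
        seg_rows = []
        for m in loess:
            result = segment_sample(
                m,
                k=config.k,
                prune=config.prune,
                pca_dims=config.pca_dims,
                resolution=config.resolution,
                seed=seg_seed,
            )
            if region_map is not None and m.sample_id in region_map:
                mapping = region_map[m.sample_id]
            elif truth is not None:
                # synthetic runs: majority-truth mapping stands in for the
                # manual H&E-guided cluster-to-region assignment
                mapping = majority_region_map(result.labels, truth.region_labels[m.sample_id])
            else:
                mapping = {}
            regions = assign_regions(result, mapping)
            region_labels[m.sample_id] = regions
            raster = export_label_raster(m, result, regions)
            raster.to_csv(out / f"segmentation_{m.sample_id}.tsv", sep="\t", index=False)
            seg_rows.append({"sample_id": m.sample_id, "n_clusters": result.n_clusters})
            markers = top_cluster_lipids(m, result.labels, annotations)
            markers.to_csv(out / f"markers_{m.sample_id}.csv", index=False)
        manifest["stages"]["segment"] = {"per_sample": seg_rows, "seed": seg_seed}
    except Exception as exc:
        raise fail("segment", exc) from exc

    # --- stats -------------------------------------------------------------
    try:
        summaries = summarize_regions(loess, region_labels, annotations)
        summaries.to_csv(out / "region_summaries.csv", index=False)
        register("region_summaries", out / "region_summaries.csv")
        results = differential_anova(summaries)
        if not results.empty:
            results = classify_volcano(results, config.p_cut, config.lfc_cut)
            sets = build_lipid_sets(annotations)
            enrichment = ks_class_enrichment(results, sets)
            results.to_csv(out / "volcano.csv", index=False)
            register("volcano", out / "volcano.csv")
            enrichment.to_csv(out / "enrichment.csv", index=False)
            register("enrichment", out / "enrichment.csv")
        manifest["stages"]["stats"] = {"n_tests": int(len(results))}
    except Exception as exc:
        raise fail("stats", exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# study-condition benchmarks
# ---------------------------------------------------------------------------
# Standardized end-to-end runs on the default synthetic study conditions,
# used by the acceptance machinery and reproducible from a single seed.

def benchmark_segmentation(seed: int = 1) -> dict:
    """Normalize -> segment one default 120x120 synthetic section and score
    region recovery against the planted truth."""
    from .normalize import sparse_loess_normalize
    from .segment import segment_sample
    from .synthetic import generate_feature_matrices

    cfg = SyntheticConfig(
        n_samples_per_cell=1, groups=("control",), sexes=("F",), seed=seed
    )
    mats, truth = generate_feature_matrices(cfg)
    m = mats[0]
    sub = m.subset_features(np.flatnonzero(~truth.background_features))
    norm, _ = sparse_loess_normalize([sub])
    result = segment_sample(norm[0], seed=seed + 1)
    ev = evaluate_segmentation(result.labels, truth.region_labels[m.sample_id])
    ev["n_pixels"] = m.n_pixels
    ev["n_clusters"] = result.n_clusters
    return ev


def benchmark_drift_correction(seed: int = 2) -> dict:
    """Six 100x100 synthetic samples with linear drift (amplitude 0.5) and a
    2x inter-sample scale spread: quantify residual drift for raw, TIC and
    sparse-LOESS processing on the annotated channels."""
    from .normalize import drift_report, sparse_loess_normalize, tic_normalize
    from .synthetic import generate_feature_matrices

    cfg = SyntheticConfig(
        width=100, height=100, groups=("control",), sexes=("F", "M"),
        n_samples_per_cell=3, seed=seed,
    )
    mats, truth = generate_feature_matrices(cfg)
    ann_idx = np.flatnonzero(~truth.background_features)
    raw_ann = [m.subset_features(ann_idx) for m in mats]
    # TIC scaling uses the full spectrum (annotated + matrix background),
    # while drift is reported on the annotated channels, as in QC practice
    tic_ann = [tic_normalize(m).subset_features(ann_idx) for m in mats]
    loess, _ = sparse_loess_normalize(raw_ann)
    report = drift_report({"raw": raw_ann, "tic": tic_ann, "loess": loess})
    slopes = report.per_sample.pivot(
        index="sample_id", columns="stage", values="relative_slope"
    )
    ranges = report.per_stage.set_index("stage")["median_tic_rel_range"]
    reduction = 1 - slopes["loess"].abs() / slopes["raw"].abs()
    return {
        "n_pixels_per_sample": mats[0].n_pixels,
        "n_samples": len(mats),
        "min_slope_reduction": float(reduction.min()),
        "loess_rel_range": float(ranges["loess"]),
        "tic_rel_range": float(ranges["tic"]),
        "raw_rel_range": float(ranges["raw"]),
        "slopes": slopes,
    }


def benchmark_ks_calibration(seed: int = 3, n_sims: int = 1000) -> dict:
    """Type-I error of the one-sided KS enrichment test at alpha = 0.05 for
    a 10-of-100 lipid set drawn from the background distribution."""
    from .stats import ks_enrichment_test

    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    rejections = 0
    for _ in range(n_sims):
        x = rng.normal(0, 1, 100)
        _, p = ks_enrichment_test(x[:10], x[10:], "increase", exact_limit=0)
        rejections += p < 0.05
    return {"n_sims": n_sims, "type_i_error": rejections / n_sims}


def benchmark_effect_recovery(seed: int = 7) -> dict:
    """Full normalize -> segment -> stats run on 12 synthetic replicates
    (2 treatments x 2 sexes x 3 sections, 60x60 pixels) with the default
    planted alveolar decreases; scores recovery of the -1.0 log2 set."""
    from .annotate import LipidAnnotation, classify_saturation
    from .normalize import sparse_loess_normalize
    from .segment import segment_sample
    from .stats import (
        build_lipid_sets,
        classify_volcano,
        differential_anova,
        ks_class_enrichment,
        summarize_regions,
    )
    from .synthetic import generate_feature_matrices

    cfg = SyntheticConfig(
        width=60, height=60, border=6, lumen_radius=8.0,
        epithelium_thickness=4.0, seed=seed,
    )
    mats, truth = generate_feature_matrices(cfg)
    ann_idx = np.flatnonzero(~truth.background_features)
    loess, _ = sparse_loess_normalize([m.subset_features(ann_idx) for m in mats])
    annotations = []
    for i, e in enumerate(truth.library.entries):
        a = LipidAnnotation(float(truth.feature_mz[i]), e, 0.0)
        a.saturation_category = classify_saturation(a)
        annotations.append(a)
    region_labels = {}
    for m in loess:
        result = segment_sample(m, seed=seed + 11)
        mapping = majority_region_map(
            result.labels, truth.region_labels[m.sample_id]
        )
        region_labels[m.sample_id] = assign_regions(result, mapping)
    summaries = summarize_regions(loess, region_labels, annotations)
    results = classify_volcano(differential_anova(summaries))
    contrast = results[
        (results.contrast == "F:HDM+O3 vs F:control")
        & (results.region == "alveolar_epithelium")
    ]
    planted = truth.effect_table
    target = planted.loc[planted.log2_effect == -1.0, "lipid"].tolist()
    sel = contrast[contrast.lipid.isin(target)]
    enrichment = ks_class_enrichment(contrast, build_lipid_sets(annotations))
    hit = enrichment[
        (enrichment.set_id == "PE (Unsat.)") & (enrichment.direction == "decrease")
    ]
    return {
        "n_planted": len(target),
        "n_recovered": int(len(sel)),
        "n_significant_high_effect": int((sel.significant & sel.high_effect).sum()),
        "median_abs_lfc_error": float(np.median(np.abs(sel.log2_fc + 1.0))),
        "median_lfc": float(sel.log2_fc.median()),
        "enrichment_fdr_q": float(hit.fdr_q.iloc[0]) if len(hit) else float("nan"),
        "results": results,
    }
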