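"""Ground-truthed synthetic MSI datasets emulating a lung-section study.

The generator plants the structure the analysis stack is meant to recover:

* a 2-D raster with an off-tissue margin, one airway (lumen disk plus an
  epithelium ring, optionally a basement-membrane ring) embedded in an
  alveolar parenchyma field;
* per-region lipid abundance profiles with designated marker lipids;
* multiplicative intensity drift over acquisition order (detector response
  changes during a raster run);
* per-sample global scale factors (slide-to-slide differences);
* matrix-background channels with their own scale factors and attenuated
  drift — matrix deposition varies per slide and its ion background does not
  follow the tissue-lipid drift, which is what makes plain TIC normalization
  insufficient between samples;
* per-feature zero inflation (dropout);
* group x sex effects of configurable log2 size on chosen lipid sets.

Intensities follow ``region_mean x group_effect x sample_scale x
drift(acquisition index) x lognormal noise``, then are zeroed with the
dropout probability.  Acquisition order is row-major.  Everything is
reproducible from the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import AnnotationLibrary, LibraryEntry, MSISample, PixelSpectrum
from .peaks import FeatureMatrix

logger = logging.getLogger("msiregion")

REGION_OFF = "off_tissue"
REGION_LUMEN = "airway_lumen"
REGION_EPITHELIUM = "airway_epithelium"
REGION_BASEMENT = "basement_membrane"
REGION_ALVEOLAR = "alveolar_epithelium"


@dataclass
class Effect:
    """A planted group x sex effect on a lipid set within one region."""

    lipids: list[str]
    region: str
    group: str
    log2_effect: float
    sex: Optional[str] = None  # None applies to both sexes


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic generator.

    Defaults mirror the emulated study: 120x120 pixel sections, 100
    LC-MS/MS-annotatable lipid features plus matrix-background channels,
    linear multiplicative drift of amplitude 0.5 across the acquisition, a
    2x inter-sample scale spread, ~20% zero inflation on tissue, three
    replicates per sex and treatment cell, and a planted decrease of -1.0
    log2 units on ten unsaturated-PE lipids (with a smaller PG decrease) in
    the alveolar region of the exposed female group.
    """

    width: int = 120
    height: int = 120
    border: int = 10
    lumen_radius: float = 14.0
    epithelium_thickness: float = 7.0
    basement_thickness: float = 0.0  # 0 disables the basement-membrane ring
    n_features: int = 100
    n_background: int = 30
    n_markers_per_region: int = 15
    marker_fold: float = 8.0
    noise_sigma: float = 0.35
    dropout: float = 0.20
    off_tissue_dropout: float = 0.90
    background_dropout: float = 0.05
    off_tissue_attenuation: float = 0.02
    background_off_tissue_fold: float = 2.0
    drift_kind: str = "linear"  # "linear" | "sinusoidal" | "none"
    drift_amplitude: float = 0.5
    background_drift_factor: float = 0.3
    sample_scale_spread: float = 2.0
    background_scale_spread: float = 2.0
    groups: tuple[str, str] = ("control", "HDM+O3")
    sexes: tuple[str, str] = ("F", "M")
    n_samples_per_cell: int = 3
    ionization_mode: str = "negative"
    scan_range: tuple[float, float] = (300.0, 900.0)
    mz_jitter_ppm: float = 1.5
    effects: Optional[list[Effect]] = None  # None -> default template
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.dropout, self.off_tissue_dropout, self.background_dropout):
            if not (0 <= p <= 1):
                raise ValueError("dropout probabilities must lie in [0, 1]")
        interior = min(self.width, self.height) / 2 - self.border
        if self.lumen_radius + self.epithelium_thickness + self.basement_thickness >= interior:
            raise ValueError("airway geometry exceeds the tissue interior (overlapping regions)")
        if self.drift_kind not in ("linear", "sinusoidal", "none"):
            raise ValueError(f"unknown drift kind {self.drift_kind!r}")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the synthetic samples."""

    region_labels: dict[str, np.ndarray]  # sample_id -> per-pixel region (acq order)
    drift: dict[str, np.ndarray]  # sample_id -> per-pixel drift factor
    region_means: dict[str, pd.DataFrame]  # sample_id -> regions x features
    effect_table: pd.DataFrame
    library: AnnotationLibrary
    feature_mz: np.ndarray  # tissue features then background channels
    background_features: np.ndarray  # boolean mask over feature axis
    sample_metadata: pd.DataFrame
    spectra: dict[str, np.ndarray] = field(default_factory=dict)  # dense truth matrices


# ---------------------------------------------------------------------------
# library construction
# ---------------------------------------------------------------------------

_CLASS_PLAN: list[tuple[str, int, tuple[int, ...]]] = [
    # (class, count, double-bond cycle)  -- carbons assigned per class below
    ("PC", 24, (0, 1, 2, 4, 6)),
    ("PE", 20, (0, 1, 4, 5, 6)),  # majority polyunsaturated
    ("PG", 10, (0, 1, 2, 3)),
    ("PI", 8, (2, 3, 4)),
    ("PS", 6, (1, 4)),
    ("SM", 8, (1, 2)),
    ("LPC", 4, (0, 1)),
    ("LPE", 4, (0, 4)),
    ("FA", 6, (0, 4, 6)),
    ("Cer", 4, (1, 2)),
    ("TG", 6, (1, 2, 3)),
]

_CLASS_CARBONS = {
    "PC": 34, "PE": 38, "PG": 34, "PI": 36, "PS": 38, "SM": 42,
    "LPC": 18, "LPE": 18, "FA": 20, "Cer": 34, "TG": 52,
}


def build_synthetic_library(config: SyntheticConfig) -> tuple[AnnotationLibrary, np.ndarray]:
    """Deterministic lipid library for ``n_features`` tissue channels.

    Lipid identities cycle through a fixed class plan; m/z values are evenly
    spread over the scan range with a small seeded jitter, guaranteeing
    pairwise separation far beyond the matching tolerance.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    per_class = []
    for cls, count, dbs in _CLASS_PLAN:
        per_class.append(
            [
                (cls, _CLASS_CARBONS[cls] + 2 * (i // len(dbs)), dbs[i % len(dbs)])
                for i in range(count)
            ]
        )
    # round-robin across classes so every library size samples all classes
    depth = max(len(e) for e in per_class)
    interleaved = [
        entries[i] for i in range(depth) for entries in per_class if i < len(entries)
    ]
    plan = []
    offset = 0
    while len(plan) < config.n_features:
        plan.extend((cls, c + offset, db) for cls, c, db in interleaved)
        offset += 40  # recycle with shifted carbon counts to keep names unique
    plan = plan[: config.n_features]

    lo, hi = config.scan_range
    span = hi - lo
    n_total = config.n_features + config.n_background
    base = np.linspace(lo + 0.05 * span, hi - 0.05 * span, n_total)
    mz = np.sort(base + rng.uniform(-0.3, 0.3, n_total))

    entries = []
    seen_names = set()
    for i, (cls, carbons, db) in enumerate(plan):
        name = f"{cls} {carbons}:{db}"
        while name in seen_names:
            carbons += 2
            name = f"{cls} {carbons}:{db}"
        seen_names.add(name)
        entries.append(
            LibraryEntry(
                lipid_name=name,
                lipid_class=cls,
                total_carbons=carbons,
                total_double_bonds=db,
                expected_mz=float(mz[i]),
                ionization_mode=config.ionization_mode,
            )
        )
    return AnnotationLibrary(entries), mz


def default_effects(library: AnnotationLibrary, config: SyntheticConfig) -> list[Effect]:
    """Default planted-effect template: alveolar decreases in the exposed
    female group on ten unsaturated PE lipids and six PG lipids."""
    pe_unsat = [
        e.lipid_name
        for e in library.entries
        if e.lipid_class == "PE" and (e.total_double_bonds or 0) >= 2
    ][:10]
    pg = [e.lipid_name for e in library.entries if e.lipid_class == "PG"][:6]
    if len(config.groups) < 2:
        return []
    exposed = config.groups[1]
    return [
        Effect(pe_unsat, REGION_ALVEOLAR, exposed, -1.0, sex="F"),
        Effect(pg, REGION_ALVEOLAR, exposed, -0.7, sex="F"),
    ]


# ---------------------------------------------------------------------------
# geometry and per-sample synthesis
# ---------------------------------------------------------------------------

def region_geometry(config: SyntheticConfig) -> np.ndarray:
    """Per-pixel region labels in acquisition (row-major) order."""
    ys, xs = np.mgrid[0 : config.height, 0 : config.width]
    cx, cy = config.width / 2, config.height / 2
    r = np.hypot(xs + 0.5 - cx, ys + 0.5 - cy)
    labels = np.full((config.height, config.width), REGION_ALVEOLAR, dtype=object)
    b = config.border
    if b > 0:
        labels[:b, :] = REGION_OFF
        labels[-b:, :] = REGION_OFF
        labels[:, :b] = REGION_OFF
        labels[:, -b:] = REGION_OFF
    tissue = labels != REGION_OFF
    r0 = config.lumen_radius
    r1 = r0 + config.epithelium_thickness
    r2 = r1 + config.basement_thickness
    labels[tissue & (r < r0)] = REGION_LUMEN
    labels[tissue & (r >= r0) & (r < r1)] = REGION_EPITHELIUM
    if config.basement_thickness > 0:
        labels[tissue & (r >= r1) & (r < r2)] = REGION_BASEMENT
    return labels.ravel()


def drift_profile(config: SyntheticConfig, n_pixels: int, amplitude: float) -> np.ndarray:
    i = np.arange(n_pixels, dtype=np.float64)
    t = i / max(n_pixels - 1, 1)
    if config.drift_kind == "linear":
        return 1.0 + amplitude * (t - 0.5)
    if config.drift_kind == "sinusoidal":
        return 1.0 + 0.5 * amplitude * np.sin(2 * np.pi * t)
    return np.ones(n_pixels)


def _region_profiles(
    config: SyntheticConfig, library: AnnotationLibrary, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-region mean vector over all channels (tissue + background).

    Fixed across samples: every region elevates its own marker lipids by
    ``marker_fold`` over a shared lognormal baseline; off-tissue retains only
    a trace of tissue lipids but doubled matrix background.
    """
    n_t, n_b = config.n_features, config.n_background
    n_total = n_t + n_b
    baseline = np.empty(n_total)
    baseline[:n_t] = rng.lognormal(mean=np.log(100.0), sigma=0.5, size=n_t)
    baseline[n_t:] = rng.lognormal(mean=np.log(250.0), sigma=0.4, size=n_b)

    tissue_regions = [REGION_LUMEN, REGION_EPITHELIUM, REGION_ALVEOLAR]
    if config.basement_thickness > 0:
        tissue_regions.append(REGION_BASEMENT)
    marker_pool = rng.permutation(n_t)
    means = {}
    for j, region in enumerate(tissue_regions):
        mult = rng.lognormal(mean=0.0, sigma=0.25, size=n_total)
        mult[n_t:] = 1.0  # background channels are region-agnostic
        markers = marker_pool[
            j * config.n_markers_per_region : (j + 1) * config.n_markers_per_region
        ]
        mult[markers] *= config.marker_fold
        means[region] = baseline * mult
    off = baseline.copy()
    off[:n_t] *= config.off_tissue_attenuation
    off[n_t:] *= config.background_off_tissue_fold
    means[REGION_OFF] = off
    df = pd.DataFrame(means).T  # regions x channels
    background_mask = np.zeros(n_total, dtype=bool)
    background_mask[n_t:] = True
    return df, background_mask, baseline


def generate_feature_matrices(
    config: SyntheticConfig,
) -> tuple[list[FeatureMatrix], SyntheticTruth]:
    """Generate dense truth feature matrices (no spectral encoding).

    This is the fast path for normalization/segmentation/statistics work; the
    feature axis is the true channel m/z list.  :func:`generate_dataset`
    wraps the same matrices into per-pixel centroided spectra for the full
    peak-processing path.
    """
    library, mz = build_synthetic_library(config)
    effects = config.effects if config.effects is not None else default_effects(library, config)
    for e in effects:
        known = {en.lipid_name for en in library.entries}
        missing = set(e.lipids) - known
        if missing:
            raise ValueError(f"effect references unknown lipids: {sorted(missing)}")

    master = np.random.SeedSequence([config.seed, 7])
    rng_profiles = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    profiles, background_mask, baseline = _region_profiles(config, library, rng_profiles)
    regions = region_geometry(config)
    n_pixels = regions.size
    name_to_col = {e.lipid_name: i for i, e in enumerate(library.entries)}

    # per-sample scale ladders with the configured max/min spread, permuted
    # across samples (acquisition order is randomized in the emulated study,
    # so slide scale must not track treatment group)
    n_samples = len(config.groups) * len(config.sexes) * config.n_samples_per_cell
    perm_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    s = config.sample_scale_spread
    tissue_scales = perm_rng.permutation(np.geomspace(1 / np.sqrt(s), np.sqrt(s), n_samples))
    b = config.background_scale_spread
    background_scales = perm_rng.permutation(np.geomspace(1 / np.sqrt(b), np.sqrt(b), n_samples))

    child_seeds = master.spawn(n_samples)
    matrices: list[FeatureMatrix] = []
    truth_regions: dict[str, np.ndarray] = {}
    truth_drift: dict[str, np.ndarray] = {}
    truth_means: dict[str, pd.DataFrame] = {}
    meta_rows = []
    effect_rows = []
    k = 0
    ys, xs = np.divmod(np.arange(n_pixels), config.width)
    pixel_table = pd.DataFrame(
        {"x": xs + 1, "y": ys + 1, "acquisition_index": np.arange(1, n_pixels + 1)}
    )
    drift_t = drift_profile(config, n_pixels, config.drift_amplitude)
    drift_b = drift_profile(
        config, n_pixels, config.drift_amplitude * config.background_drift_factor
    )
    drift_all = np.where(background_mask[None, :], drift_b[:, None], drift_t[:, None])

    for group in config.groups:
        for sex in config.sexes:
            for rep in range(config.n_samples_per_cell):
                sample_id = f"{group}_{sex}_{rep + 1}"
                rng = np.random.default_rng(child_seeds[k])
                mean_by_region = profiles.copy()
                for e in effects:
                    if e.group == group and (e.sex is None or e.sex == sex):
                        cols = [name_to_col[name] for name in e.lipids]
                        mean_by_region.loc[e.region, mean_by_region.columns[cols]] *= (
                            2.0**e.log2_effect
                        )
                scale = np.where(background_mask, background_scales[k], tissue_scales[k])
                base = mean_by_region.loc[regions].to_numpy() * scale[None, :]
                noise = (
                    rng.lognormal(mean=0.0, sigma=config.noise_sigma, size=base.shape)
                    if config.noise_sigma > 0
                    else 1.0
                )
                values = base * drift_all * noise
                # zero inflation: per-channel dropout scaled inversely with
                # the *pre-effect* regional abundance (ion-count zeros
                # concentrate in weak signals; a marker lipid in its home
                # region rarely drops out), capped at 0.95.  Dropout is kept
                # independent of the planted group effects so the effect
                # table is the exact ground truth of the measured per-pixel
                # means.  Off-tissue tissue channels use the flat off-tissue
                # rate.
                rel = profiles.loc[regions].to_numpy() / baseline[None, :]
                p_drop = np.minimum(config.dropout / np.maximum(rel, 1e-9), 0.95)
                p_drop = np.where(
                    background_mask[None, :],
                    config.background_dropout,
                    np.where(
                        (regions == REGION_OFF)[:, None],
                        config.off_tissue_dropout,
                        p_drop,
                    ),
                )
                if np.any(p_drop > 0):
                    values = np.where(rng.random(values.shape) < p_drop, 0.0, values)

                matrices.append(
                    FeatureMatrix(
                        sample_id=sample_id,
                        values=values,
                        feature_mz=mz.copy(),
                        pixel_table=pixel_table.copy(),
                        ionization_mode=config.ionization_mode,
                        group=group,
                        sex=sex,
                    )
                )
                truth_regions[sample_id] = regions.copy()
                truth_drift[sample_id] = drift_t.copy()
                truth_means[sample_id] = mean_by_region * 1.0
                meta_rows.append(
                    {
                        "sample_id": sample_id,
                        "ionization_mode": config.ionization_mode,
                        "group": group,
                        "sex": sex,
                        "run_order": k + 1,
                        "tissue_scale": tissue_scales[k],
                        "background_scale": background_scales[k],
                    }
                )
                k += 1
    for e in effects:
        for name in e.lipids:
            effect_rows.append(
                {
                    "lipid": name,
                    "region": e.region,
                    "group": e.group,
                    "sex": e.sex if e.sex is not None else "both",
                    "log2_effect": e.log2_effect,
                }
            )
    truth = SyntheticTruth(
        region_labels=truth_regions,
        drift=truth_drift,
        region_means=truth_means,
        effect_table=pd.DataFrame(effect_rows),
        library=library,
        feature_mz=mz,
        background_features=background_mask,
        sample_metadata=pd.DataFrame(meta_rows),
    )
    return matrices, truth


def generate_dataset(config: SyntheticConfig) -> tuple[list[MSISample], SyntheticTruth]:
    """Generate synthetic samples as pixel spectra plus the truth record.

    Each pixel's spectrum holds the non-zero channels as centroided peaks; a
    small seeded ppm jitter perturbs peak m/z so cross-sample alignment is
    exercised realistically.  The truth matrices (pre-jitter, exact channel
    axis) are kept in ``truth.spectra``.
    """
    matrices, truth = generate_feature_matrices(config)
    jitter_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    samples = []
    for m in matrices:
        pixels = []
        for row in range(m.n_pixels):
            inten = m.values[row]
            nz = inten > 0
            mzs = m.feature_mz[nz]
            if config.mz_jitter_ppm > 0 and mzs.size:
                mzs = mzs * (
                    1.0
                    + jitter_rng.normal(0.0, config.mz_jitter_ppm * 1e-6, mzs.size)
                )
                order = np.argsort(mzs)
                mzs = mzs[order]
                vals = inten[nz][order]
            else:
                vals = inten[nz]
            rec = m.pixel_table.iloc[row]
            pixels.append(
                PixelSpectrum(
                    x=int(rec["x"]),
                    y=int(rec["y"]),
                    acquisition_index=int(rec["acquisition_index"]),
                    mz=mzs,
                    intensity=vals,
                )
            )
        samples.append(
            MSISample(
                sample_id=m.sample_id,
                ionization_mode=m.ionization_mode,
                pixels=pixels,
                group=m.group,
                sex=m.sex,
                run_order=int(
                    truth.sample_metadata.set_index("sample_id").loc[
                        m.sample_id, "run_order"
                    ]
                ),
                scan_range=config.scan_range,
            )
        )
        truth.spectra[m.sample_id] = m.values
    return samples, truth


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def majority_region_map(labels: np.ndarray, truth_regions: np.ndarray) -> dict[int, str]:
    """Map each cluster to the truth region holding most of its pixels."""
    labels = np.asarray(labels)
    truth_regions = np.asarray(truth_regions)
    mapping = {}
    for c in np.unique(labels):
        members = truth_regions[labels == c]
        regions, counts = np.unique(members, return_counts=True)
        mapping[int(c)] = str(regions[np.argmax(counts)])
    return mapping


def evaluate_segmentation(labels: np.ndarray, truth_regions: np.ndarray) -> dict:
    """Score a segmentation against planted regions.

    Returns the raw adjusted Rand index, the ARI after merging clusters to
    regions by majority truth label, and per-region recall under that merge.
    """
    labels = np.asarray(labels)
    truth_regions = np.asarray(truth_regions)
    if labels.shape != truth_regions.shape:
        raise ValueError("segmentation and truth cover different pixel sets")
    ari = float(adjusted_rand_score(truth_regions, labels))
    mapping = majority_region_map(labels, truth_regions)
    merged = np.array([mapping[int(c)] for c in labels], dtype=object)
    merged_ari = float(adjusted_rand_score(truth_regions, merged))
    recall = {}
    for region in np.unique(truth_regions):
        mask = truth_regions == region
        recall[str(region)] = float((merged[mask] == region).mean())
    return {
        "ari": ari,
        "merged_ari": merged_ari,
        "per_region_recall": recall,
        "cluster_to_region": mapping,
    }
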