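"""Accurate-mass lipid annotation of aligned features.

Features are matched against the LC-MS/MS-validated library at a fixed Da
tolerance (10 mDa default, matching the accuracy of the TOF data), mode
incompatibilities are removed (PI/PS never ionize appreciably in positive
mode), and manually curated noisy-image exclusion windows are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .io import (
    GLYCEROPHOSPHOLIPID_CLASSES,
    AnnotationLibrary,
    LibraryEntry,
)
from .peaks import FeatureBinSet

logger = logging.getLogger("msiregion")

#: Library classes removed from positive-mode annotations.
POSITIVE_MODE_INCOMPATIBLE = frozenset({"PI", "PS"})
#: Negative-mode incompatibility set (none by default).
NEGATIVE_MODE_INCOMPATIBLE: frozenset = frozenset()


@dataclass
class LipidAnnotation:
    """A feature-to-lipid assignment with its signed mass error."""

    feature_mz: float
    entry: LibraryEntry
    mass_error_da: float
    ambiguous: bool = False
    saturation_category: str = "unknown"  # saturated | unsaturated | unknown
    caveat: str = ""

    @property
    def lipid_name(self) -> str:
        return self.entry.lipid_name

    @property
    def lipid_class(self) -> str:
        return self.entry.lipid_class


def match_features(
    bins: FeatureBinSet,
    library: AnnotationLibrary,
    tolerance_da: float = 0.010,
) -> list[LipidAnnotation]:
    """Match aligned features to library entries by accurate mass.

    A feature matches entries with ``|feature_mz - expected_mz| <=
    tolerance_da``; when several qualify the smallest absolute error wins, and
    exact error ties are all reported flagged ambiguous.  Unmatched features
    carry no annotation.
    """
    if tolerance_da < 0:
        raise ValueError("tolerance_da must be non-negative")
    if len(library) == 0:
        raise ValueError("annotation library is empty")

    annotations: list[LipidAnnotation] = []
    for fmz in bins.centers:
        errors = [(e, fmz - e.expected_mz) for e in library.entries]
        within = [(e, err) for e, err in errors if abs(err) <= tolerance_da]
        if not within:
            continue
        best = min(abs(err) for _, err in within)
        winners = [(e, err) for e, err in within if abs(err) == best]
        ambiguous = len(winners) > 1
        for e, err in winners:
            annotations.append(
                LipidAnnotation(
                    feature_mz=float(fmz),
                    entry=e,
                    mass_error_da=float(err),
                    ambiguous=ambiguous,
                    caveat=e.caveat,
                )
            )
    for a in annotations:
        a.saturation_category = classify_saturation(a)
    return annotations


def filter_incompatible_classes(
    annotations: Sequence[LipidAnnotation],
    mode: str,
    incompatible: Optional[frozenset] = None,
) -> list[LipidAnnotation]:
    """Drop annotations whose class cannot plausibly ionize in ``mode``.

    Positive mode removes PI and PS (their LC-MS/MS detection reflects
    negative-mode ionization); the negative-mode set is empty by default.
    """
    if mode not in ("positive", "negative"):
        raise ValueError(f"unknown ionization mode {mode!r}")
    if incompatible is None:
        incompatible = (
            POSITIVE_MODE_INCOMPATIBLE if mode == "positive" else NEGATIVE_MODE_INCOMPATIBLE
        )
    kept = [a for a in annotations if a.lipid_class not in incompatible]
    n_removed = len(annotations) - len(kept)
    if n_removed:
        logger.info(
            "mode filter (%s): removed %d annotation(s) in classes %s",
            mode, n_removed, sorted(incompatible),
        )
    return kept


def apply_exclusion_list(
    annotations: Sequence[LipidAnnotation],
    exclusions: Sequence[tuple[float, float]],
) -> list[LipidAnnotation]:
    """Remove annotations whose feature m/z falls in any exclusion window.

    ``exclusions`` are ``(mz, tolerance_ppm)`` pairs from the manual
    noisy-image list.  Every window's removal count is logged (including
    zero-hit windows) for the audit trail.
    """
    kept = list(annotations)
    for mz, tol_ppm in exclusions:
        half = tol_ppm * 1e-6 * mz
        hit = [a for a in kept if abs(a.feature_mz - mz) <= half]
        kept = [a for a in kept if abs(a.feature_mz - mz) > half]
        logger.info(
            "exclusion %.4f +/- %g ppm removed %d annotation(s)", mz, tol_ppm, len(hit)
        )
    return kept


def classify_saturation(
    annotation: LipidAnnotation, saturated_max_db: int = 1
) -> str:
    """Split lipids into high/low saturation by total double-bond count.

    "saturated" when total double bonds <= ``saturated_max_db`` (default 1:
    monounsaturated species group with the saturated fraction), otherwise
    "unsaturated"; unknown double-bond counts give "unknown" and are excluded
    from saturation-split sets downstream.
    """
    db = annotation.entry.total_double_bonds
    if db is None:
        return "unknown"
    return "saturated" if db <= saturated_max_db else "unsaturated"


def annotate_features(
    bins: FeatureBinSet,
    library: AnnotationLibrary,
    mode: str,
    tolerance_da: float = 0.010,
    exclusions: Sequence[tuple[float, float]] = (),
    saturated_max_db: int = 1,
) -> list[LipidAnnotation]:
    """Full annotation pass: match, mode filter, exclusions, saturation."""
    anns = match_features(bins, library.for_mode(mode), tolerance_da)
    anns = filter_incompatible_classes(anns, mode)
    anns = apply_exclusion_list(anns, exclusions)
    for a in anns:
        a.saturation_category = classify_saturation(a, saturated_max_db)
    return anns


def annotation_table(annotations: Sequence[LipidAnnotation]) -> pd.DataFrame:
    """Tidy annotation export (one row per assignment)."""
    return pd.DataFrame(
        {
            "feature_mz": [a.feature_mz for a in annotations],
            "lipid_name": [a.lipid_name for a in annotations],
            "lipid_class": [a.lipid_class for a in annotations],
            "total_carbons": [a.entry.total_carbons for a in annotations],
            "double_bonds": [a.entry.total_double_bonds for a in annotations],
            "mass_error_mda": [a.mass_error_da * 1e3 for a in annotations],
            "mode": [a.entry.ionization_mode for a in annotations],
            "source": [a.entry.source for a in annotations],
            "saturation": [a.saturation_category for a in annotations],
            "ambiguous": [a.ambiguous for a in annotations],
        }
    )


def summarize_annotation_classes(
    annotations: Sequence[LipidAnnotation],
) -> pd.DataFrame:
    """Per-mode annotation counts and the glycerophospholipid fraction.

    Mirrors the class-proportion summary of an annotation list: counts per
    ionization mode, total, and the fraction of annotated lipids in
    glycerophospholipid classes (PC/PE/PG/PI/PS/PA and lyso forms).
    """
    df = annotation_table(annotations)
    rows = []
    for mode, sub in df.groupby("mode"):
        rows.append(
            {
                "mode": mode,
                "n_annotated": len(sub),
                "glycerophospholipid_fraction": float(
                    sub["lipid_class"].isin(GLYCEROPHOSPHOLIPID_CLASSES).mean()
                )
                if len(sub)
                else float("nan"),
            }
        )
    total = {
        "mode": "total",
        "n_annotated": len(df),
        "glycerophospholipid_fraction": float(
            df["lipid_class"].isin(GLYCEROPHOSPHOLIPID_CLASSES).mean()
        )
        if len(df)
        else float("nan"),
    }
    return pd.DataFrame(rows + [total])
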