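"""Peak detection, ppm binning and cross-sample feature alignment.

All samples of one ionization mode are processed simultaneously: apex m/z
values pooled over every pixel of every sample are merged by a single greedy
ppm-binning pass, which guarantees one shared feature list (the alignment
contract).  Per-sample pixel-by-feature matrices are then populated against
that list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import MSISample

logger = logging.getLogger("msiregion")


@dataclass
class FeatureBinSet:
    """Aligned m/z bins shared by all samples.

    ``centers`` are bin means, strictly increasing, with consecutive centers
    separated by more than ``tolerance_ppm``.
    """

    centers: np.ndarray
    tolerance_ppm: float = 5.0
    provenance: np.ndarray = field(default=None)  # per-bin member count

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        if self.provenance is None:
            self.provenance = np.ones(self.centers.size, dtype=np.int64)
        if self.centers.size > 1:
            if not np.all(np.diff(self.centers) > 0):
                raise ValueError("bin centers must be strictly increasing")
            gaps_ppm = np.diff(self.centers) / self.centers[:-1] * 1e6
            if np.any(gaps_ppm <= self.tolerance_ppm):
                raise ValueError("bin centers closer than tolerance (overlapping bins)")

    def __len__(self) -> int:
        return self.centers.size


@dataclass
class FeatureMatrix:
    """Pixels-by-features intensity matrix for one sample.

    Rows follow acquisition order; ``pixel_table`` maps row index to
    (x, y, acquisition_index).  Zero is the absent value.
    """

    sample_id: str
    values: np.ndarray  # (n_pixels, n_features) float64, >= 0
    feature_mz: np.ndarray  # (n_features,)
    pixel_table: pd.DataFrame  # columns x, y, acquisition_index
    ionization_mode: str = "positive"
    group: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_mz = np.asarray(self.feature_mz, dtype=np.float64)
        if self.values.shape != (len(self.pixel_table), self.feature_mz.size):
            raise ValueError("matrix shape inconsistent with pixel/feature maps")
        if np.any(self.values < 0):
            raise ValueError("feature matrix values must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            sample_id=self.sample_id,
            values=np.asarray(values, dtype=np.float64),
            feature_mz=self.feature_mz,
            pixel_table=self.pixel_table,
            ionization_mode=self.ionization_mode,
            group=self.group,
            sex=self.sex,
        )

    def subset_features(self, col_idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            sample_id=self.sample_id,
            values=self.values[:, col_idx],
            feature_mz=self.feature_mz[col_idx],
            pixel_table=self.pixel_table,
            ionization_mode=self.ionization_mode,
            group=self.group,
            sex=self.sex,
        )


def detect_peaks(
    mz: np.ndarray,
    intensity: np.ndarray,
    snr_threshold: float = 3.0,
    centroided: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Pick peaks from one pixel spectrum.

    Profile mode: local maxima whose intensity exceeds ``snr_threshold`` times
    the noise level, estimated as 1.4826 x the median absolute deviation of
    the intensities.  Centroided input (``centroided=True``): every non-zero
    point above the threshold is already a peak, so detection degenerates to
    thresholding.  Returns ``(apex_mz, apex_intensity)``.
    """
    if snr_threshold <= 0:
        raise ValueError("snr_threshold must be positive")
    mz = np.asarray(mz, dtype=np.float64)
    intensity = np.asarray(intensity, dtype=np.float64)
    if mz.size == 0 or not np.any(intensity > 0):
        return np.empty(0), np.empty(0)

    if centroided or mz.size < 3:
        # centroid data carries no baseline to estimate noise from: keep
        # every stored (non-zero) peak
        keep = intensity > 0
        return mz[keep], intensity[keep]

    mad = np.median(np.abs(intensity - np.median(intensity)))
    noise = 1.4826 * mad
    # flat baseline (zeros plus isolated peaks): fall back to > 0
    threshold = snr_threshold * noise if noise > 0 else 0.0

    inner = intensity[1:-1]
    is_max = (inner > intensity[:-2]) & (inner >= intensity[2:]) & (inner > threshold)
    idx = np.flatnonzero(is_max) + 1
    return mz[idx], intensity[idx]


def bin_mz(values: Sequence[float] | np.ndarray, tolerance_ppm: float = 5.0) -> FeatureBinSet:
    """Greedy left-to-right ppm binning of m/z values.

    Values are processed in ascending order; a value joins the open bin when
    its ppm distance to the running bin mean is at most ``tolerance_ppm``,
    otherwise it opens a new bin.  Centers are bin means.  A final pass merges
    any residual centers closer than the tolerance so the bin set never
    contains overlapping bins.
    """
    values = np.sort(np.asarray(values, dtype=np.float64))
    if values.size == 0:
        return FeatureBinSet(np.empty(0), tolerance_ppm)
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("m/z values must be finite and positive")

    tol = tolerance_ppm * 1e-6
    centers: list[float] = []
    counts: list[int] = []
    mean = values[0]
    n = 1
    for v in values[1:]:
        if (v - mean) <= tol * mean:
            n += 1
            mean += (v - mean) / n  # running mean
        else:
            centers.append(mean)
            counts.append(n)
            mean = v
            n = 1
    centers.append(mean)
    counts.append(n)

    # post-merge: guarantee consecutive centers separated by > tolerance
    merged_c: list[float] = [centers[0]]
    merged_n: list[int] = [counts[0]]
    for c, k in zip(centers[1:], counts[1:]):
        if (c - merged_c[-1]) <= tol * merged_c[-1]:
            total = merged_n[-1] + k
            merged_c[-1] = (merged_c[-1] * merged_n[-1] + c * k) / total
            merged_n[-1] = total
        else:
            merged_c.append(c)
            merged_n.append(k)
    return FeatureBinSet(np.array(merged_c), tolerance_ppm, np.array(merged_n))


def _assign_to_bins(mz: np.ndarray, bins: FeatureBinSet) -> np.ndarray:
    """Nearest-center bin index for each m/z, or -1 when outside tolerance."""
    centers = bins.centers
    idx = np.searchsorted(centers, mz)
    idx = np.clip(idx, 0, centers.size - 1)
    left = np.clip(idx - 1, 0, centers.size - 1)
    d_right = np.abs(mz - centers[idx])
    d_left = np.abs(mz - centers[left])
    best = np.where(d_left < d_right, left, idx)
    tol_da = bins.tolerance_ppm * 1e-6 * centers[best]
    best = np.where(np.abs(mz - centers[best]) <= tol_da, best, -1)
    return best


def pool_peak_mz(
    samples: Iterable[MSISample],
    snr_threshold: float = 3.0,
    centroided: bool = False,
) -> np.ndarray:
    """Apex m/z pooled over every pixel of every sample (alignment input)."""
    pools: list[np.ndarray] = []
    for s in samples:
        for p in s.pixels:
            apex_mz, _ = detect_peaks(p.mz, p.intensity, snr_threshold, centroided)
            pools.append(apex_mz)
    if not pools:
        return np.empty(0)
    return np.concatenate(pools)


def align_samples(
    samples: Sequence[MSISample],
    tolerance_ppm: float = 5.0,
    snr_threshold: float = 3.0,
    centroided: bool = False,
) -> FeatureBinSet:
    """One global binning pass over the pooled apex m/z of all samples."""
    pooled = pool_peak_mz(samples, snr_threshold, centroided)
    bins = bin_mz(pooled, tolerance_ppm)
    logger.info("aligned %d samples into %d feature bins", len(samples), len(bins))
    return bins


def build_feature_matrix(
    samples: Sequence[MSISample],
    bins: FeatureBinSet,
    snr_threshold: float = 3.0,
    centroided: bool = False,
) -> list[FeatureMatrix]:
    """Populate one pixel-by-feature matrix per sample over a shared bin set.

    A pixel's bin value is the sum of its detected peak intensities whose m/z
    falls within tolerance of the bin center; absent signal is 0.
    """
    if len(bins) == 0:
        raise ValueError("bin set must be non-empty")
    modes = {s.ionization_mode for s in samples}
    if len(modes) > 1:
        raise ValueError(f"samples mix ionization modes: {sorted(modes)}")

    matrices = []
    for s in samples:
        ordered = s.pixels_in_acquisition_order()
        values = np.zeros((len(ordered), len(bins)))
        for row, p in enumerate(ordered):
            apex_mz, apex_int = detect_peaks(p.mz, p.intensity, snr_threshold, centroided)
            if apex_mz.size == 0:
                continue
            cols = _assign_to_bins(apex_mz, bins)
            ok = cols >= 0
            np.add.at(values[row], cols[ok], apex_int[ok])
        pixel_table = pd.DataFrame(
            {
                "x": [p.x for p in ordered],
                "y": [p.y for p in ordered],
                "acquisition_index": [p.acquisition_index for p in ordered],
            }
        )
        matrices.append(
            FeatureMatrix(
                sample_id=s.sample_id,
                values=values,
                feature_mz=bins.centers.copy(),
                pixel_table=pixel_table,
                ionization_mode=s.ionization_mode,
                group=s.group,
                sex=s.sex,
            )
        )
    return matrices


def export_sparse_triplets(matrix: FeatureMatrix, path) -> None:
    """Write a matrix as sparse (row, col, value) triplet CSV."""
    rows, cols = np.nonzero(matrix.values)
    pd.DataFrame(
        {"pixel": rows, "feature": cols, "value": matrix.values[rows, cols]}
    ).to_csv(path, index=False)
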