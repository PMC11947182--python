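"""TIC and sparse LOESS normalization of feature matrices.

MALDI imaging runs drift: detector response changes over the hours of a
raster acquisition, and absolute signal levels differ between slides.  Two
correction layers are provided:

* :func:`tic_normalize` — classic total-ion-current scaling of each pixel to
  a shared target sum.
* :func:`sparse_loess_normalize` — the drift correction used throughout this
  package: per sample and per feature, a locally weighted polynomial
  regression of log intensity against acquisition index is fitted on the
  *non-zero* pixels only ("sparse"), with the local window sized to roughly
  10% of the sample's pixel count; each non-zero intensity is divided by the
  shape of the fitted trend, and samples are brought to a common scale by a
  single robust per-sample factor estimated across all features against the
  pooled per-feature reference medians.  Zero pixels — off-tissue or true
  absence — are never touched, so the correction cannot invent signal or
  erase the spatial pattern of a compound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .peaks import FeatureMatrix

logger = logging.getLogger("msiregion")

#: Guard factor against near-zero fitted trend values.
EPS_FACTOR = 1e-8


@dataclass
class LoessFit:
    """Fitted drift trend for one (sample, feature) pair."""

    sample_id: str
    feature_index: int
    span: float  # realized span as a fraction of the support
    support: np.ndarray  # acquisition indices of non-zero pixels
    fitted: np.ndarray  # positive trend values on the support
    reference: float  # pooled-median target level
    passed_through: bool = False  # too sparse to fit


@dataclass
class DriftReport:
    """Per-sample drift slopes and medians, per processing stage."""

    per_sample: pd.DataFrame  # stage, sample_id, slope, median_tic, n_nonzero
    per_stage: pd.DataFrame  # stage, median_tic_rel_range
    tic_series: dict  # (stage, sample_id) -> per-pixel TIC array (QC export)


# ---------------------------------------------------------------------------
# TIC
# ---------------------------------------------------------------------------

def tic_normalize(matrix: FeatureMatrix, target: float = 1.0) -> FeatureMatrix:
    """Scale each pixel so its feature sum equals ``target``.

    All-zero pixels are left unchanged (no division by zero); the matrix is
    expected to be restricted to the features whose sum defines the TIC.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    sums = matrix.values.sum(axis=1)
    scale = np.ones_like(sums)
    nz = sums > 0
    scale[nz] = target / sums[nz]
    return matrix.copy_with(matrix.values * scale[:, None])


# ---------------------------------------------------------------------------
# sparse LOESS
# ---------------------------------------------------------------------------

def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def _local_poly_fit(
    x: np.ndarray,
    y: np.ndarray,
    window: int,
    degree: int,
    eval_x: np.ndarray,
) -> np.ndarray:
    """Local polynomial regression (tricube weights) at ``eval_x``.

    ``x`` must be sorted ascending.  The local window at each evaluation point
    is the contiguous span of ``window`` points minimizing the farthest
    distance, the usual nearest-neighbour span for sorted predictors.
    """
    n = x.size
    window = min(window, n)
    degree = min(degree, window - 1)
    out = np.empty(eval_x.size)
    max_start = n - window
    for j, e in enumerate(eval_x):
        lo = np.searchsorted(x, e)
        s0 = max(0, min(lo - window, max_start))
        s1 = max(0, min(lo, max_start))
        starts = np.arange(s0, s1 + 1)
        cost = np.maximum(e - x[starts], x[starts + window - 1] - e)
        s = starts[np.argmin(cost)]
        xw = x[s : s + window] - e
        yw = y[s : s + window]
        dmax = max(np.max(np.abs(xw)), 1e-12) * (1 + 1e-9)
        w = _tricube(xw / dmax)
        # weighted least squares via normal equations on the Vandermonde basis
        V = np.vander(xw, degree + 1, increasing=True)
        Vw = V * w[:, None]
        coef = np.linalg.lstsq(Vw.T @ V, Vw.T @ yw, rcond=None)[0]
        out[j] = coef[0]  # value at the evaluation point
    return out


def sparse_loess_normalize(
    matrices: Sequence[FeatureMatrix],
    span_fraction: float = 0.10,
    degree: int = 2,
    max_eval_points: int = 100,
) -> tuple[list[FeatureMatrix], list[LoessFit]]:
    """Correct acquisition drift and inter-sample scale by sparse LOESS.

    Per feature and per sample the drift trend is fitted on non-zero pixels
    only, with the local window sized to ``span_fraction`` of the sample's
    *total* pixel count (clamped to at least ``degree + 2`` points and at most
    the support size).  Each non-zero intensity is divided by the trend's
    shape (the fit normalized to its own geometric mean), which removes the
    acquisition drift without touching the feature's per-sample abundance
    level.  Samples are then aligned by one robust technical scale factor:
    the median over features of the sample's non-zero-median intensity
    relative to the pooled per-feature reference (the median of the feature's
    non-zero intensities over all samples).  Correcting the scale with a
    single cross-feature factor, rather than forcing every feature to the
    reference, preserves genuine between-sample differences in individual
    lipids — a group effect on a handful of lipids cannot move the median of
    a hundred level ratios.  Features with fewer non-zero pixels than the
    minimum window pass through unchanged and are logged.

    For speed the trend is evaluated at up to ``max_eval_points`` quantile
    points of the support and linearly interpolated in between; with the
    default 10% span this grid is far denser than the smoothing bandwidth.
    """
    if not (0 < span_fraction <= 1):
        raise ValueError("span_fraction must be in (0, 1]")
    if degree < 0:
        raise ValueError("degree must be non-negative")
    mz0 = matrices[0].feature_mz
    for m in matrices[1:]:
        if not np.array_equal(m.feature_mz, mz0):
            raise ValueError("matrices must share one feature axis")

    n_features = matrices[0].n_features
    # pooled per-feature reference: median of non-zero intensities over all samples
    references = np.empty(n_features)
    for f in range(n_features):
        pooled = np.concatenate([m.values[:, f][m.values[:, f] > 0] for m in matrices])
        references[f] = np.median(pooled) if pooled.size else 0.0

    out: list[FeatureMatrix] = []
    fits: list[LoessFit] = []
    min_points = degree + 2
    for m in matrices:
        values = m.values.copy()
        acq = m.pixel_table["acquisition_index"].to_numpy(dtype=np.float64)
        order = np.argsort(acq)
        window = int(round(span_fraction * m.n_pixels))
        level_ratios: list[float] = []
        fitted_cols: list[int] = []
        for f in range(n_features):
            col = values[:, f]
            nz_rows = order[col[order] > 0]
            ref = references[f]
            if nz_rows.size < min_points or ref <= 0:
                fits.append(
                    LoessFit(m.sample_id, f, 0.0, acq[nz_rows], col[nz_rows].copy(),
                             ref, passed_through=True)
                )
                logger.debug(
                    "sample %s feature %d too sparse for LOESS (%d non-zero pixels)",
                    m.sample_id, f, nz_rows.size,
                )
                continue
            x = acq[nz_rows]
            y = col[nz_rows]
            win = int(np.clip(window, min_points, x.size))
            n_eval = min(max_eval_points, x.size)
            eval_x = np.quantile(x, np.linspace(0, 1, n_eval))
            eps = EPS_FACTOR * ref
            # trend fitted on log intensity: keeps the fit positive and
            # matches the multiplicative drift model of ion counts
            fit_grid = np.exp(_local_poly_fit(x, np.log(y), win, degree, eval_x))
            fit = np.interp(x, eval_x, fit_grid)
            fit = np.maximum(fit, eps)
            # divide out only the *shape* of the trend (geometric-mean
            # normalized): the feature's per-sample abundance level — which
            # may be genuine biology — is corrected separately below by one
            # robust per-sample factor shared across features
            shape = fit / float(np.exp(np.mean(np.log(fit))))
            values[nz_rows, f] = y / shape
            level_ratios.append(float(np.median(y)) / ref)
            fitted_cols.append(f)
            fits.append(
                LoessFit(m.sample_id, f, win / x.size, x, fit, ref)
            )
        # robust per-sample technical scale: the median over features of the
        # sample's feature level relative to the pooled reference; a few
        # features with real group effects cannot move this median
        sample_scale = float(np.median(level_ratios)) if level_ratios else 1.0
        if sample_scale <= 0:
            sample_scale = 1.0
        # too-sparse features pass through truly unchanged
        values[:, fitted_cols] /= sample_scale
        out.append(m.copy_with(values))
    n_passed = sum(f.passed_through for f in fits)
    if n_passed:
        logger.info("sparse LOESS: %d (sample, feature) pairs passed through unchanged", n_passed)
    return out, fits


# ---------------------------------------------------------------------------
# drift reporting
# ---------------------------------------------------------------------------

def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    return float(np.polyfit(x, y, 1)[0])


def drift_report(
    matrix_sets: dict[str, Sequence[FeatureMatrix]],
    feature_mask: Optional[np.ndarray] = None,
) -> DriftReport:
    """Quantify residual drift for named processing stages.

    For every stage and sample: the OLS slope of per-pixel TIC (sum over the
    masked features; non-zero pixels only) against acquisition index, and the
    median non-zero TIC.  Across samples, each stage's inter-sample spread is
    summarized as (max - min) / median of the per-sample median TICs.
    ``feature_mask`` restricts the TIC to (e.g.) annotated features; all
    stages are measured identically.
    """
    rows = []
    series: dict = {}
    stage_summary = []
    for stage, matrices in matrix_sets.items():
        medians = []
        for m in matrices:
            cols = m.values if feature_mask is None else m.values[:, feature_mask]
            tic = cols.sum(axis=1)
            acq = m.pixel_table["acquisition_index"].to_numpy(dtype=np.float64)
            nz = tic > 0
            slope = _ols_slope(acq[nz], tic[nz])
            med = float(np.median(tic[nz])) if nz.any() else 0.0
            medians.append(med)
            rows.append(
                {
                    "stage": stage,
                    "sample_id": m.sample_id,
                    "slope": slope,
                    # slope per unit of typical signal: comparable across
                    # stages that rescale the data (e.g. TIC target = 1)
                    "relative_slope": slope / med if med > 0 else float("nan"),
                    "median_tic": med,
                    "n_nonzero": int(nz.sum()),
                }
            )
            series[(stage, m.sample_id)] = tic
        medians = np.asarray(medians, dtype=np.float64)
        rel_range = (
            float((medians.max() - medians.min()) / np.median(medians))
            if medians.size and np.median(medians) > 0
            else float("nan")
        )
        stage_summary.append({"stage": stage, "median_tic_rel_range": rel_range})
    return DriftReport(
        per_sample=pd.DataFrame(rows),
        per_stage=pd.DataFrame(stage_summary),
        tic_series=series,
    )
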