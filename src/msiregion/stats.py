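"""Region-level differential and lipid-class enrichment statistics.

Pixel intensities are first collapsed to one value per sample, region and
lipid — the per-pixel mean over all pixels of the region, log2-transformed to
make the replicate-level distribution approximately normal.  Differential
analysis is a one-way ANOVA over the sex-by-treatment cells with Tukey HSD
pairwise contrasts; a volcano rule (p < 0.05, |log2 fold change| > 0.5)
flags significant, high-effect lipids.  Class-level coordination is tested by
a one-sided two-sample Kolmogorov–Smirnov statistic comparing the fold
changes of a lipid set (class x saturation) against all remaining lipids,
run in both directions, with Benjamini–Hochberg FDR across the sets of a
region/contrast.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .annotate import LipidAnnotation
from .peaks import FeatureMatrix
from .segment import NON_STATISTICAL_REGIONS

logger = logging.getLogger("msiregion")


# ---------------------------------------------------------------------------
# region summaries
# ---------------------------------------------------------------------------

def feature_indices_for(
    feature_mz: np.ndarray, annotations: Sequence[LipidAnnotation]
) -> list[tuple[int, LipidAnnotation]]:
    """Map annotations back to feature columns by their recorded feature m/z."""
    out = []
    for a in annotations:
        idx = int(np.argmin(np.abs(feature_mz - a.feature_mz)))
        if not np.isclose(feature_mz[idx], a.feature_mz, rtol=0, atol=1e-9):
            raise ValueError(f"annotation m/z {a.feature_mz} not on the feature axis")
        out.append((idx, a))
    return out


def summarize_regions(
    matrices: Sequence[FeatureMatrix],
    region_labels: dict[str, np.ndarray],
    annotations: Sequence[LipidAnnotation],
) -> pd.DataFrame:
    """Per sample x region x lipid summary of pixel intensities.

    ``mean_intensity`` averages over *all* pixels of the region (zeros
    included); ``log2_mean`` is defined only for positive means.  Off-tissue
    and unassigned pixels never enter; regions absent from a sample simply
    have no record.
    """
    rows = []
    for m in matrices:
        regions = np.asarray(region_labels[m.sample_id])
        if regions.shape[0] != m.n_pixels:
            raise ValueError(f"region labels do not cover sample {m.sample_id}")
        pairs = feature_indices_for(m.feature_mz, annotations)
        for region in pd.unique(regions):
            if region in NON_STATISTICAL_REGIONS:
                continue
            mask = regions == region
            for fidx, ann in pairs:
                mean = float(m.values[mask, fidx].mean())
                rows.append(
                    {
                        "sample_id": m.sample_id,
                        "group": m.group,
                        "sex": m.sex,
                        "region": region,
                        "lipid": ann.lipid_name,
                        "lipid_class": ann.lipid_class,
                        "saturation": ann.saturation_category,
                        "pixel_count": int(mask.sum()),
                        "mean_intensity": mean,
                        "log2_mean": float(np.log2(mean)) if mean > 0 else np.nan,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differential analysis
# ---------------------------------------------------------------------------

def differential_anova(
    summaries: pd.DataFrame,
    cell_cols: Sequence[str] = ("sex", "group"),
    min_replicates: int = 2,
) -> pd.DataFrame:
    """One-way ANOVA + Tukey HSD per lipid per region.

    Cells are the combinations of ``cell_cols`` (sex x treatment by default).
    For each lipid/region with at least two cells of ``min_replicates``
    replicates, the one-way ANOVA F and p are computed on ``log2_mean``
    values, and Tukey's studentized-range adjustment gives one adjusted p per
    pairwise contrast; ``log2_fc`` is the difference of cell means
    (first-named cell minus second).  Lipids with insufficient replication
    are skipped with a logged reason.
    """
    df = summaries.dropna(subset=["log2_mean"]).copy()
    df["cell"] = df[list(cell_cols)].astype(str).agg(":".join, axis=1)
    rows = []
    for (region, lipid), sub in df.groupby(["region", "lipid"], sort=False):
        counts = sub["cell"].value_counts()
        cells = counts[counts >= min_replicates].index.tolist()
        if len(cells) < 2:
            logger.info(
                "skipping %s in %s: fewer than 2 cells with >= %d replicates",
                lipid, region, min_replicates,
            )
            continue
        sub = sub[sub["cell"].isin(cells)]
        groups = [sub.loc[sub["cell"] == c, "log2_mean"].to_numpy() for c in cells]
        f_stat, p_value = sps.f_oneway(*groups)
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            f_stat, p_value = 0.0, 1.0  # all observations identical
        tukey = pairwise_tukeyhsd(
            sub["log2_mean"].to_numpy(), sub["cell"].to_numpy(), alpha=0.05
        )
        res = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        for _, r in res.iterrows():
            g1, g2 = str(r["group1"]), str(r["group2"])
            # Tukey reports each pair once; emit both orientations so any
            # "A vs B" lookup works (log2_fc = mean(A) - mean(B))
            for a, b, sign in ((g2, g1, 1.0), (g1, g2, -1.0)):
                rows.append(
                    {
                        "lipid": lipid,
                        "lipid_class": sub["lipid_class"].iloc[0],
                        "saturation": sub["saturation"].iloc[0],
                        "region": region,
                        "contrast": f"{a} vs {b}",
                        "log2_fc": sign * float(r["meandiff"]),
                        "f_statistic": float(f_stat),
                        "p_value": float(p_value),
                        "tukey_adjusted_p": float(r["p-adj"]),
                    }
                )
    return pd.DataFrame(rows)


def classify_volcano(
    results: pd.DataFrame,
    p_cut: float = 0.05,
    lfc_cut: float = 0.5,
    p_col: str = "tukey_adjusted_p",
) -> pd.DataFrame:
    """Flag significant (p < cut) and high-effect (|log2_fc| > cut, strict) rows."""
    out = results.copy()
    out["significant"] = out[p_col] < p_cut
    out["high_effect"] = out["log2_fc"].abs() > lfc_cut
    return out


# ---------------------------------------------------------------------------
# class enrichment (one-sided KS)
# ---------------------------------------------------------------------------

def _dplus(member: np.ndarray, background: np.ndarray) -> float:
    """One-sided KS statistic for "member values stochastically greater".

    D+ = sup_t [F_background(t) - F_member(t)]; equals 1 when every member
    exceeds every background value.
    """
    grid = np.sort(np.concatenate([member, background]))
    fm = np.searchsorted(np.sort(member), grid, side="right") / member.size
    fb = np.searchsorted(np.sort(background), grid, side="right") / background.size
    return float(np.max(fb - fm))


def _exact_permutation_p(
    values: np.ndarray, member_idx: np.ndarray, observed: float
) -> float:
    """Exact permutation tail: P(D+ >= observed) over all equal-size subsets."""
    n = values.size
    m = member_idx.size
    total = comb(n, m)
    count = 0
    all_idx = np.arange(n)
    for subset in combinations(range(n), m):
        sel = np.zeros(n, dtype=bool)
        sel[list(subset)] = True
        d = _dplus(values[sel], values[~sel])
        if d >= observed - 1e-12:
            count += 1
    return count / total


def ks_enrichment_test(
    member: np.ndarray,
    background: np.ndarray,
    direction: str = "increase",
    exact_limit: int = 100_000,
) -> tuple[float, float]:
    """One-sided two-sample KS test of a lipid set against its complement.

    ``direction="increase"`` tests whether member fold changes are
    stochastically greater than the background, ``"decrease"`` the reverse.
    When the number of equal-size subsets C(n, m) is at most ``exact_limit``
    the p-value is the exact permutation tail probability; otherwise scipy's
    two-sample one-sided KS p is used.  Returns ``(statistic, p)``.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError(f"unknown direction {direction!r}")
    member = np.asarray(member, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if direction == "decrease":
        member, background = -member, -background
    stat = _dplus(member, background)
    n_total = member.size + background.size
    if comb(n_total, member.size) <= exact_limit:
        values = np.concatenate([member, background])
        p = _exact_permutation_p(values, np.arange(member.size), stat)
    else:
        # scipy: alternative="less" tests CDF(member) below CDF(background),
        # i.e. member values stochastically greater
        p = float(sps.ks_2samp(member, background, alternative="less").pvalue)
    return stat, p


def build_lipid_sets(
    annotations: Sequence[LipidAnnotation], min_set_size: int = 3
) -> dict[str, list[str]]:
    """Class x saturation lipid sets (e.g. "PE (Unsat.)") of sufficient size.

    Lipids with unknown saturation are excluded from saturation-split sets.
    """
    sets: dict[str, list[str]] = {}
    suffix = {"saturated": "Sat.", "unsaturated": "Unsat."}
    for a in annotations:
        if a.saturation_category not in suffix:
            continue
        key = f"{a.lipid_class} ({suffix[a.saturation_category]})"
        sets.setdefault(key, []).append(a.lipid_name)
    return {k: v for k, v in sets.items() if len(v) >= min_set_size}


def ks_class_enrichment(
    results: pd.DataFrame,
    lipid_sets: dict[str, Sequence[str]],
    min_set_size: int = 3,
    exact_limit: int = 100_000,
) -> pd.DataFrame:
    """Lipid-class enrichment over per-lipid log2 fold changes.

    For every region/contrast in ``results`` and every set: the member fold
    changes are compared against all non-member lipids by the one-sided KS
    test in both directions; Benjamini–Hochberg FDR is applied across all
    set x direction tests within the region/contrast.  Undersized sets are
    skipped with a log entry.
    """
    rows = []
    for (region, contrast), sub in results.groupby(["region", "contrast"], sort=False):
        sub = sub.dropna(subset=["log2_fc"]).drop_duplicates(subset="lipid")
        lfc = sub.set_index("lipid")["log2_fc"]
        block = []
        for set_id, members in lipid_sets.items():
            mem = lfc[lfc.index.isin(members)].to_numpy()
            bg = lfc[~lfc.index.isin(members)].to_numpy()
            if mem.size < min_set_size or bg.size == 0:
                logger.info(
                    "skipping set %s in %s / %s: %d member(s) with fold changes",
                    set_id, region, contrast, mem.size,
                )
                continue
            for direction in ("increase", "decrease"):
                stat, p = ks_enrichment_test(mem, bg, direction, exact_limit)
                block.append(
                    {
                        "set_id": set_id,
                        "region": region,
                        "contrast": contrast,
                        "direction": direction,
                        "set_size": int(mem.size),
                        "ks_statistic": stat,
                        "p_value": p,
                    }
                )
        if block:
            pvals = [b["p_value"] for b in block]
            qvals = multipletests(pvals, method="fdr_bh")[1]
            for b, q in zip(block, qvals):
                b["fdr_q"] = float(q)
            rows.extend(block)
    return pd.DataFrame(rows)
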