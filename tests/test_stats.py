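"""Region summaries, ANOVA/Tukey, volcano rules and KS class enrichment."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from msiregion import (
    classify_volcano,
    differential_anova,
    ks_class_enrichment,
    ks_enrichment_test,
    summarize_regions,
)
from msiregion.annotate import LipidAnnotation
from msiregion.io import LibraryEntry


def _annotation(name, cls="PE", db=4, mz=700.0):
    entry = LibraryEntry(name, cls, 40, db, mz, "negative")
    a = LipidAnnotation(mz, entry, 0.0)
    a.saturation_category = "unsaturated" if db > 1 else "saturated"
    return a


class TestSummarizeRegions:
    def test_mean_and_log2_oracle(self, matrix_factory):
        """Region pixels {2,4,8,16} average to 7.5, log2 = 2.9069."""
        fm = matrix_factory([[2.0], [4.0], [8.0], [16.0]], feature_mz=[700.0])
        regions = {"s1": np.array(["airway_epithelium"] * 4, dtype=object)}
        df = summarize_regions([fm], regions, [_annotation("PE 38:4")])
        assert df["mean_intensity"].iloc[0] == pytest.approx(7.5)
        assert df["log2_mean"].iloc[0] == pytest.approx(np.log2(7.5), abs=1e-4)
        assert df["pixel_count"].iloc[0] == 4

    def test_zeros_included_in_mean(self, matrix_factory):
        fm = matrix_factory([[4.0], [0.0]], feature_mz=[700.0])
        regions = {"s1": np.array(["alveolar_epithelium"] * 2, dtype=object)}
        df = summarize_regions([fm], regions, [_annotation("PE 38:4")])
        assert df["mean_intensity"].iloc[0] == pytest.approx(2.0)

    def test_all_zero_region_has_missing_log2(self, matrix_factory):
        fm = matrix_factory([[0.0], [0.0]], feature_mz=[700.0])
        regions = {"s1": np.array(["alveolar_epithelium"] * 2, dtype=object)}
        df = summarize_regions([fm], regions, [_annotation("PE 38:4")])
        assert np.isnan(df["log2_mean"].iloc[0])

    def test_single_pixel_region_identity(self, matrix_factory):
        fm = matrix_factory([[5.0], [9.0]], feature_mz=[700.0])
        regions = {
            "s1": np.array(["airway_epithelium", "alveolar_epithelium"], dtype=object)
        }
        df = summarize_regions([fm], regions, [_annotation("PE 38:4")])
        by_region = df.set_index("region")["mean_intensity"]
        assert by_region["airway_epithelium"] == 5.0

    def test_off_tissue_excluded(self, matrix_factory):
        fm = matrix_factory([[5.0], [9.0]], feature_mz=[700.0])
        regions = {"s1": np.array(["off_tissue", "alveolar_epithelium"], dtype=object)}
        df = summarize_regions([fm], regions, [_annotation("PE 38:4")])
        assert set(df["region"]) == {"alveolar_epithelium"}


def _summary_frame(group_values, lipid="PE 38:4", region="alveolar_epithelium"):
    """Summaries with one observation per sample for given cell -> values."""
    rows = []
    i = 0
    for (sex, group), values in group_values.items():
        for v in values:
            rows.append(
                {
                    "sample_id": f"s{i}",
                    "group": group,
                    "sex": sex,
                    "region": region,
                    "lipid": lipid,
                    "lipid_class": "PE",
                    "saturation": "unsaturated",
                    "pixel_count": 10,
                    "mean_intensity": 2.0**v,
                    "log2_mean": v,
                }
            )
            i += 1
    return pd.DataFrame(rows)


class TestDifferentialAnova:
    def test_identical_groups_null(self):
        df = _summary_frame(
            {("F", "control"): [3, 3], ("F", "HDM+O3"): [3, 3]}
        )
        res = differential_anova(df)
        assert res["p_value"].iloc[0] == pytest.approx(1.0)
        assert res["log2_fc"].iloc[0] == 0.0

    def test_f_statistic_closed_form(self):
        """Groups {1,2,3},{2,3,4},{6,7,8}: hand-computed F = 21."""
        df = _summary_frame(
            {
                ("F", "a"): [1, 2, 3],
                ("F", "b"): [2, 3, 4],
                ("F", "c"): [6, 7, 8],
            }
        )
        res = differential_anova(df)
        # SSB = 3[(2-4)^2+(3-4)^2+(7-4)^2] = 42, MSB = 21; SSW = 6, MSW = 1
        assert res["f_statistic"].iloc[0] == pytest.approx(21.0, abs=1e-8)

    def test_two_groups_equal_t_test(self):
        """With two groups the ANOVA p equals the pooled t-test p (F = t^2)."""
        a, b = [1.0, 2.2, 3.1], [4.0, 5.5, 4.8]
        df = _summary_frame({("F", "control"): a, ("F", "HDM+O3"): b})
        res = differential_anova(df)
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res["p_value"].iloc[0] == pytest.approx(p, abs=1e-8)
        assert res["f_statistic"].iloc[0] == pytest.approx(t**2, abs=1e-8)

    def test_insufficient_replication_skipped(self):
        df = _summary_frame({("F", "control"): [1.0], ("F", "HDM+O3"): [2.0]})
        res = differential_anova(df)
        assert res.empty

    def test_shift_invariance(self):
        base = {("F", "a"): [1.0, 2.0, 3.0], ("F", "b"): [4.0, 6.0, 5.0]}
        shifted = {k: [v + 100 for v in vals] for k, vals in base.items()}
        f0 = differential_anova(_summary_frame(base))["f_statistic"].iloc[0]
        f1 = differential_anova(_summary_frame(shifted))["f_statistic"].iloc[0]
        assert f0 == pytest.approx(f1, rel=1e-9)

    def test_log2fc_antisymmetric(self):
        """Both contrast orientations are reported with opposite fold change
        and identical adjusted p."""
        df = _summary_frame({("F", "a"): [1.0, 2.0], ("F", "b"): [5.0, 6.0]})
        res = differential_anova(df).set_index("contrast")
        ab, ba = res.loc["F:a vs F:b"], res.loc["F:b vs F:a"]
        assert ab["log2_fc"] == pytest.approx(-ba["log2_fc"])
        assert ab["log2_fc"] == pytest.approx(1.5 - 5.5)
        assert ab["tukey_adjusted_p"] == ba["tukey_adjusted_p"]


class TestVolcano:
    @pytest.mark.parametrize(
        "p,lfc,sig,high",
        [
            (0.04, 0.6, True, True),
            (0.06, 2.0, False, True),
            (0.04, 0.5, True, False),  # boundary: strict inequality
            (0.5, 0.1, False, False),
        ],
    )
    def test_threshold_rules(self, p, lfc, sig, high):
        df = pd.DataFrame(
            {"log2_fc": [lfc], "tukey_adjusted_p": [p]}
        )
        out = classify_volcano(df)
        assert bool(out["significant"].iloc[0]) is sig
        assert bool(out["high_effect"].iloc[0]) is high


class TestKsEnrichment:
    def test_top3_of_10_exact_permutation(self):
        """A 3-member set holding the 3 largest fold changes: D+ = 1 and the
        p equals the enumerated tail 1/C(10,3)."""
        values = np.arange(10, dtype=float)
        stat, p = ks_enrichment_test(values[-3:], values[:-3], "increase")
        assert stat == 1.0
        # independent enumeration oracle
        def dplus(mem, bg):
            grid = np.sort(np.concatenate([mem, bg]))
            fm = np.searchsorted(np.sort(mem), grid, "right") / len(mem)
            fb = np.searchsorted(np.sort(bg), grid, "right") / len(bg)
            return np.max(fb - fm)

        hits = sum(
            dplus(values[list(c)], np.delete(values, list(c))) >= 1.0
            for c in combinations(range(10), 3)
        )
        assert p == pytest.approx(hits / 120)
        assert p == pytest.approx(1 / 120)

    def test_directions_are_mirror_images(self, rng):
        mem = rng.normal(1, 1, 8)
        bg = rng.normal(0, 1, 40)
        s_inc, p_inc = ks_enrichment_test(mem, bg, "increase")
        s_dec, p_dec = ks_enrichment_test(-mem, -bg, "decrease")
        assert s_inc == pytest.approx(s_dec)
        assert p_inc == pytest.approx(p_dec)

    def test_null_calibration(self, rng):
        """Type-I error near the nominal 5% when the set is exchangeable with
        the background (seeded Monte Carlo)."""
        n_rej = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(0, 1, 100)
            _, p = ks_enrichment_test(x[:10], x[10:], "increase", exact_limit=0)
            n_rej += p < 0.05
        assert 0.02 <= n_rej / reps <= 0.08

    def test_null_pvalues_calibrated_at_all_levels(self, rng):
        """Null enrichment p-values hit their nominal levels.

        The one-sided D+ statistic is discrete for small sets, so instead of
        a continuous-uniformity test the empirical CDF is checked at several
        nominal levels (seeded Monte Carlo, binomial tolerance)."""
        pvals = np.array(
            [
                ks_enrichment_test(x[:10], x[10:], "increase", exact_limit=0)[1]
                for x in rng.normal(0, 1, (500, 60))
            ]
        )
        for alpha in (0.05, 0.1, 0.25, 0.5):
            assert abs((pvals <= alpha).mean() - alpha) < 0.06


class TestKsClassEnrichment:
    def _results(self, lfcs, classes):
        return pd.DataFrame(
            {
                "lipid": [f"L{i}" for i in range(len(lfcs))],
                "lipid_class": classes,
                "region": "alveolar_epithelium",
                "contrast": "F:HDM+O3 vs F:control",
                "log2_fc": lfcs,
            }
        )

    def test_planted_decrease_detected(self, rng):
        lfcs = np.concatenate([np.full(8, -1.2) + rng.normal(0, 0.05, 8),
                               rng.normal(0, 0.1, 40)])
        res = self._results(lfcs, ["PE"] * 8 + ["PC"] * 40)
        sets = {"PE (Unsat.)": [f"L{i}" for i in range(8)]}
        enr = ks_class_enrichment(res, sets)
        dec = enr[enr.direction == "decrease"].iloc[0]
        assert dec["fdr_q"] < 0.05
        inc = enr[enr.direction == "increase"].iloc[0]
        assert inc["p_value"] > 0.5

    def test_undersized_set_skipped(self):
        res = self._results([0.1, 0.2, 0.3, 0.4], ["PE", "PE", "PC", "PC"])
        enr = ks_class_enrichment(res, {"PE (Unsat.)": ["L0", "L1"]}, min_set_size=3)
        assert enr.empty

    def test_bh_q_monotone_in_p_rank(self, rng):
        lfcs = rng.normal(0, 1, 60)
        classes = [f"C{i % 6}" for i in range(60)]
        res = self._results(lfcs, classes)
        sets = {
            f"C{j}": [f"L{i}" for i in range(60) if i % 6 == j] for j in range(6)
        }
        enr = ks_class_enrichment(res, sets)
        enr = enr.sort_values("p_value")
        assert enr["fdr_q"].is_monotonic_increasing
        assert ((enr["fdr_q"] >= enr["p_value"] - 1e-12)).all()
        assert enr["p_value"].between(0, 1).all() and enr["fdr_q"].between(0, 1).all()
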