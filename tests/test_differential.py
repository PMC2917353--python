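"""Normalized intensity, splicing index, ANOVA, BH and pairwise tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from exonsplice.differential import (
    anova_oneway,
    anova_oneway_rows,
    bh_reject,
    bh_threshold,
    normalized_intensity,
    pairwise_tests,
    run_concurrent_analyses,
    splicing_index,
)
from exonsplice.models import ParameterError
from exonsplice.summarize import SummaryMatrices


def _design(groups):
    names, labels = [], []
    for g, n in groups.items():
        for i in range(n):
            names.append(f"{g}{i}")
            labels.append(g)
    return pd.Series(labels, index=names)


class TestNormalizedIntensity:
    def _summary(self, ps_vals, gene_vals):
        cols = ["s1", "s2"]
        ps = pd.DataFrame([ps_vals], index=["ps1"], columns=cols)
        gene = pd.DataFrame([gene_vals], index=["g1"], columns=cols)
        anno = pd.DataFrame({"gene_id": ["g1"]}, index=["ps1"])
        return SummaryMatrices(ps, gene), anno

    def test_elementwise_ratio(self):
        sm, anno = self._summary([8.0, 8.0], [16.0, 16.0])
        ni = normalized_intensity(sm, anno)
        np.testing.assert_allclose(ni.to_numpy(), 0.5)

    def test_identity_when_probeset_equals_gene(self):
        sm, anno = self._summary([16.0, 16.0], [16.0, 16.0])
        np.testing.assert_allclose(
            normalized_intensity(sm, anno).to_numpy(), 1.0
        )

    def test_invariant_under_sample_rescaling(self):
        sm, anno = self._summary([8.0, 12.0], [16.0, 24.0])
        ni1 = normalized_intensity(sm, anno)
        sm.probeset_signal["s2"] *= 10.0
        sm.gene_signal["s2"] *= 10.0
        ni2 = normalized_intensity(sm, anno)
        np.testing.assert_allclose(ni1.to_numpy(), ni2.to_numpy(), rtol=1e-12)


class TestSplicingIndex:
    design = _design({"A": 2, "B": 2})

    def _ni(self, a, b):
        return pd.DataFrame([a + b], index=["ps1"], columns=self.design.index)

    def test_identical_groups_give_unity(self):
        si = splicing_index(self._ni([1.0, 1.0], [1.0, 1.0]), self.design, ("A", "B"))
        assert si["ps1"] == pytest.approx(1.0)

    def test_ratio_of_geometric_means(self):
        si = splicing_index(
            self._ni([0.5, 0.5], [0.125, 0.125]), self.design, ("A", "B")
        )
        assert si["ps1"] == pytest.approx(4.0)
        assert np.log2(si["ps1"]) == pytest.approx(2.0)

    def test_reciprocity(self):
        ni = self._ni([0.7, 0.9], [0.2, 0.4])
        ab = splicing_index(ni, self.design, ("A", "B"))
        ba = splicing_index(ni, self.design, ("B", "A"))
        assert ab["ps1"] * ba["ps1"] == pytest.approx(1.0, rel=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ParameterError):
            splicing_index(self._ni([1, 1], [1, 1]), self.design, ("A", "C"))


class TestAnova:
    def test_identical_groups_give_p_one(self):
        assert anova_oneway([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])]) == 1.0

    def test_zero_within_variance_distinct_means(self):
        p = anova_oneway([np.zeros(4), np.ones(4), np.full(4, 2.0)])
        assert p == 0.0

    def test_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1.0, size=4) for m in (0.0, 0.5, 1.0)]
        # explicit SS decomposition
        allv = np.concatenate(groups)
        grand = allv.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        F = (ssb / 2) / (ssw / (len(allv) - 3))
        expected = sps.f.sf(F, 2, len(allv) - 3)
        assert anova_oneway(groups) == pytest.approx(expected, abs=1e-12)
        assert anova_oneway(groups) == pytest.approx(
            sps.f_oneway(*groups).pvalue, abs=1e-12
        )

    def test_rowwise_matches_scipy_on_random_rows(self):
        rng = np.random.default_rng(8)
        blocks = [rng.normal(size=(50, n)) for n in (4, 5, 4)]
        p = anova_oneway_rows(blocks)
        for i in range(50):
            ref = sps.f_oneway(*[b[i] for b in blocks]).pvalue
            assert p[i] == pytest.approx(ref, abs=1e-10)


class TestBhThreshold:
    def test_hand_enumerated_step_up(self):
        assert bh_threshold([0.001, 0.02, 0.03, 0.9], 0.05) == pytest.approx(0.03)

    def test_all_ones_gives_zero(self):
        assert bh_threshold([1.0, 1.0, 1.0], 0.05) == 0.0

    def test_single_p_reduces_to_raw_alpha(self):
        assert bh_threshold([0.04], 0.05) == pytest.approx(0.04)
        assert bh_threshold([0.06], 0.05) == 0.0

    def test_rejections_match_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(0, 1e-3, 20), rng.uniform(0, 1, 200)])
        flags, _cutoff = bh_reject(pd.Series(p), alpha=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        np.testing.assert_array_equal(flags.to_numpy(), ref)

    def test_zero_pvalues_are_rejected(self):
        flags, cutoff = bh_reject(pd.Series([0.0, 0.0, 0.9]), alpha=0.05)
        assert cutoff == 0.0
        assert list(flags) == [True, True, False]

    def test_empty_list_warns(self):
        with pytest.warns(UserWarning):
            assert bh_threshold([], 0.05) == 0.0


class TestPairwise:
    design = _design({"A": 4, "B": 4})

    def test_identical_groups(self):
        vals = pd.DataFrame(
            [[1.0, 2, 3, 4, 1, 2, 3, 4]], index=["ps1"], columns=self.design.index
        )
        res = pairwise_tests(vals, self.design, reference="B")
        assert res["A"].loc["ps1", "log2fc"] == pytest.approx(0.0)
        assert res["A"].loc["ps1", "t_p"] == pytest.approx(1.0)

    def test_fold_change_sign_convention(self):
        # log2 means 3 (group A) and 1 (reference) -> fc = +2 toward A
        vals = pd.DataFrame(
            [[3.0] * 4 + [1.0] * 4], index=["ps1"], columns=self.design.index
        )
        res = pairwise_tests(vals, self.design, reference="B")
        assert res["A"].loc["ps1", "log2fc"] == pytest.approx(2.0)

    def test_matches_explicit_formula_and_scipy(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 4), rng.normal(0.5, 1, 4)
        vals = pd.DataFrame(
            [np.concatenate([a, b])], index=["ps1"], columns=self.design.index
        )
        res = pairwise_tests(vals, self.design, reference="B")
        sp2 = (3 * a.var(ddof=1) + 3 * b.var(ddof=1)) / 6
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * 0.5)
        p_manual = 2 * sps.t.sf(abs(t), 6)
        assert res["A"].loc["ps1", "t_p"] == pytest.approx(p_manual, abs=1e-12)
        assert res["A"].loc["ps1", "t_p"] == pytest.approx(
            sps.ttest_ind(a, b).pvalue, abs=1e-12
        )

    def test_welch_option_matches_scipy(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 4), rng.normal(0, 3, 4)
        vals = pd.DataFrame(
            [np.concatenate([a, b])], index=["ps1"], columns=self.design.index
        )
        res = pairwise_tests(vals, self.design, reference="B", equal_var=False)
        assert res["A"].loc["ps1", "t_p"] == pytest.approx(
            sps.ttest_ind(a, b, equal_var=False).pvalue, abs=1e-12
        )


class TestConcurrentAnalyses:
    def test_injected_cassette_found_and_gene_level_restriction_holds(
        self, results200, truth200
    ):
        tbl = results200.stats.table
        gene_sig = results200.stats.gene_table["sig_gene"]
        # SI analysis never reports a probe set from a gene-level rejection
        si_genes = tbl.loc[tbl["sig_si"], "gene_id"].unique()
        assert not gene_sig.reindex(si_genes).fillna(False).any()
        # at least 80% of injected cassette exons surface in an analysis
        cassettes = [
            ps for ps, inj in truth200.ase.items()
            if inj.kind == "cassette_exon" and ps in tbl.index
        ]
        flagged = (tbl["sig_expr"] | tbl["sig_si"]).reindex(cassettes)
        assert flagged.mean() >= 0.8

    def test_whole_gene_shift_detected_at_gene_level(self, results200, truth200):
        gene_sig = results200.stats.gene_table["sig_gene"]
        shifted = [g for g in truth200.gene_effects if g in gene_sig.index]
        assert gene_sig.reindex(shifted).mean() >= 0.8

    def test_statistics_invariant_under_column_permutation(self, dataset200):
        from exonsplice.models import ExpressionStudy
        from exonsplice.summarize import summarize_study

        study, _ = dataset200
        sm = summarize_study(study)
        from exonsplice.differential import normalized_intensity

        anno = study.annotation
        ni = normalized_intensity(sm, anno)
        stats1 = run_concurrent_analyses(sm, ni, anno, study.design)
        # permute sample columns within groups
        perm = []
        for g in study.groups:
            cols = [c for c in sm.probeset_signal.columns if study.design[c] == g]
            perm.extend(cols[::-1])
        sm2 = SummaryMatrices(
            sm.probeset_signal[perm], sm.gene_signal[perm], sm.dabg_p[perm]
        )
        stats2 = run_concurrent_analyses(sm2, ni[perm], anno, study.design)
        np.testing.assert_allclose(
            stats1.table["anova_p_expr"].to_numpy(),
            stats2.table["anova_p_expr"].to_numpy(), atol=1e-12,
        )
        np.testing.assert_allclose(
            stats1.table["anova_p_si"].to_numpy(),
            stats2.table["anova_p_si"].to_numpy(), atol=1e-12,
        )

    def test_log2fc_ni_consistent_with_splicing_index(self, dataset200):
        from exonsplice.summarize import summarize_study
        from exonsplice.differential import normalized_intensity

        study, _ = dataset200
        sm = summarize_study(study)
        anno = study.annotation
        ni = normalized_intensity(sm, anno)
        stats1 = run_concurrent_analyses(sm, ni, anno, study.design,
                                         reference="4T1")
        si = splicing_index(ni, study.design, ("168FARN", "4T1"))
        np.testing.assert_allclose(
            stats1.table["log2fc_ni_168FARN"].to_numpy(),
            np.log2(si.reindex(stats1.table.index).to_numpy()),
            atol=1e-9,
        )

    def test_all_null_probe_sets_rarely_rejected(self):
        rng = np.random.default_rng(12)
        design = _design({"A": 4, "B": 5, "C": 4})
        m = 2000
        blocks = [rng.normal(7, 0.25, size=(m, n)) for n in (4, 5, 4)]
        p = anova_oneway_rows(blocks)
        flags, _ = bh_reject(pd.Series(p), alpha=0.05)
        assert flags.sum() <= 2 * 0.05 * m
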