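"""Filtering cascade: outlier replicates, probe-set and gene criteria."""

import numpy as np
import pandas as pd
import pytest

from exonsplice.filtering import (
    FilterConfig,
    detect_outlier_replicates,
    filter_genes,
    filter_probesets,
    present_calls,
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


class TestPresentCalls:
    design = _design({"A": 4, "B": 5})

    def _dabg(self, a_ps, b_ps):
        return pd.DataFrame([list(a_ps) + list(b_ps)], index=["ps1"],
                            columns=self.design.index)

    def test_half_of_four_replicates_counts(self):
        table, flag = present_calls(
            self._dabg([0.01, 0.01, 0.9, 0.9], [1, 1, 1, 1, 1]), self.design
        )
        assert bool(table.loc["ps1", "A"]) is True
        assert bool(flag["ps1"]) is True

    def test_all_absent_fails(self):
        _t, flag = present_calls(
            self._dabg([1, 1, 1, 1], [1, 1, 1, 1, 1]), self.design
        )
        assert bool(flag["ps1"]) is False

    def test_two_of_five_is_below_half(self):
        table, _ = present_calls(
            self._dabg([1, 1, 1, 1], [0.01, 0.01, 1, 1, 1]), self.design
        )
        assert bool(table.loc["ps1", "B"]) is False


def _toy_summary_and_annotation():
    """One gene, four probe sets engineered to trip individual criteria."""
    design = _design({"A": 2, "B": 2})
    cols = design.index
    ps = pd.DataFrame(
        {
            "ps_ok": [50.0] * 4,       # NI = 0.5, passes everything
            "ps_xhyb": [50.0] * 4,     # fails cross-hyb flag
            "ps_hi_ni": [600.0] * 4,   # NI = 6, fails upper bound
            "ps_lo_ni": [10.0] * 4,    # NI = 0.1, fails lower bound
        },
        index=cols,
    ).T
    gene = pd.DataFrame([[100.0] * 4], index=["g1"], columns=cols)
    dabg_p = pd.DataFrame(0.01, index=ps.index, columns=cols)
    anno = pd.DataFrame(
        {
            "gene_id": "g1",
            "kind": "exon",
            "tier": "core",
            "xhyb": [1, 2, 1, 1],
            "order": range(4),
        },
        index=ps.index,
    )
    return SummaryMatrices(ps, gene, dabg_p), anno, design


class TestFilterProbesets:
    def test_each_criterion_removes_its_probe_set(self):
        sm, anno, design = _toy_summary_and_annotation()
        retained, report = filter_probesets(sm, anno, design)
        assert list(retained) == ["ps_ok"]
        assert report.probeset_losses == {
            "present_call": 0, "xhyb": 1, "ni_upper": 1, "ni_lower": 1,
        }

    def test_conjunctive_final_set_is_intersection(self):
        sm, anno, design = _toy_summary_and_annotation()
        retained, _ = filter_probesets(sm, anno, design)
        cfg = FilterConfig()
        present_tbl, present = present_calls(sm.dabg_p, design)
        ni = (sm.probeset_signal / 100.0).mean(axis=1)
        manual = sm.probeset_signal.index[
            present.values
            & anno["xhyb"].isin(cfg.xhyb_allowed).values
            & (ni < cfg.ni_high).values
            & (ni > cfg.ni_low).values
        ]
        assert list(retained) == list(manual)

    def test_idempotent(self):
        sm, anno, design = _toy_summary_and_annotation()
        retained, _ = filter_probesets(sm, anno, design)
        sm2 = SummaryMatrices(
            sm.probeset_signal.loc[retained],
            sm.gene_signal,
            sm.dabg_p.loc[retained],
        )
        retained2, _ = filter_probesets(sm2, anno.loc[retained], design)
        assert list(retained2) == list(retained)

    def test_tightening_thresholds_never_grows_retained_set(self):
        sm, anno, design = _toy_summary_and_annotation()
        base, _ = filter_probesets(sm, anno, design)
        tighter = FilterConfig(ni_low=0.45, ni_high=2.0, dabg_alpha=0.001)
        sub, _ = filter_probesets(sm, anno, design, tighter)
        assert set(sub) <= set(base)


class TestFilterGenes:
    def _inputs(self, intensity=100.0, groups_present=2):
        design = _design({"A": 2, "B": 2, "C": 2})
        anno = pd.DataFrame(
            {
                "gene_id": "g1",
                "kind": "exon",
                "tier": "core",
                "xhyb": 1,
                "order": range(4),
            },
            index=[f"ps{i}" for i in range(4)],
        )
        present = pd.DataFrame(False, index=anno.index, columns=["A", "B", "C"])
        for g in ["A", "B", "C"][:groups_present]:
            present.loc[["ps0", "ps1"], g] = True  # 2 of 4 core exons present
        gene_signal = pd.DataFrame(
            [[intensity] * 6], index=["g1"], columns=design.index
        )
        return anno.index, present, gene_signal, anno

    def test_passing_gene_retained(self):
        ps, present, gs, anno = self._inputs()
        retained, _ = filter_genes(ps, present, gs, anno)
        assert list(retained) == ["g1"]

    def test_intensity_just_below_threshold_excluded(self):
        ps, present, gs, anno = self._inputs(intensity=29.9)
        retained, report = filter_genes(ps, present, gs, anno)
        assert len(retained) == 0
        assert report.gene_losses["gene_intensity"] == 1

    def test_present_in_single_group_excluded(self):
        ps, present, gs, anno = self._inputs(groups_present=1)
        retained, report = filter_genes(ps, present, gs, anno)
        assert len(retained) == 0
        assert report.gene_losses["core_present"] == 1

    def test_gene_without_core_exons_fails_and_is_logged(self):
        ps, present, gs, anno = self._inputs()
        anno = anno.assign(tier="noncore")
        retained, report = filter_genes(ps, present, gs, anno)
        assert len(retained) == 0
        assert any("zero core" in n for n in report.notes)


class TestOutlierDetection:
    def test_identical_replicates_give_empty_set(self):
        design = _design({"A": 3, "B": 3})
        gs = pd.DataFrame(
            np.tile([[100.0], [50.0], [80.0]], (1, 6)),
            index=["g1", "g2", "g3"], columns=design.index,
        )
        assert detect_outlier_replicates(gs, design) == []

    def test_infinite_multiplier_flags_nothing(self, dataset200):
        from exonsplice.summarize import summarize_study

        study, _ = dataset200
        sm = summarize_study(study)
        out = detect_outlier_replicates(sm.gene_signal, study.design, 1e12)
        assert out == []

    def test_injected_outlier_is_the_only_flagged_sample(self, results200):
        assert results200.filter_report.outliers_removed == ["4T07_5"]

    def test_too_few_samples_rejected(self):
        design = _design({"A": 2})
        gs = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=design.index)
        with pytest.raises(ParameterError):
            detect_outlier_replicates(gs, design)
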