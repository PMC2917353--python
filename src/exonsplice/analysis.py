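"""Model/Results interface tying the pipeline stages together.

:class:`ExonArrayAnalysis` is built from an :class:`ExpressionStudy` (raw
probe-set intensities, design, annotation, background probes); calling
:meth:`~ExonArrayAnalysis.fit` runs summarization, outlier removal, the
filtering cascade, the two concurrent differential analyses and event
classification, returning an :class:`ExonArrayResults` that carries the
estimates, their significance, diagnostics and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as esio
from .classify import (
    ASECall,
    category_proportions,
    classify_all,
    tally_group_specific_introns,
)
from .differential import (
    ProbeSetStats,
    normalized_intensity,
    run_concurrent_analyses,
)
from .filtering import (
    FilterConfig,
    FilterReport,
    detect_outlier_replicates,
    filter_genes,
    filter_probesets,
    present_calls,
)
from .models import ExpressionStudy
from .summarize import SummaryMatrices, summarize_study
from .tracks import export_tracks, report_run


class ExonArrayAnalysis:
    """Exon-level differential expression / alternative splicing analysis.

    Parameters
    ----------
    study:
        The raw probe-set x sample study.
    config:
        Filtering thresholds; defaults mirror the standard exon-array
        workflow (DABG 0.05, 50% present, xhyb == 1, NI in (0.20, 5),
        gene intensity > 30, 3-SD PCA outlier rule).
    alpha:
        Nominal FDR level for all three BH families.
    reference:
        Reference group for pairwise comparisons; defaults to the last
        group in design order (the fully metastatic line in the emulated
        design).
    """

    def __init__(
        self,
        study: ExpressionStudy,
        config: FilterConfig | None = None,
        alpha: float = 0.05,
        reference: str | None = None,
        equal_var: bool = True,
        min_run: int = 2,
        remove_outliers: bool = True,
    ) -> None:
        self.study = study
        self.config = config or FilterConfig()
        self.alpha = alpha
        self.reference = reference
        self.equal_var = equal_var
        self.min_run = min_run
        self.remove_outliers = remove_outliers

    @classmethod
    def from_tsv(cls, in_dir, **kwargs) -> "ExonArrayAnalysis":
        """Build from a directory written by :func:`exonsplice.io.write_study`."""
        return cls(esio.read_study(in_dir), **kwargs)

    def fit(self) -> "ExonArrayResults":
        study = self.study
        summary = summarize_study(study)
        outliers: list[str] = []
        if self.remove_outliers:
            outliers = detect_outlier_replicates(
                summary.gene_signal, study.design, self.config.pca_sd_multiplier
            )
            if outliers:
                study = study.drop_samples(outliers)
                summary = summarize_study(study)

        report = FilterReport(outliers_removed=outliers)
        anno = study.annotation
        retained_ps, report = filter_probesets(
            summary, anno, study.design, self.config, report
        )
        present_table, _flags = present_calls(
            summary.dabg_p, study.design,
            self.config.dabg_alpha, self.config.present_fraction,
        )
        retained_genes, report = filter_genes(
            retained_ps, present_table, summary.gene_signal, anno,
            self.config, report,
        )
        # analyzable set: retained probe sets whose gene also survived
        gene_of = anno.loc[retained_ps, "gene_id"]
        final_ps = retained_ps[gene_of.isin(retained_genes).to_numpy()]

        sub = SummaryMatrices(
            probeset_signal=summary.probeset_signal.loc[final_ps],
            gene_signal=summary.gene_signal.loc[retained_genes],
            dabg_p=summary.dabg_p.loc[final_ps],
        )
        ni = normalized_intensity(sub, anno)
        stats = run_concurrent_analyses(
            sub, ni, anno, study.design, alpha=self.alpha,
            reference=self.reference, equal_var=self.equal_var,
        )
        calls = classify_all(stats, anno, retained_genes, min_run=self.min_run)
        tallies = tally_group_specific_introns(stats, anno)
        return ExonArrayResults(
            model=self,
            study=study,
            summary_matrices=summary,
            filter_report=report,
            retained_probesets=final_ps,
            retained_genes=retained_genes,
            ni=ni,
            stats=stats,
            ase_calls=calls,
            intron_tallies=tallies,
        )


@dataclass
class ExonArrayResults:
    """Fitted pipeline output: statistics, thresholds, calls, diagnostics."""

    model: ExonArrayAnalysis
    study: ExpressionStudy
    summary_matrices: SummaryMatrices
    filter_report: FilterReport
    retained_probesets: pd.Index
    retained_genes: pd.Index
    ni: pd.DataFrame
    stats: ProbeSetStats
    ase_calls: list[ASECall] = field(default_factory=list)
    intron_tallies: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    def category_proportions(self) -> pd.Series:
        return category_proportions(self.ase_calls)

    def significant_genes(self) -> pd.Index:
        tbl = self.stats.table
        sig = tbl.loc[tbl["sig_expr"] | tbl["sig_si"], "gene_id"].unique()
        gene_sig = self.stats.gene_table.index[self.stats.gene_table["sig_gene"]]
        return pd.Index(sorted(set(sig) | set(gene_sig)), name="gene_id")

    def summary(self, seed: int | None = None) -> str:
        return report_run(self, seed=seed)

    def export_tracks(self, out_dir, metric: str = "expr") -> list[Path]:
        return export_tracks(self.stats, self.study.annotation, out_dir, metric)

    def to_tsv(self, out_dir) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        esio.write_stats_table(self.stats, out_dir / "probeset_stats.tsv")
        self.stats.gene_table.to_csv(out_dir / "gene_stats.tsv", sep="\t")
        calls = pd.DataFrame(
            [
                {
                    "gene_id": c.gene_id,
                    "category": c.category.value,
                    "source": c.source,
                    "probesets": ",".join(ps for ps, _ in c.supporting),
                    "directions": ",".join(d for _, d in c.supporting),
                    "secondary": ",".join(s.value for s in c.secondary),
                }
                for c in self.ase_calls
            ]
        )
        calls.to_csv(out_dir / "ase_calls.tsv", sep="\t", index=False)
        self.intron_tallies.rename("count").to_frame().to_csv(
            out_dir / "intron_tallies.tsv", sep="\t"
        )
        (out_dir / "report.txt").write_text(self.summary())
        return out_dir
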