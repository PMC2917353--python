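"""Expression filtering cascade: outlier replicates, probe sets, genes.

Before any testing, the analyzable data set is reduced in three stages:

1. PCA-based removal of biological replicates that fail to cluster with
   their tumor group (computed on log2 gene signals).
2. Probe-set criteria: (i) called Present (DABG p < 0.05) in at least 50%
   of the replicates of at least one tumor group; (ii) cross-hybridization
   potential equal to 1; (iii) mean gene-level normalized intensity below 5;
   (iv) mean gene-level normalized intensity above 0.20.
3. Gene criteria: (i) at least 50% of the gene's core exonic probe sets
   Present (>=50% of replicates) in at least two tumor groups; (ii) mean
   gene signal above 30.

The criteria are conjunctive, so the final retained set does not depend on
the order of application; the report attributes losses in cascade order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ParameterError
from .summarize import INTENSITY_FLOOR, SummaryMatrices


@dataclass
class FilterConfig:
    """Thresholds of the filtering cascade (defaults follow the study design)."""

    dabg_alpha: float = 0.05
    present_fraction: float = 0.5
    xhyb_allowed: frozenset = frozenset({1})
    ni_low: float = 0.20
    ni_high: float = 5.0
    gene_core_present_fraction: float = 0.5
    gene_groups_required: int = 2
    gene_intensity_min: float = 30.0
    pca_sd_multiplier: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.dabg_alpha < 1.0:
            raise ParameterError("dabg_alpha must be in (0, 1)")
        if not self.ni_low < self.ni_high:
            raise ParameterError("ni_low must be < ni_high")
        if self.gene_intensity_min <= 0:
            raise ParameterError("gene_intensity_min must be > 0")


@dataclass
class FilterReport:
    """Bookkeeping of what each criterion removed."""

    outliers_removed: list[str] = field(default_factory=list)
    n_probesets_in: int = 0
    n_probesets_retained: int = 0
    n_genes_in: int = 0
    n_genes_retained: int = 0
    probeset_losses: dict[str, int] = field(default_factory=dict)
    gene_losses: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def detect_outlier_replicates(
    gene_signal: pd.DataFrame,
    design: pd.Series,
    pca_sd_multiplier: float = 3.0,
) -> list[str]:
    """Flag samples that fail to cluster with their group in PC1/PC2.

    Samples are projected onto the first two principal components of the
    log2 gene signals; a sample is flagged when its distance to its own
    group centroid strictly exceeds ``pca_sd_multiplier`` times the pooled
    within-group distance SD.  The SD is computed leave-one-out so a single
    gross outlier cannot mask itself by inflating the pooled spread.
    Groups with fewer than two replicates are excluded from flagging.
    """
    if gene_signal.shape[1] < 3 or gene_signal.shape[0] < 2:
        raise ParameterError("need >=3 samples and >=2 genes for outlier detection")
    X = np.log2(np.maximum(gene_signal.to_numpy(float), INTENSITY_FLOOR)).T
    X = X - X.mean(axis=0)
    # first two PCs via SVD of the centered sample x gene matrix
    U, S, _Vt = np.linalg.svd(X, full_matrices=False)
    k = min(2, len(S))
    scores = U[:, :k] * S[:k]

    samples = list(gene_signal.columns)
    groups = design.reindex(samples)
    dists = pd.Series(np.nan, index=samples)
    for g, members in groups.groupby(groups).groups.items():
        idx = [samples.index(s) for s in members]
        if len(idx) < 2:
            warnings.warn(f"group {g!r} has <2 replicates; excluded from flagging")
            continue
        centroid = scores[idx].mean(axis=0)
        dists[list(members)] = np.linalg.norm(scores[idx] - centroid, axis=1)

    valid = dists.dropna()
    flagged: list[str] = []
    for s, d in valid.items():
        others = valid.drop(s).to_numpy()
        if len(others) < 2:
            continue
        sd = float(np.sqrt(np.mean(others**2)))
        if d > pca_sd_multiplier * sd:
            flagged.append(s)
    return flagged


def present_calls(
    dabg_p: pd.DataFrame,
    design: pd.Series,
    dabg_alpha: float = 0.05,
    present_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-group present table and the probe-set level present pass flag.

    A probe set is Present in a group when at least ``present_fraction`` of
    that group's replicates have DABG p below ``dabg_alpha``; it passes when
    Present in at least one group.
    """
    missing = set(dabg_p.columns) - set(design.index)
    if missing:
        raise ParameterError(f"design does not cover samples: {sorted(missing)}")
    calls = dabg_p < dabg_alpha
    by_group = {}
    for g, cols in design.reindex(dabg_p.columns).groupby(
        design.reindex(dabg_p.columns)
    ).groups.items():
        frac = calls[list(cols)].mean(axis=1)
        by_group[g] = frac >= present_fraction
    table = pd.DataFrame(by_group)
    return table, table.any(axis=1)


def filter_probesets(
    summary: SummaryMatrices,
    annotation: pd.DataFrame,
    design: pd.Series,
    config: FilterConfig = FilterConfig(),
    report: FilterReport | None = None,
) -> tuple[pd.Index, FilterReport]:
    """Apply the four probe-set expression criteria; returns retained ids.

    The normalized-intensity bounds are applied to each probe set's mean NI
    across samples; the mean is used for stability with 4-5 replicates per
    group.
    """
    if report is None:
        report = FilterReport()
    ps = summary.probeset_signal
    gene_of = annotation.loc[ps.index, "gene_id"]
    missing_gene = ~gene_of.isin(summary.gene_signal.index)
    if missing_gene.any():
        report.notes.append(
            f"{int(missing_gene.sum())} probe sets dropped: gene not summarized"
        )
    _table, present = present_calls(
        summary.dabg_p, design, config.dabg_alpha, config.present_fraction
    )
    present = present.reindex(ps.index, fill_value=False)

    xhyb_ok = annotation.loc[ps.index, "xhyb"].isin(config.xhyb_allowed)

    gsig = summary.gene_signal.reindex(gene_of).to_numpy(float)
    ni = ps.to_numpy(float) / np.maximum(gsig, INTENSITY_FLOOR)
    mean_ni = pd.Series(ni.mean(axis=1), index=ps.index)
    ni_upper_ok = mean_ni < config.ni_high
    ni_lower_ok = mean_ni > config.ni_low

    keep = ~missing_gene.values
    report.n_probesets_in = len(ps)
    cascade = [
        ("present_call", present.values),
        ("xhyb", xhyb_ok.values),
        ("ni_upper", ni_upper_ok.values),
        ("ni_lower", ni_lower_ok.values),
    ]
    for name, ok in cascade:
        lost = int(np.sum(keep & ~ok))
        report.probeset_losses[name] = lost
        keep = keep & ok
    retained = ps.index[keep]
    report.n_probesets_retained = len(retained)
    return retained, report


def filter_genes(
    retained_probesets: pd.Index,
    present_by_group: pd.DataFrame,
    gene_signal: pd.DataFrame,
    annotation: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
    report: FilterReport | None = None,
) -> tuple[pd.Index, FilterReport]:
    """Apply the two gene-level criteria over genes of retained probe sets."""
    if report is None:
        report = FilterReport()
    genes = annotation.loc[
        annotation.index.intersection(retained_probesets), "gene_id"
    ].unique()
    genes = pd.Index(genes, name="gene_id")
    report.n_genes_in = len(genes)

    core_exon = annotation[
        (annotation["kind"] == "exon") & (annotation["tier"] == "core")
    ]
    core_ok = {}
    for gid in genes:
        ids = core_exon.index[core_exon["gene_id"] == gid]
        if len(ids) == 0:
            core_ok[gid] = False
            continue
        pres = present_by_group.reindex(ids).fillna(False).astype(bool)
        frac_per_group = pres.mean(axis=0)
        n_groups = int((frac_per_group >= config.gene_core_present_fraction).sum())
        core_ok[gid] = n_groups >= config.gene_groups_required
    core_ok = pd.Series(core_ok)
    n_no_core = int(
        (core_exon.groupby("gene_id").size().reindex(genes).fillna(0) == 0).sum()
    )
    if n_no_core:
        report.notes.append(f"{n_no_core} genes have zero core exonic probe sets")

    mean_int = gene_signal.reindex(genes).mean(axis=1)
    intensity_ok = mean_int > config.gene_intensity_min

    keep = np.ones(len(genes), dtype=bool)
    for name, ok in [
        ("core_present", core_ok.reindex(genes).values),
        ("gene_intensity", intensity_ok.values),
    ]:
        lost = int(np.sum(keep & ~ok))
        report.gene_losses[name] = lost
        keep = keep & ok
    retained = genes[keep]
    report.n_genes_retained = len(retained)
    return retained, report
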