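"""Differential exon usage: normalized intensity, splicing index, tests.

Two concurrent probe-set analyses are run across tumor groups:

* an *expression-intensity* analysis — one-way ANOVA on log2 probe-set
  signals; and
* a *splicing-index* (SI) analysis — one-way ANOVA on log2 gene-level
  normalized intensities (NI = probe-set signal / its gene's meta-probe-set
  signal), restricted to genes whose overall expression does not change,
  because dividing by the gene signal only isolates splicing when the
  denominator is stable.

Gene-level ANOVA on log2 meta-probe-set signals determines which genes
change as a whole.  Each of the three p-value families (gene, probe-set
expression, SI) receives its own Benjamini-Hochberg step-up threshold at
FDR 0.05.  Pairwise two-sample t-tests and log2 fold-changes are computed
for every non-reference group against the reference group (positive
fold-change = higher in the non-reference group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import ParameterError
from .summarize import INTENSITY_FLOOR, SummaryMatrices


@dataclass
class FdrThresholds:
    """BH step-up p-value cutoffs for the three test families."""

    alpha: float = 0.05
    t_expr: float = 0.0
    t_si: float = 0.0
    t_gene: float = 0.0


@dataclass
class ProbeSetStats:
    """Per-probe-set and per-gene test results.

    ``table`` has one row per probe set with columns ``gene_id``, ``kind``,
    ``anova_p_expr``, ``anova_p_si``, ``sig_expr``, ``sig_si``,
    ``sig_secondary`` and, for every non-reference group ``G``,
    ``t_p_expr_G``, ``log2fc_expr_G``, ``t_p_si_G``, ``log2fc_ni_G``.
    ``gene_table`` carries the gene-level ANOVA and pairwise results.
    """

    table: pd.DataFrame
    gene_table: pd.DataFrame
    thresholds: FdrThresholds
    reference: str
    groups: list[str] = field(default_factory=list)


def normalized_intensity(
    summary: SummaryMatrices, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Elementwise probe-set signal / gene signal (unitless, positive).

    Invariant under array-wide multiplicative rescaling of any sample.
    Probe sets whose gene signal sits at the intensity floor are unreliable;
    a warning is emitted for them.
    """
    gene_of = annotation.loc[summary.probeset_signal.index, "gene_id"]
    gsig = summary.gene_signal.reindex(gene_of).to_numpy(float)
    at_floor = (gsig <= INTENSITY_FLOOR).any(axis=1)
    if at_floor.any():
        warnings.warn(
            f"{int(at_floor.sum())} probe sets have gene signal at the floor; "
            "their normalized intensities are unreliable"
        )
    ni = summary.probeset_signal.to_numpy(float) / np.maximum(gsig, INTENSITY_FLOOR)
    return pd.DataFrame(
        np.maximum(ni, INTENSITY_FLOOR),
        index=summary.probeset_signal.index,
        columns=summary.probeset_signal.columns,
    )


def splicing_index(
    ni: pd.DataFrame, design: pd.Series, pair: tuple[str, str]
) -> pd.Series:
    """SI(A, B): ratio of geometric-mean NI in group A over group B.

    Satisfies ``SI(A, B) * SI(B, A) = 1``.  Replicates are aggregated by
    the geometric mean since all testing operates on the log2 scale.
    """
    a, b = pair
    design = design.reindex(ni.columns)
    cols_a = ni.columns[design == a]
    cols_b = ni.columns[design == b]
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ParameterError(f"empty group in pair {pair}")
    log2 = np.log2(ni.to_numpy(float))
    ga = log2[:, [ni.columns.get_loc(c) for c in cols_a]].mean(axis=1)
    gb = log2[:, [ni.columns.get_loc(c) for c in cols_b]].mean(axis=1)
    return pd.Series(2.0 ** (ga - gb), index=ni.index, name=f"si_{a}_vs_{b}")


def _group_arrays(
    log2: np.ndarray, columns: pd.Index, design: pd.Series
) -> dict[str, np.ndarray]:
    design = design.reindex(columns)
    return {
        g: log2[:, np.flatnonzero((design == g).to_numpy())]
        for g in design.unique()
    }


def anova_oneway(groups: list[np.ndarray]) -> float:
    """Classical one-way fixed-effects F-test p-value (scalar convenience)."""
    stacked = [np.asarray(g, float).reshape(1, -1) for g in groups]
    return float(anova_oneway_rows(stacked)[0])


def anova_oneway_rows(group_blocks: list[np.ndarray]) -> np.ndarray:
    """Row-wise one-way ANOVA p-values across ``group_blocks``.

    Each block is an ``n_rows x n_replicates`` array for one group.  Cells
    with zero within-group variance follow the convention p = 1 when the
    group means are also equal, p = 0 otherwise.
    """
    if len(group_blocks) < 2:
        raise ParameterError("ANOVA needs >=2 groups")
    ns = np.array([b.shape[1] for b in group_blocks])
    N = int(ns.sum())
    k = len(group_blocks)
    if N - k < 1:
        raise ParameterError("ANOVA needs >=2 total residual df")
    means = np.stack([b.mean(axis=1) for b in group_blocks], axis=1)
    grand = sum(b.sum(axis=1) for b in group_blocks) / N
    ssb = (ns[None, :] * (means - grand[:, None]) ** 2).sum(axis=1)
    ssw = sum(((b - m[:, None]) ** 2).sum(axis=1)
              for b, m in zip(group_blocks, means.T))
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (N - k))
        p = stats.f.sf(F, k - 1, N - k)
    zero_w = ssw <= 0
    p = np.where(zero_w & (ssb <= 0), 1.0, p)
    p = np.where(zero_w & (ssb > 0), 0.0, p)
    return p


def bh_threshold(pvalues: np.ndarray, alpha: float = 0.05) -> float:
    """Benjamini-Hochberg step-up cutoff.

    Returns the largest order statistic ``p_(i)`` satisfying
    ``p_(i) <= i * alpha / m`` (0.0 when none does); the rejection set is
    then ``{p <= cutoff}``.
    """
    p = np.asarray(pvalues, float)
    if p.size == 0:
        warnings.warn("bh_threshold: empty p-value list, cutoff 0")
        return 0.0
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    srt = np.sort(p)
    crit = (np.arange(1, m + 1) * alpha) / m
    passing = np.flatnonzero(srt <= crit)
    if passing.size == 0:
        return 0.0
    return float(srt[passing[-1]])


def bh_reject(pvalues: pd.Series, alpha: float = 0.05) -> tuple[pd.Series, float]:
    """Rejection flags plus the cutoff for one p-value family.

    When no order statistic satisfies the step-up condition nothing is
    rejected; otherwise the rejection set is ``{p <= cutoff}`` (which also
    covers the degenerate cutoff 0.0 reached by exactly-zero p-values).
    """
    p = pvalues.to_numpy(float)
    if p.size == 0:
        return pd.Series(False, index=pvalues.index), 0.0
    m = p.size
    srt = np.sort(p)
    crit = (np.arange(1, m + 1) * alpha) / m
    passing = np.flatnonzero(srt <= crit)
    if passing.size == 0:
        return pd.Series(False, index=pvalues.index), 0.0
    cutoff = float(srt[passing[-1]])
    return pvalues <= cutoff, cutoff


def _ttest_rows(
    a: np.ndarray, b: np.ndarray, equal_var: bool = True
) -> np.ndarray:
    """Row-wise two-sample t-test p-values with zero-variance conventions."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if equal_var:
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            df = np.full(a.shape[0], na + nb - 2, dtype=float)
        else:
            se2 = va / na + vb / nb
            t = (ma - mb) / np.sqrt(se2)
            df = se2**2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = (va + vb) <= 0
    p = np.where(zero & (ma == mb), 1.0, p)
    p = np.where(zero & (ma != mb), 0.0, p)
    return p


def pairwise_tests(
    values: pd.DataFrame,
    design: pd.Series,
    reference: str,
    equal_var: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-group t-test p and log2 fold-change vs the reference group.

    ``values`` must already be on the log2 scale.  The fold-change sign is
    positive when the non-reference group is higher.  Groups with a single
    replicate get fold-changes but no t-test (p = NaN, with a warning).
    """
    design = design.reindex(values.columns)
    if reference not in set(design):
        raise ParameterError(f"reference group {reference!r} not in design")
    X = values.to_numpy(float)
    blocks = _group_arrays(X, values.columns, design)
    ref = blocks[reference]
    out: dict[str, pd.DataFrame] = {}
    for g, blk in blocks.items():
        if g == reference:
            continue
        fc = blk.mean(axis=1) - ref.mean(axis=1)
        if blk.shape[1] < 2 or ref.shape[1] < 2:
            warnings.warn(f"group {g!r} or reference has <2 replicates; t-test skipped")
            p = np.full(len(fc), np.nan)
        else:
            p = _ttest_rows(blk, ref, equal_var=equal_var)
        out[g] = pd.DataFrame({"t_p": p, "log2fc": fc}, index=values.index)
    return out


def run_concurrent_analyses(
    summary: SummaryMatrices,
    ni: pd.DataFrame,
    annotation: pd.DataFrame,
    design: pd.Series,
    alpha: float = 0.05,
    reference: str | None = None,
    equal_var: bool = True,
) -> ProbeSetStats:
    """Gene-level, expression and SI analyses with per-family BH thresholds.

    The SI family (and its BH threshold) covers only probe sets of genes the
    gene-level test did not reject; SI ANOVA p-values are still computed for
    the excluded probe sets and drive the ``sig_secondary`` flag used to
    annotate residual splicing inside genes with whole-gene changes.
    """
    design = design.reindex(summary.probeset_signal.columns)
    groups = list(dict.fromkeys(design))
    if reference is None:
        reference = groups[-1]

    log2_ps = np.log2(np.maximum(summary.probeset_signal.to_numpy(float),
                                 INTENSITY_FLOOR))
    log2_ni = np.log2(ni.reindex(summary.probeset_signal.index).to_numpy(float))
    log2_gene = np.log2(np.maximum(summary.gene_signal.to_numpy(float),
                                   INTENSITY_FLOOR))

    cols = summary.probeset_signal.columns
    blocks_ps = _group_arrays(log2_ps, cols, design)
    blocks_ni = _group_arrays(log2_ni, cols, design)
    blocks_gene = _group_arrays(log2_gene, summary.gene_signal.columns, design)
    order = [g for g in groups]

    p_gene = pd.Series(
        anova_oneway_rows([blocks_gene[g] for g in order]),
        index=summary.gene_signal.index, name="anova_p_gene",
    )
    gene_sig, t_gene = bh_reject(p_gene, alpha)

    p_expr = pd.Series(
        anova_oneway_rows([blocks_ps[g] for g in order]),
        index=summary.probeset_signal.index, name="anova_p_expr",
    )
    sig_expr, t_expr = bh_reject(p_expr, alpha)

    p_si = pd.Series(
        anova_oneway_rows([blocks_ni[g] for g in order]),
        index=summary.probeset_signal.index, name="anova_p_si",
    )
    gene_of = annotation.loc[p_si.index, "gene_id"]
    in_si_family = ~gene_sig.reindex(gene_of).fillna(False).to_numpy(bool)
    si_family = p_si[in_si_family]
    sig_si_family, t_si = bh_reject(si_family, alpha)
    sig_si = pd.Series(False, index=p_si.index)
    sig_si.loc[sig_si_family.index] = sig_si_family
    sig_secondary = pd.Series(False, index=p_si.index)
    if sig_si_family.any():
        sig_secondary = (~pd.Series(in_si_family, index=p_si.index)) & (p_si <= t_si)

    table = pd.DataFrame(
        {
            "gene_id": gene_of,
            "kind": annotation.loc[p_si.index, "kind"],
            "anova_p_expr": p_expr,
            "anova_p_si": p_si,
            "sig_expr": sig_expr,
            "sig_si": sig_si,
            "sig_secondary": sig_secondary,
        }
    )
    lps = pd.DataFrame(log2_ps, index=table.index, columns=cols)
    lni = pd.DataFrame(log2_ni, index=table.index, columns=cols)
    for g, res in pairwise_tests(lps, design, reference, equal_var).items():
        table[f"t_p_expr_{g}"] = res["t_p"]
        table[f"log2fc_expr_{g}"] = res["log2fc"]
    for g, res in pairwise_tests(lni, design, reference, equal_var).items():
        table[f"t_p_si_{g}"] = res["t_p"]
        table[f"log2fc_ni_{g}"] = res["log2fc"]

    gene_table = pd.DataFrame({"anova_p_gene": p_gene, "sig_gene": gene_sig})
    lg = pd.DataFrame(log2_gene, index=gene_table.index,
                      columns=summary.gene_signal.columns)
    for g, res in pairwise_tests(lg, design, reference, equal_var).items():
        gene_table[f"t_p_gene_{g}"] = res["t_p"]
        gene_table[f"log2fc_gene_{g}"] = res["log2fc"]

    thresholds = FdrThresholds(alpha=alpha, t_expr=t_expr, t_si=t_si, t_gene=t_gene)
    return ProbeSetStats(
        table=table, gene_table=gene_table, thresholds=thresholds,
        reference=reference, groups=order,
    )
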