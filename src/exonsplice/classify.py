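"""Rule-based classification of per-gene transcript variation patterns.

The original selection of variation patterns was a manual curation step;
this module codifies those judgements into deterministic rules so they can
be applied reproducibly and scored against simulated truth.  Decision
order for a gene that survived filtering:

1. Gene-level ANOVA significant -> ``gene_expression_change``; residual
   splicing inside the gene (secondary events) is annotated from probe sets
   significant in the splicing-index family, which is immune to the
   whole-gene shift.
2. Otherwise significant probe sets are interpreted by their region kind
   and transcript position: a contiguous significant run (>=2 probe sets
   among the testable regions) touching the 3' end indicates an extra short
   transcript sharing the 3' end, i.e. an *alternative start*; a run
   touching the 5' end indicates an *alternative termination*; a pure 5'/3'
   UTR signal is a UTR change; intronic signal is intron or cryptic-exon
   inclusion; isolated internal exonic signal is cassette exon usage;
   anything of mixed kinds or opposing directions is *complex*.

``alt5_splice_site`` is only reachable when the annotation marks a
junction-adjacent sub-exonic region (``subexon``); standard whole-exon
probe sets cannot distinguish a 5' splice-site shift from exon-level
inclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .differential import ProbeSetStats


class ASECategory(str, Enum):
    GENE_EXPRESSION_CHANGE = "gene_expression_change"
    CASSETTE_EXON = "cassette_exon"
    INTRON_OR_CRYPTIC_INCLUSION = "intron_or_cryptic_inclusion"
    ALTERNATIVE_START = "alternative_start"
    ALTERNATIVE_TERMINATION = "alternative_termination"
    UTR5_CHANGE = "utr5_change"
    UTR3_CHANGE = "utr3_change"
    ALT5_SPLICE_SITE = "alt5_splice_site"
    COMPLEX = "complex"


@dataclass
class ASECall:
    """One classified gene: primary category plus supporting evidence."""

    gene_id: str
    category: ASECategory
    source: str  # 'expression' | 'si' | 'gene'
    supporting: list[tuple[str, str]] = field(default_factory=list)  # (probeset, group)
    secondary: list[ASECategory] = field(default_factory=list)


def _direction(row: pd.Series, groups: list[str], reference: str,
               fc_prefix: str) -> str:
    """Group that over-expresses this probe set, from pairwise fold-changes."""
    fcs = {g: row.get(f"{fc_prefix}_{g}", 0.0) for g in groups if g != reference}
    fcs[reference] = 0.0
    return max(fcs, key=lambda g: fcs[g])


def _pattern_category(
    sig_rows: pd.DataFrame,
    ordered_rows: pd.DataFrame,
    groups: list[str],
    reference: str,
    fc_prefix: str,
    min_run: int,
) -> tuple[ASECategory, list[tuple[str, str]]]:
    """Map a set of significant probe sets to an event category."""
    dirs = {
        ps: _direction(row, groups, reference, fc_prefix)
        for ps, row in sig_rows.iterrows()
    }
    supporting = [(ps, d) for ps, d in dirs.items()]
    if len(set(dirs.values())) > 1:
        return ASECategory.COMPLEX, supporting

    pos = {ps: i for i, ps in enumerate(ordered_rows.index)}
    idx = sorted(pos[ps] for ps in sig_rows.index)
    n = len(ordered_rows)
    contiguous = idx[-1] - idx[0] + 1 == len(idx)
    if contiguous and len(idx) >= min_run and len(idx) < n:
        if idx[-1] == n - 1:
            return ASECategory.ALTERNATIVE_START, supporting
        if idx[0] == 0:
            return ASECategory.ALTERNATIVE_TERMINATION, supporting

    kinds = set(sig_rows["kind"])
    if kinds == {"utr5"}:
        return ASECategory.UTR5_CHANGE, supporting
    if kinds == {"utr3"}:
        return ASECategory.UTR3_CHANGE, supporting
    if kinds == {"intron"}:
        return ASECategory.INTRON_OR_CRYPTIC_INCLUSION, supporting
    if kinds == {"exon"}:
        sub = sig_rows.get("subexon")
        if sub is not None and len(sig_rows) and bool(np.all(sub)) and sub.any():
            return ASECategory.ALT5_SPLICE_SITE, supporting
        return ASECategory.CASSETTE_EXON, supporting
    return ASECategory.COMPLEX, supporting


def classify_gene(
    gene_rows: pd.DataFrame,
    annotation: pd.DataFrame,
    stats: ProbeSetStats,
    min_run: int = 2,
) -> ASECall | None:
    """Classify one gene's variation pattern; None when nothing is significant.

    ``gene_rows`` is the gene's slice of the probe-set stats table; rows are
    reordered internally by transcript position, so input order is
    irrelevant.
    """
    if gene_rows.empty:
        return None
    gid = str(gene_rows["gene_id"].iloc[0])
    anno = annotation.reindex(gene_rows.index)
    ordered = gene_rows.assign(
        _order=anno["order"], subexon=anno["subexon"]
    ).sort_values("_order")

    thr = stats.thresholds
    gene_sig = bool(stats.gene_table["sig_gene"].get(gid, False))
    if gene_sig:
        call = ASECall(gene_id=gid,
                       category=ASECategory.GENE_EXPRESSION_CHANGE, source="gene")
        grow = stats.gene_table.loc[gid]
        gdir = _direction(grow, stats.groups, stats.reference, "log2fc_gene")
        call.supporting = [(ps, gdir) for ps in ordered.index]
        sec = ordered[ordered["sig_secondary"].astype(bool)]
        if not sec.empty:
            cat, _sup = _pattern_category(
                sec, ordered, stats.groups, stats.reference, "log2fc_ni", min_run
            )
            call.secondary = [cat]
        return call

    sig = ordered[(ordered["sig_expr"] | ordered["sig_si"]).astype(bool)]
    if sig.empty:
        return None
    source = "expression" if sig["sig_expr"].any() else "si"
    fc_prefix = "log2fc_expr" if source == "expression" else "log2fc_ni"
    cat, supporting = _pattern_category(
        sig, ordered, stats.groups, stats.reference, fc_prefix, min_run
    )
    return ASECall(gene_id=gid, category=cat, source=source, supporting=supporting)


def classify_all(
    stats: ProbeSetStats,
    annotation: pd.DataFrame,
    retained_genes: pd.Index | None = None,
    min_run: int = 2,
) -> list[ASECall]:
    """Classify every retained gene with at least one significant probe set."""
    calls: list[ASECall] = []
    for gid, rows in stats.table.groupby("gene_id", sort=True):
        if retained_genes is not None and gid not in retained_genes:
            continue
        call = classify_gene(rows, annotation, stats, min_run=min_run)
        if call is not None:
            calls.append(call)
    return calls


def category_proportions(calls: list[ASECall]) -> pd.Series:
    """Percentage of classified genes per primary category."""
    if not calls:
        return pd.Series(dtype=float)
    counts = pd.Series([c.category.value for c in calls]).value_counts()
    return counts / counts.sum() * 100.0


def tally_group_specific_introns(
    stats: ProbeSetStats,
    annotation: pd.DataFrame,
    pairwise_alpha: float = 0.05,
) -> pd.Series:
    """Count over-expressed intronic regions per tumor group.

    An ANOVA-significant intronic probe set counts toward a non-reference
    group when its pairwise log2 fold-change versus the reference is
    positive and the pairwise t-test p-value is below ``pairwise_alpha``;
    it counts toward the reference group when every pairwise fold-change is
    negative and at least one pairwise test is significant.  A region may
    count toward more than one group.
    """
    tbl = stats.table
    kinds = annotation.reindex(tbl.index)["kind"]
    introns = tbl[(kinds == "intron").to_numpy()
                  & (tbl["sig_expr"] | tbl["sig_si"]).to_numpy()]
    counts = {g: 0 for g in stats.groups}
    nonref = [g for g in stats.groups if g != stats.reference]
    for _, row in introns.iterrows():
        fcs = {g: row[f"log2fc_expr_{g}"] for g in nonref}
        ps_ = {g: row[f"t_p_expr_{g}"] for g in nonref}
        for g in nonref:
            if fcs[g] > 0 and ps_[g] < pairwise_alpha:
                counts[g] += 1
        if all(fc < 0 for fc in fcs.values()) and any(
            p < pairwise_alpha for p in ps_.values()
        ):
            counts[stats.reference] += 1
    return pd.Series(counts, name="overexpressed_introns")
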