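"""Genome-browser track export and run-level reporting.

Per-probe-set statistics are written as UCSC bedGraph custom tracks — one
fold-change track and one -log10(p) track per pairwise comparison — so
variation patterns can be inspected against transcript annotation in a
genome browser.  Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .differential import ProbeSetStats

P_FLOOR = 1e-300


def write_bedgraph(
    path: str | Path,
    intervals: pd.DataFrame,
    name: str,
    description: str = "",
) -> Path:
    """Write a ``chrom/start/end/value`` frame as a UCSC bedGraph file.

    Rows are emitted sorted by (chrom, start); values are printed with
    enough digits to round-trip through :func:`read_bedgraph`.
    """
    path = Path(path)
    df = intervals.sort_values(["chrom", "start"])
    with open(path, "w") as fh:
        fh.write(
            f'track type=bedGraph name="{name}" description="{description}"\n'
        )
        for _, row in df.iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['start'])}\t{int(row['end'])}\t"
                f"{row['value']:.10g}\n"
            )
    return path


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Parse a bedGraph file written by :func:`write_bedgraph`."""
    df = pd.read_csv(
        path, sep="\t", skiprows=1,
        names=["chrom", "start", "end", "value"],
    )
    return df


def export_tracks(
    stats: ProbeSetStats,
    annotation: pd.DataFrame,
    out_dir: str | Path,
    metric: str = "expr",
) -> list[Path]:
    """One fold-change and one -log10(p) bedGraph per pairwise comparison.

    ``metric`` selects the expression analysis (``expr``) or the
    splicing-index analysis (``si``, fold-changes of normalized intensity).
    Probe sets lacking coordinates are skipped with a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fc_prefix = "log2fc_expr" if metric == "expr" else "log2fc_ni"
    p_prefix = "t_p_expr" if metric == "expr" else "t_p_si"

    anno = annotation.reindex(stats.table.index)
    has_coords = anno[["chrom", "start", "end"]].notna().all(axis=1)
    if (~has_coords).any():
        warnings.warn(
            f"{int((~has_coords).sum())} probe sets lack coordinates; skipped"
        )
    written: list[Path] = []
    for g in stats.groups:
        if g == stats.reference:
            continue
        comp = f"{g}_vs_{stats.reference}"
        base = pd.DataFrame(
            {
                "chrom": anno["chrom"],
                "start": anno["start"],
                "end": anno["end"],
            }
        )[has_coords.to_numpy()]
        fc = base.assign(value=stats.table.loc[base.index, f"{fc_prefix}_{g}"])
        pv = stats.table.loc[base.index, f"{p_prefix}_{g}"].astype(float)
        logp = base.assign(value=-np.log10(np.maximum(pv, P_FLOOR)))
        written.append(
            write_bedgraph(
                out_dir / f"{comp}.{metric}.log2fc.bedGraph",
                fc, name=f"{comp} log2FC ({metric})",
                description=f"log2 fold-change, {comp}",
            )
        )
        written.append(
            write_bedgraph(
                out_dir / f"{comp}.{metric}.neglog10p.bedGraph",
                logp.dropna(subset=["value"]),
                name=f"{comp} -log10(p) ({metric})",
                description=f"pairwise t-test significance, {comp}",
            )
        )
    return written


def report_run(results, seed: int | None = None) -> str:
    """Human-readable run summary with counts, denominators and thresholds.

    ``results`` is an :class:`~exonsplice.analysis.ExonArrayResults`; every
    percentage printed here is reconstructible from the reported
    numerator/denominator pair.
    """
    rep = results.filter_report
    thr = results.stats.thresholds
    lines = [
        "exon-level differential expression / splicing run summary",
        "=" * 58,
        f"seed: {seed if seed is not None else 'n/a'}",
        f"groups: {', '.join(results.stats.groups)} "
        f"(reference {results.stats.reference})",
        f"outlier replicates removed: "
        f"{', '.join(rep.outliers_removed) if rep.outliers_removed else 'none'}",
        "",
        "filtering",
        f"  probe sets in: {rep.n_probesets_in}",
    ]
    for crit, lost in rep.probeset_losses.items():
        lines.append(f"  removed by {crit}: {lost}")
    lines.append(f"  probe sets retained: {rep.n_probesets_retained}")
    lines.append(f"  genes in: {rep.n_genes_in}")
    for crit, lost in rep.gene_losses.items():
        lines.append(f"  removed by {crit}: {lost}")
    lines.append(f"  genes retained: {rep.n_genes_retained}")
    lines += [
        "",
        "BH-FDR thresholds (alpha = %.3g)" % thr.alpha,
        f"  probe-set expression analysis: p <= {thr.t_expr:.3g}",
        f"  splicing-index analysis:       p <= {thr.t_si:.3g}",
        f"  gene-level analysis:           p <= {thr.t_gene:.3g}",
        "",
        "significance counts",
    ]
    tbl = results.stats.table
    n_ps = len(tbl)
    n_expr = int(tbl["sig_expr"].sum())
    n_si = int(tbl["sig_si"].sum())
    n_any = int((tbl["sig_expr"] | tbl["sig_si"]).sum())
    sig_genes = tbl.loc[tbl["sig_expr"] | tbl["sig_si"], "gene_id"].nunique()
    n_genes = results.stats.gene_table.shape[0]
    n_gene_sig = int(results.stats.gene_table["sig_gene"].sum())

    def pct(num: int, den: int) -> str:
        return f"{num}/{den} ({100.0 * num / den:.1f}%)" if den else f"{num}/0"

    lines += [
        f"  probe sets significant (expression): {pct(n_expr, n_ps)}",
        f"  probe sets significant (SI):         {pct(n_si, n_ps)}",
        f"  probe sets significant (either):     {pct(n_any, n_ps)}",
        f"  genes with significant probe sets:   {pct(sig_genes, n_genes)}",
        f"  genes significant at gene level:     {pct(n_gene_sig, n_genes)}",
        "",
        "classification",
    ]
    props = results.category_proportions()
    n_calls = len(results.ase_calls)
    for cat, p in props.items():
        n_cat = int(round(p / 100.0 * n_calls))
        lines.append(f"  {cat}: {pct(n_cat, n_calls)}")
    lines += ["", "group-specific over-expressed intronic regions"]
    for g, c in results.intron_tallies.items():
        lines.append(f"  {g}: {int(c)}")
    return "\n".join(lines) + "\n"
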