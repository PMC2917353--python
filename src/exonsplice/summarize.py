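"""Signal summarization and detection-above-background (DABG) calls.

Probe intensities are quantile normalized across arrays, then summarized
into probe-set signals (exon-level expression) and meta-probe-set signals
(gene-level expression).  The summarizer is Tukey's median polish on log2
intensities, exponentiated back to the linear scale — a standard robust
additive-model fit that plays the same role as the proprietary
probe-summarization models shipped with the array vendor's tooling; the
downstream statistics are agnostic to this choice.

DABG assigns each probe-set signal an empirical upper-tail p-value against
a GC-matched population of background probes; ``p < 0.05`` defines a
"present" call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import AnnotationError, BackgroundPopulation

INTENSITY_FLOOR = 1e-6


@dataclass
class SummaryMatrices:
    """Probe-set and gene signals (linear scale) plus DABG p-values."""

    probeset_signal: pd.DataFrame
    gene_signal: pd.DataFrame
    dabg_p: pd.DataFrame | None = None


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the across-sample mean of order statistics.

    Ties within a column all receive the mean of the reference values at the
    tied positions.  Single-column input is returned unchanged with a
    warning (there is nothing to normalize against).
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: <2 samples, returning input unchanged")
        return matrix.copy()
    X = matrix.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        target = ref.copy()
        sorted_col = col[order]
        # average reference values over runs of tied input values
        i = 0
        n = len(col)
        while i < n:
            k = i + 1
            while k < n and sorted_col[k] == sorted_col[i]:
                k += 1
            if k - i > 1:
                target[i:k] = target[i:k].mean()
            i = k
        out[order, j] = target
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish(
    X: np.ndarray, max_iter: int = 20, tol: float = 1e-8
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish of a 2-D table.

    Returns ``(overall, row_effects, col_effects, residuals)`` for the
    additive decomposition ``X = overall + row + col + residual``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("median_polish expects a 2-D array")
    resid = X.copy()
    overall = 0.0
    row = np.zeros(X.shape[0])
    col = np.zeros(X.shape[1])
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        cmed = np.median(row)
        overall += cmed
        row -= cmed
        ccol = np.median(resid, axis=0)
        resid -= ccol[None, :]
        col += ccol
        rmed2 = np.median(col)
        overall += rmed2
        col -= rmed2
        if np.abs(rmed).max(initial=0.0) < tol and np.abs(ccol).max(initial=0.0) < tol:
            break
    return overall, row, col, resid


def _polish_signal(log2_block: np.ndarray) -> np.ndarray:
    """Per-sample summary of one probe (or probe-set) block on the log2 scale."""
    overall, _row, colfx, _res = median_polish(log2_block)
    return overall + colfx


def summarize_probesets(
    probe_matrix: pd.DataFrame, probe_to_probeset: pd.Series
) -> pd.DataFrame:
    """Median-polish probe-level intensities into probe-set signals."""
    missing = probe_matrix.index.difference(probe_to_probeset.index)
    if len(missing):
        raise AnnotationError(f"probes without a probe set: {list(missing[:5])}")
    log2 = np.log2(np.maximum(probe_matrix.to_numpy(float), INTENSITY_FLOOR))
    groups = probe_to_probeset.reindex(probe_matrix.index)
    out, idx = [], []
    for ps, pos in probe_matrix.groupby(groups, sort=False).indices.items():
        out.append(2.0 ** _polish_signal(log2[pos]))
        idx.append(ps)
    return pd.DataFrame(
        np.asarray(out), index=pd.Index(idx, name="probeset_id"),
        columns=probe_matrix.columns,
    )


def summarize_genes(
    probeset_signal: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Meta-probe-set (gene) signal from all probe sets belonging to the gene."""
    missing = probeset_signal.index.difference(annotation.index)
    if len(missing):
        raise AnnotationError(f"probe sets without annotation: {list(missing[:5])}")
    gene_of = annotation.loc[probeset_signal.index, "gene_id"]
    log2 = np.log2(np.maximum(probeset_signal.to_numpy(float), INTENSITY_FLOOR))
    out, idx = [], []
    for gid, pos in probeset_signal.groupby(gene_of, sort=False).indices.items():
        out.append(2.0 ** _polish_signal(log2[pos]))
        idx.append(gid)
    return pd.DataFrame(
        np.asarray(out), index=pd.Index(idx, name="gene_id"),
        columns=probeset_signal.columns,
    )


def summarize(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    probe_to_probeset: pd.Series | None = None,
    normalize: bool | None = None,
) -> SummaryMatrices:
    """Quantile normalize and summarize to probe-set and gene signals.

    When ``probe_to_probeset`` is None the input is taken to be probe-set
    level already and passed through to the probe-set signal; gene signals
    are then summarized from it.

    Quantile normalization belongs to probe-*level* fluorescence
    preprocessing, where the row count is large enough that forcing a
    common distribution leaves individual signals essentially untouched.
    By default (``normalize=None``) it is therefore applied only to
    probe-level input; on a pass-through probe-set matrix with a few
    thousand rows it would compress the distribution's extreme tail and
    bias exactly the strongly-changing probe sets of interest.  Set
    ``normalize`` explicitly to override either way.
    """
    if normalize is None:
        normalize = probe_to_probeset is not None
    work = quantile_normalize(matrix) if normalize else matrix
    if probe_to_probeset is not None:
        probeset_signal = summarize_probesets(work, probe_to_probeset)
    else:
        probeset_signal = work.copy()
    gene_signal = summarize_genes(probeset_signal, annotation)
    return SummaryMatrices(probeset_signal=probeset_signal, gene_signal=gene_signal)


def empirical_upper_p(signal: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Add-one empirical upper-tail probability of ``signal`` under ``background``.

    ``p = (#background >= signal + 1) / (B + 1)``, which is in ``(0, 1]``.
    """
    bg = np.sort(np.asarray(background, float))
    B = len(bg)
    n_ge = B - np.searchsorted(bg, np.asarray(signal, float), side="left")
    return (n_ge + 1.0) / (B + 1.0)


def fisher_combine(pvals: np.ndarray) -> float:
    """Fisher's method across independent p-values."""
    p = np.asarray(pvals, float)
    stat = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(stat, df=2 * len(p)))


def dabg(
    signal: pd.DataFrame,
    background: BackgroundPopulation,
    gc_bins: pd.Series | None = None,
    probe_to_probeset: pd.Series | None = None,
) -> pd.DataFrame:
    """DABG p-values: one per probe set per sample.

    ``gc_bins`` maps each signal row to its GC bin for matched-bin lookup;
    an empty bin falls back to the pooled background with a warning.  When
    ``probe_to_probeset`` is given the rows of ``signal`` are probes, and
    per-probe p-values are combined across each probe set by Fisher's
    method; otherwise each row is scored directly.
    """
    X = signal.to_numpy(float)
    P = np.empty_like(X)
    if gc_bins is None:
        bins = np.zeros(len(signal), dtype=int)
        pooled_only = True
    else:
        bins = gc_bins.reindex(signal.index).fillna(-1).to_numpy(int)
        pooled_only = False
    for b in np.unique(bins):
        rows = bins == b
        bg = background.values if pooled_only else background.bin_values(int(b))
        if bg.size == 0:
            warnings.warn(f"dabg: empty background bin {b}, using pooled background")
            bg = background.values
        for j in range(X.shape[1]):
            P[rows, j] = empirical_upper_p(X[rows, j], bg)
    pdf = pd.DataFrame(P, index=signal.index, columns=signal.columns)
    if probe_to_probeset is None:
        return pdf
    out, idx = [], []
    for ps, pos in pdf.groupby(
        probe_to_probeset.reindex(pdf.index), sort=False
    ).indices.items():
        block = P[pos]
        out.append([fisher_combine(block[:, j]) for j in range(block.shape[1])])
        idx.append(ps)
    return pd.DataFrame(
        np.asarray(out), index=pd.Index(idx, name="probeset_id"),
        columns=signal.columns,
    )


def summarize_study(study, normalize: bool | None = None) -> SummaryMatrices:
    """Full summarization of an :class:`~exonsplice.models.ExpressionStudy`."""
    sm = summarize(study.matrix, study.annotation, normalize=normalize)
    sm.dabg_p = dabg(
        sm.probeset_signal, study.background,
        gc_bins=study.annotation["gc_bin"],
    )
    return sm
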