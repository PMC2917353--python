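"""Scoring fitted results against simulated truth.

Used by the test suite and the acceptance script to measure how well the
pipeline recovers injected perturbations: probe-set-level sensitivity and
false-discovery proportion, and the classifier's category accuracy on
single-event genes.
"""

from __future__ import annotations

from dataclasses import dataclass

from .analysis import ExonArrayResults
from .simulate import SimulationTruth


@dataclass
class RecoveryMetrics:
    sensitivity: float
    false_discovery_proportion: float
    classifier_accuracy: float
    n_injected: int
    n_detected: int
    n_flagged: int
    n_false: int
    n_truth_genes: int
    n_correct_genes: int


def score_recovery(
    results: ExonArrayResults, truth: SimulationTruth
) -> RecoveryMetrics:
    """Sensitivity / FDP over probe-set calls and classifier accuracy.

    A probe set counts as *detected* when flagged significant in the
    expression analysis, the SI analysis, or as a secondary event.  A
    flagged probe set is a *false discovery* when neither it nor its gene
    carries any injected effect.  Classifier accuracy is the fraction of
    truth-labelled (single-event) genes whose primary category matches;
    genes the pipeline filtered out or left uncalled count as misses.
    """
    tbl = results.stats.table
    flagged = tbl["sig_expr"] | tbl["sig_si"] | tbl["sig_secondary"]

    injected = [ps for ps in truth.ase if ps in tbl.index]
    n_detected = int(flagged.reindex(injected).fillna(False).sum())
    # probe sets only reachable if they survive filtering; count the rest
    # as misses against the full injected denominator
    n_injected = len(truth.ase)

    effect_genes = set(truth.gene_effects)
    false_mask = flagged & ~tbl.index.isin(truth.ase) & ~tbl["gene_id"].isin(
        effect_genes
    )
    n_flagged = int(flagged.sum())
    n_false = int(false_mask.sum())
    fdp = n_false / n_flagged if n_flagged else 0.0

    calls = {c.gene_id: c.category.value for c in results.ase_calls}
    n_truth_genes = len(truth.gene_category)
    n_correct = sum(
        1 for gid, cat in truth.gene_category.items() if calls.get(gid) == cat
    )
    return RecoveryMetrics(
        sensitivity=n_detected / n_injected if n_injected else 1.0,
        false_discovery_proportion=fdp,
        classifier_accuracy=n_correct / n_truth_genes if n_truth_genes else 1.0,
        n_injected=n_injected,
        n_detected=n_detected,
        n_flagged=n_flagged,
        n_false=n_false,
        n_truth_genes=n_truth_genes,
        n_correct_genes=n_correct,
    )
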