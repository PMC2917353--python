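"""Synthetic exon-array studies with known injected truth.

The generator emulates a three-group tumor profiling design (two weakly
metastatic lines and one highly metastatic line, 4/5/4 biological
replicates) on a gene-annotated probe-set matrix: each gene is decomposed
into UTR, exon and intron probe sets carrying core/noncore annotation tiers
and cross-hybridization flags.  Known whole-gene expression shifts and
alternative-splicing events (cassette exons, intron/cryptic inclusions,
alternative starts/terminations, UTR changes) are injected on the log2
scale so that every downstream stage of the pipeline can be scored against
the truth.

Intensity model: ``intensity = 2 ** (baseline + gene_effect + ase_effect +
noise)`` with i.i.d. Gaussian noise on the log2 scale.  Regions that are not
part of any expressed transcript (introns without injected inclusion) have
baselines drawn near the GC-matched background distribution, so their
detection-above-background present rate stays at the nominal false-positive
level.  All randomness flows from one integer seed through counter-based
substreams (one per gene), making output bit-identical for identical seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    BackgroundPopulation,
    ConsistencyError,
    ExpressionStudy,
    GeneModel,
    ParameterError,
    Region,
)

DEFAULT_GROUPS = ("168FARN", "4T07", "4T1")
DEFAULT_REPLICATES = (4, 5, 4)

# log2-scale intensity landscape
EXPRESSED_LOG2_MEAN = 6.5
EXPRESSED_LOG2_SD = 0.5
BG_BIN_LOG2_MEANS = (4.2, 4.4, 4.6, 4.8)   # one mean per GC bin
BG_LOG2_SD = 0.4
INTRON_BASELINE_SD = 0.3
N_GC_BINS = 4

# substream domains (spawn-key prefixes) so no two draws share a stream
_D_STRUCTURE, _D_TIER, _D_TRUTH, _D_NOISE, _D_OUTLIER, _D_BACKGROUND = range(6)

ASE_KINDS = (
    "cassette_exon",
    "intron_or_cryptic_inclusion",
    "alternative_start",
    "alternative_termination",
    "utr5_change",
    "utr3_change",
)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


@dataclass(frozen=True)
class AseInjection:
    """One injected splicing perturbation on one probe set."""

    kind: str
    groups: tuple[str, ...]
    effect: float  # log2 inclusion effect in the affected group(s)


@dataclass
class SimulationTruth:
    """Everything the pipeline is supposed to recover.

    ``gene_effects`` holds whole-gene log2 shifts per group; ``ase`` maps
    probe-set id -> injected event; ``gene_category`` is the single primary
    event label per perturbed gene (the classifier's target);
    ``baseline`` is the per-probe-set baseline log2 intensity.
    """

    seed: int
    noise_sd: float
    baseline: dict[str, float]
    gene_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    ase: dict[str, AseInjection] = field(default_factory=dict)
    gene_category: dict[str, str] = field(default_factory=dict)

    def ase_probesets(self) -> list[str]:
        return list(self.ase)


def simulate_gene_models(
    n_genes: int,
    exons_per_gene: tuple[int, int] = (4, 8),
    noncore_fraction: float = 0.562,
    seed: int = 0,
    xhyb_flagged_fraction: float = 0.05,
) -> dict[str, GeneModel]:
    """Generate ``n_genes`` gene models with alternating exon/intron layout.

    Each gene is ``utr5, E1, I1, E2, ..., En, utr3`` in transcript order.
    Introns are always noncore; additional noncore status is spread over the
    remaining regions so the overall noncore probe-set fraction approaches
    ``noncore_fraction`` (it cannot go below the intron share).
    """
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    lo, hi = int(exons_per_gene[0]), int(exons_per_gene[1])
    if lo < 1 or lo > hi:
        raise ParameterError(f"invalid exons_per_gene range {exons_per_gene}")
    if not 0.0 <= noncore_fraction <= 1.0:
        raise ParameterError("noncore_fraction must be in [0, 1]")

    n_exons = np.array(
        [_rng(seed, _D_STRUCTURE, i).integers(lo, hi + 1) for i in range(n_genes)]
    )
    n_regions = 2 * n_exons + 1
    n_introns = n_exons - 1
    total, introns = int(n_regions.sum()), int(n_introns.sum())
    other = total - introns
    p_noncore = float(np.clip((noncore_fraction * total - introns) / other, 0.0, 1.0))

    chrom_cursor: dict[str, int] = {}
    models: dict[str, GeneModel] = {}
    for i in range(n_genes):
        rng = _rng(seed, _D_STRUCTURE, i)
        ne = int(rng.integers(lo, hi + 1))  # same first draw as above
        strand = "+" if rng.random() < 0.5 else "-"
        chrom = f"chr{1 + i % 19}"

        kinds = ["utr5"]
        for j in range(ne):
            kinds.append("exon")
            if j < ne - 1:
                kinds.append("intron")
        kinds.append("utr3")
        lengths = []
        for k in kinds:
            if k == "exon":
                lengths.append(int(rng.integers(50, 301)))
            elif k == "intron":
                lengths.append(int(rng.integers(200, 2001)))
            else:
                lengths.append(int(rng.integers(100, 501)))
        gc_bins = rng.integers(0, N_GC_BINS, size=len(kinds))

        tier_rng = _rng(seed, _D_TIER, i)
        tiers = []
        for k in kinds:
            if k == "intron":
                tiers.append("noncore")
            else:
                tiers.append("noncore" if tier_rng.random() < p_noncore else "core")
        xhyb = np.where(
            tier_rng.random(len(kinds)) < xhyb_flagged_fraction,
            tier_rng.integers(2, 4, size=len(kinds)),
            1,
        )

        tx_start = chrom_cursor.get(chrom, 10_000)
        span = int(np.sum(lengths))
        chrom_cursor[chrom] = tx_start + span + 10_000
        # genomic layout left->right equals transcript order on '+', reversed on '-'
        order_g = range(len(kinds)) if strand == "+" else range(len(kinds) - 1, -1, -1)
        starts = {}
        pos = tx_start
        for idx in order_g:
            starts[idx] = pos
            pos += lengths[idx]

        gene_id = f"g{i:05d}"
        regions = [
            Region(
                probeset_id=f"{gene_id}_ps{j:02d}",
                kind=kinds[j],
                tier=tiers[j],
                xhyb=int(xhyb[j]),
                start=starts[j],
                end=starts[j] + lengths[j],
                gc_bin=int(gc_bins[j]),
            )
            for j in range(len(kinds))
        ]
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            tx_start=tx_start,
            tx_end=tx_start + span,
            regions=regions,
        )
    return models


def _exonic_positions(gm: GeneModel) -> list[int]:
    return [i for i, r in enumerate(gm.regions) if r.kind == "exon"]


def make_truth(
    models: dict[str, GeneModel],
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    n_per_category: int | dict[str, int] = 20,
    effect: float = 1.5,
    gene_effect: float = 1.5,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> SimulationTruth:
    """Draw baselines and inject one event per selected gene.

    ``n_per_category`` genes receive each ASE kind (plus
    ``gene_expression_change`` whole-gene shifts); remaining genes are null.
    Every event over-expresses its region(s) by ``effect`` log2 units in one
    randomly chosen group.
    """
    if isinstance(n_per_category, int):
        wanted = {k: n_per_category for k in ASE_KINDS + ("gene_expression_change",)}
    else:
        wanted = dict(n_per_category)
    rng = _rng(seed, _D_TRUTH)

    truth = SimulationTruth(seed=seed, noise_sd=float(noise_sd), baseline={})
    for gm in models.values():
        for r in gm.regions:
            if r.kind == "intron":
                mu = BG_BIN_LOG2_MEANS[r.gc_bin % N_GC_BINS]
                truth.baseline[r.probeset_id] = float(
                    rng.normal(mu, INTRON_BASELINE_SD)
                )
            else:
                truth.baseline[r.probeset_id] = float(
                    rng.normal(EXPRESSED_LOG2_MEAN, EXPRESSED_LOG2_SD)
                )

    gene_ids = list(models)
    rng.shuffle(gene_ids)
    pool = iter(gene_ids)

    for kind, n_want in wanted.items():
        assigned = 0
        while assigned < n_want:
            try:
                gid = next(pool)
            except StopIteration as exc:
                raise ParameterError(
                    "not enough genes to host the requested events"
                ) from exc
            gm = models[gid]
            group = str(rng.choice(list(groups)))
            if kind == "gene_expression_change":
                truth.gene_effects[gid] = {group: float(gene_effect)}
            else:
                targets = _event_probesets(gm, kind, rng)
                if targets is None:
                    continue
                for ps in targets:
                    truth.ase[ps] = AseInjection(kind, (group,), float(effect))
            truth.gene_category[gid] = kind
            assigned += 1
    return truth


def _event_probesets(
    gm: GeneModel, kind: str, rng: np.random.Generator
) -> list[str] | None:
    """Probe sets perturbed by one event, chosen on the gene's layout.

    An alternative start adds a short transcript sharing the gene's 3' end,
    so the over-expressed block is the 3'-terminal run (last exons + 3'
    UTR); an alternative termination is the mirror image.  Events target
    only uniquely-hybridizing regions (xhyb == 1) — a perturbation on a
    cross-hybridizing probe set is unobservable by construction because the
    filtering cascade discards such regions.  Returns None when the gene
    has no suitable layout.
    """
    regions = gm.regions
    exonic = _exonic_positions(gm)

    def unique(positions):
        return [i for i in positions if regions[i].xhyb == 1]

    if kind == "cassette_exon":
        candidates = unique(exonic[1:-1])
        if not candidates:
            return None
        pos = int(rng.choice(candidates))
        return [regions[pos].probeset_id]
    if kind == "intron_or_cryptic_inclusion":
        introns = unique(i for i, r in enumerate(regions) if r.kind == "intron")
        if not introns:
            return None
        pos = int(rng.choice(introns))
        return [regions[pos].probeset_id]
    if kind == "alternative_start":
        picks = exonic[-2:] + [len(regions) - 1]  # last two exons + 3' UTR
        if len(exonic) < 4 or len(unique(picks)) < len(picks):
            return None
        return [regions[i].probeset_id for i in picks]
    if kind == "alternative_termination":
        picks = [0] + exonic[:2]  # 5' UTR + first two exons
        if len(exonic) < 4 or len(unique(picks)) < len(picks):
            return None
        return [regions[i].probeset_id for i in picks]
    if kind == "utr5_change":
        return [regions[0].probeset_id] if regions[0].xhyb == 1 else None
    if kind == "utr3_change":
        return [regions[-1].probeset_id] if regions[-1].xhyb == 1 else None
    raise ParameterError(f"unknown event kind {kind!r}")


def simulate_background(seed: int, n_per_bin: int = 500) -> BackgroundPopulation:
    """Log-normal background-probe population in ``N_GC_BINS`` GC bins."""
    rng = _rng(seed, _D_BACKGROUND)
    values, bins = [], []
    for b, mu in enumerate(BG_BIN_LOG2_MEANS):
        values.append(2.0 ** rng.normal(mu, BG_LOG2_SD, size=n_per_bin))
        bins.append(np.full(n_per_bin, b))
    return BackgroundPopulation(np.concatenate(values), np.concatenate(bins))


def _build_design(
    groups: tuple[str, ...], replicates: tuple[int, ...]
) -> pd.Series:
    if len(groups) != len(replicates):
        raise ParameterError("groups and replicates must have the same length")
    names, labels = [], []
    for g, n in zip(groups, replicates):
        for i in range(1, n + 1):
            names.append(f"{g}_{i}")
            labels.append(g)
    return pd.Series(labels, index=pd.Index(names, name="sample"), name="group")


def simulate_study(
    models: dict[str, GeneModel],
    truth: SimulationTruth,
    replicates: tuple[int, ...] = DEFAULT_REPLICATES,
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    outlier_spec: tuple[str, float] | None = None,
) -> ExpressionStudy:
    """Materialize the intensity matrix implied by ``truth``.

    ``outlier_spec = (group, shift)`` degrades the last replicate of
    ``group`` with an uncorrelated per-probe-set log2 perturbation of SD
    ``shift``, emulating a biological replicate that fails to cluster with
    its group.  (A uniform additive shift would be removed by quantile
    normalization and could not reproduce that behaviour.)
    """
    known = {r.probeset_id for gm in models.values() for r in gm.regions}
    for ps in list(truth.ase) + list(truth.baseline):
        if ps not in known:
            raise ConsistencyError(f"truth references unknown probe set {ps!r}")
    for gid in truth.gene_effects:
        if gid not in models:
            raise ConsistencyError(f"truth references unknown gene {gid!r}")

    design = _build_design(groups, replicates)
    samples = list(design.index)
    group_of = design.to_dict()

    rows, index = [], []
    for gi, (gid, gm) in enumerate(models.items()):
        rng = _rng(truth.seed, _D_NOISE, gi)
        eff = truth.gene_effects.get(gid, {})
        for r in gm.regions:
            base = truth.baseline[r.probeset_id]
            inj = truth.ase.get(r.probeset_id)
            log2 = np.empty(len(samples))
            for j, s in enumerate(samples):
                g = group_of[s]
                v = base + eff.get(g, 0.0)
                if inj is not None and g in inj.groups:
                    v += inj.effect
                log2[j] = v
            log2 = log2 + rng.normal(0.0, truth.noise_sd, size=len(samples))
            rows.append(log2)
            index.append(r.probeset_id)

    matrix = pd.DataFrame(
        2.0 ** np.asarray(rows), index=pd.Index(index, name="probeset_id"),
        columns=samples,
    )
    if outlier_spec is not None:
        grp, shift = outlier_spec
        members = [s for s in samples if group_of[s] == grp]
        if not members:
            raise ParameterError(f"outlier group {grp!r} not in design")
        victim = members[-1]
        orng = _rng(truth.seed, _D_OUTLIER)
        matrix[victim] = matrix[victim].values * 2.0 ** orng.normal(
            0.0, float(shift), size=len(matrix)
        )
    return ExpressionStudy(
        matrix=matrix,
        design=design,
        background=simulate_background(truth.seed),
        models=models,
    )


def simulate_dataset(
    n_genes: int = 500,
    seed: int = 0,
    groups: tuple[str, ...] = DEFAULT_GROUPS,
    replicates: tuple[int, ...] = DEFAULT_REPLICATES,
    n_per_category: int | dict[str, int] | None = None,
    effect: float = 1.5,
    gene_effect: float = 1.5,
    noise_sd: float = 0.25,
    noncore_fraction: float = 0.562,
    outlier_spec: tuple[str, float] | None = ("4T07", 4.0),
) -> tuple[ExpressionStudy, SimulationTruth]:
    """One-call study generator mirroring the emulated experimental design."""
    if n_per_category is None:
        n_per_category = max(1, n_genes // 25)
    models = simulate_gene_models(
        n_genes, noncore_fraction=noncore_fraction, seed=seed
    )
    truth = make_truth(
        models, groups=groups, n_per_category=n_per_category, effect=effect,
        gene_effect=gene_effect, noise_sd=noise_sd, seed=seed,
    )
    study = simulate_study(
        models, truth, replicates=replicates, groups=groups,
        outlier_spec=outlier_spec,
    )
    return study, truth
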