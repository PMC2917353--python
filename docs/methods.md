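# Methods

This note documents the models, rules and numerical choices behind
`exonsplice`, in the order the pipeline applies them, together with what
the synthetic-data generator does and does not emulate.

## Signal model and summarization

Probe intensities are modelled as multiplicative (log-additive)
fluorescence: all statistics operate on log2 intensities and are
exponentiated back only for reporting. Summarization into probe-set and
meta-probe-set (gene) signals uses **Tukey median polish** of the log2
probe (or probe-set) × sample table; the per-sample summary is
`overall + column effect`. Median polish is the standard robust additive
fit used by RMA-style summarizers: it is scale-equivariant, resistant to a
minority of aberrant rows, and — important for splicing work — a gene
signal built from the *median* over probe sets barely moves when one or
two regions change, so the gene-level normalized intensity of an
alternative region reflects the splicing change rather than leaking it
into the denominator. The gene summary deliberately uses **all** of a
gene's probe sets (including intronic ones near background); with intronic
regions never a majority of a gene's regions, the median stays anchored on
the expressed part.

**Quantile normalization** forces every array onto the across-sample mean
of order statistics (ties share the mean of their target values; it is
idempotent). It belongs at the probe level, where the row count is large
enough that the forced common distribution leaves individual signals
essentially untouched. The pipeline therefore applies it only to
probe-level input; a pass-through probe-set matrix (the simulator's
output, a few thousand rows) is *not* re-normalized, because at that scale
the transform visibly compresses the distribution's upper tail — exactly
where strongly changing probe sets live. `normalize=` overrides either
way.

**DABG** (detection above background): each probe-set signal gets an
add-one empirical upper-tail p-value against the background-probe
population of its GC bin, `p = (#bg ≥ x + 1)/(B + 1)` (never 0, never
> 1); probe-level p-values are combined per probe set by Fisher's method.
An empty GC bin falls back to the pooled background with a warning.
Intensities are floored at 1e-6 before any log.

## Filtering cascade

Applied in order, though the criteria are conjunctive so the final set is
order-independent:

1. **Outlier replicates** — samples are projected onto the first two
   principal components of log2 gene signals; a sample whose distance to
   its own group centroid exceeds `3 ×` the pooled within-group distance
   SD is removed and the data re-summarized. The SD is computed
   leave-one-out so one gross outlier cannot mask itself by inflating the
   pooled spread. Groups with <2 replicates are excluded from flagging.
2. **Probe sets** — kept iff (i) Present (DABG p < 0.05) in ≥50% of the
   replicates of ≥1 group (ties at exactly 50% count — 2 of 4 replicates
   pass); (ii) cross-hybridization flag equal to 1; (iii) mean NI < 5;
   (iv) mean NI > 0.20. The NI bounds use the across-sample mean per
   probe set; the mean was chosen for stability where a per-sample rule
   would be noise-dominated with 4–5 replicates.
3. **Genes** — kept iff ≥50% of the gene's *core exonic* probe sets are
   Present in ≥2 groups, and the mean gene signal exceeds 30. A gene with
   zero core exonic probe sets fails and is logged.

## Testing

One-way fixed-effects ANOVA is computed row-wise from explicit sums of
squares (cross-checked against `scipy.stats.f_oneway` in the tests) with
the conventions p = 1 for zero between- and within-group variance and
p = 0 for distinct means with zero within-group variance. Pairwise tests
default to the pooled-variance two-sample t-test (Welch available via
`equal_var=False`); fold-changes are differences of group mean log2
values, positive when the non-reference group is higher.

BH-FDR: each family (gene ANOVA, probe-set expression ANOVA, SI ANOVA)
gets its own step-up cutoff — the largest `p(i) ≤ i·α/m` — and the
rejection set `{p ≤ cutoff}`. The **SI family** contains only probe sets
of genes the gene-level test did not reject: dividing by a changing gene
signal does not isolate splicing, and this restriction also mirrors how a
whole-gene change should be reported at the gene level, not as hundreds of
probe-set hits. SI ANOVA p-values are still computed for the excluded
probe sets; inside gene-significant genes, `p_si ≤ t_si` defines
*secondary* splicing events on top of the expression change, which keeps
secondary-event detection immune to the whole-gene shift without
re-running BH on a different family.

Group-level SI aggregates replicates by the geometric mean, so
`log2 SI = Δ mean log2 NI` and the reported `log2fc_ni` equals the log of
the splicing index exactly; `SI(A,B)·SI(B,A) = 1` by construction.

## Event classification

The original interpretation of variation patterns was a curation step;
the classifier codifies it into deterministic rules (input order never
matters — regions are taken in transcript 5′→3′ order):

1. Gene-level significant → `gene_expression_change`, with secondary
   categories from SI-significant probe sets as above.
2. Otherwise, significant probe sets (either family) are interpreted
   jointly. Opposing over-expression directions → `complex`. A contiguous
   run of ≥2 significant probe sets *among the retained regions* touching
   the 3′ end → `alternative_start` (an extra short transcript sharing
   the gene's 3′ end, over-expressed where it is active); touching the 5′
   end → `alternative_termination` (mirror image). Pure UTR signal →
   `utr5_change`/`utr3_change`; pure intronic signal →
   `intron_or_cryptic_inclusion`; internal exonic signal →
   `cassette_exon`; mixed kinds → `complex`. `alt5_splice_site` is
   callable only when the annotation marks junction-adjacent sub-exonic
   regions; ordinary whole-exon probe sets cannot resolve it.

The ≥2 run length is a noise guard: a single significant terminal region
is far more often a UTR change or a false positive than a genuine
alternative start; it is configurable (`min_run`).

Group-specific intron tallies: an ANOVA-significant intronic probe set
counts toward a non-reference group when its pairwise log2 fold-change
versus the reference is positive with pairwise p < 0.05, and toward the
reference group when every pairwise fold-change is negative with at least
one pairwise test significant. A region may count toward more than one
group (e.g. both weakly metastatic lines).

## Cross-study overlap

Dice `2|A∩B|/(|A|+|B|)`, its maximum for the given sizes
`2·min(|A|,|B|)/(|A|+|B|)`, and percent overlap observed/max × 100.
Enrichment uses the Pearson chi-square (no continuity correction) on the
2×2 membership table over an **explicit** universe — no default universe
is assumed because the choice (all annotated genes vs expressed genes)
changes the test materially. "One-tailed" is defined as the directional
half-p of the 1-df chi-square: `p/2` when the observed intersection
exceeds its expectation, `1 − p/2` below it, 0.5 at it.

## Synthetic data

The generator emulates a three-group tumor study (168FARN/4T07/4T1 labels,
4/5/4 replicates, one degraded replicate) on ~500 genes of 4–8 exons laid
out `utr5, E1, I1, …, En, utr3` with 0-based half-open coordinates on
both strands. Defaults, chosen to mirror the emulated study where stated
and otherwise set once at values typical for this array class:

| parameter | default | meaning |
|---|---|---|
| noncore fraction | 0.562 | share of probe sets with EST/predicted-only support (introns always noncore) |
| xhyb-flagged fraction | 0.05 | probe sets with cross-hybridization flag 2–3 |
| expressed baseline | log2 ~ N(6.5, 0.5) | exon/UTR regions |
| intron baseline | log2 ~ N(GC-bin mean, 0.3) | matches the background population |
| background | log2 ~ N(4.2…4.8, 0.4), 4 GC bins | 500 probes per bin |
| effect size | 1.5 log2 | injected ASE and whole-gene effects |
| noise | log2 SD 0.25 | i.i.d. Gaussian, per observation |
| outlier | SD 4 log2 perturbation | uncorrelated per-probe-set, last 4T07 replicate |

Intensities are `2^(baseline + gene effect + ASE effect + noise)`. Events
target only uniquely-hybridizing regions — a perturbation on an
xhyb-flagged probe set is unobservable by construction since the filter
discards it. The outlier is an uncorrelated per-probe-set perturbation
rather than a uniform shift: a replicate that "doesn't cluster" has lost
its correlation structure, and a uniform shift would disappear under any
across-array normalization. All randomness flows from one integer seed
through counter-based substreams (one per gene), so identical seeds give
bit-identical matrices.

What the simulator does **not** emulate: probe-sequence effects and
GC-dependent signal bias within expressed regions, batch/dye effects,
correlated noise between neighbouring probe sets, partial isoform mixtures
(events are all-or-nothing log2 shifts), and the long-tailed abundance
distribution of real transcriptomes. Passing recovery tests therefore
demonstrates that the statistics and rules behave as designed under the
stated noise model — not that real-array sensitivity equals the simulated
~99%.

## Problem sizes and determinism

The test suite and the acceptance script run the full pipeline on 200- and
500-gene studies (~2.6k and ~6.5k probe sets, 13 samples) and the null
calibration on 100 replicates of 1000 probe sets; these sizes give stable
metrics (sensitivity, FDP and accuracy vary by ~±0.03 across seeds) while
keeping a full run in seconds. Empirical FDR under the global null is the
across-replicate mean false-discovery proportion, since a single all-null
run has an almost-binary FDP.

## Known limitations

- The summarizer is a documented stand-in for the vendor's probe
  logarithmic intensity error models; absolute signal values differ even
  though downstream statistics are agnostic to the choice.
- The classifier resolves only patterns the array geometry can express;
  multi-event genes beyond one secondary annotation collapse to
  `complex`, matching how ambiguous patterns were treated upstream.
- The reported one-tailed chi-square for cross-study overlap depends
  strongly on the chosen universe; the package refuses to choose one
  silently.
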