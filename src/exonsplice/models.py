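"""Core data containers: gene models, probe-set regions and expression studies.

An exon array interrogates each gene through many short *probe sets*, one per
exonic, intronic or UTR region.  The *meta-probe set* is the aggregation of
all probe sets belonging to one gene and represents whole-transcript
expression.  These containers carry the annotation hierarchy (gene -> ordered
regions) plus the probe-set x sample intensity matrix and the background-probe
population used for detection-above-background calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_KINDS = ("exon", "intron", "utr5", "utr3")
TIERS = ("core", "noncore")

ANNOTATION_COLUMNS = [
    "gene_id", "kind", "tier", "xhyb", "gc_bin",
    "chrom", "start", "end", "strand", "order", "subexon",
]


class ParameterError(ValueError):
    """Invalid user-supplied parameter."""


class AnnotationError(ValueError):
    """Inconsistent gene/probe-set annotation."""


class ConsistencyError(ValueError):
    """Cross-references between inputs do not line up."""


@dataclass(frozen=True)
class Region:
    """One probe-set target region within a gene.

    ``xhyb`` is the cross-hybridization potential flag (1 = unique in the
    genome); ``tier`` distinguishes curated (core) from EST/predicted
    (noncore) annotation; ``gc_bin`` indexes the GC-content bin used to match
    the region against background probes.  ``subexon`` marks a
    junction-adjacent sub-exonic region (needed to call alternative 5'
    splice sites).
    """

    probeset_id: str
    kind: str
    tier: str
    xhyb: int
    start: int
    end: int
    gc_bin: int = 0
    subexon: bool = False

    def __post_init__(self) -> None:
        if self.kind not in REGION_KINDS:
            raise AnnotationError(f"unknown region kind {self.kind!r}")
        if self.tier not in TIERS:
            raise AnnotationError(f"unknown annotation tier {self.tier!r}")
        if self.xhyb not in (1, 2, 3):
            raise AnnotationError(f"xhyb flag must be 1, 2 or 3, got {self.xhyb}")
        if not self.start < self.end:
            raise AnnotationError(
                f"{self.probeset_id}: need start < end, got [{self.start}, {self.end})"
            )


@dataclass
class GeneModel:
    """A gene's ordered probe-set layout.

    ``regions`` are listed 5'->3' in *transcript* orientation and must be
    non-overlapping.  Coordinates are 0-based half-open genomic positions.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    regions: list[Region] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.tx_start < self.tx_end:
            raise AnnotationError(f"{self.gene_id}: tx_start must be < tx_end")
        if not any(r.kind == "exon" for r in self.regions):
            raise AnnotationError(f"{self.gene_id}: a gene needs >=1 exonic region")
        genomic = sorted(self.regions, key=lambda r: r.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise AnnotationError(
                    f"{self.gene_id}: regions {a.probeset_id} and {b.probeset_id} overlap"
                )
        ordered = genomic if self.strand == "+" else genomic[::-1]
        if [r.probeset_id for r in ordered] != [r.probeset_id for r in self.regions]:
            raise AnnotationError(
                f"{self.gene_id}: regions not in 5'->3' transcript order"
            )

    @property
    def probeset_ids(self) -> list[str]:
        return [r.probeset_id for r in self.regions]


def annotation_table(models: dict[str, GeneModel] | list[GeneModel]) -> pd.DataFrame:
    """Flatten gene models into one probe-set annotation row per region.

    The ``order`` column is the 0-based position of the region in transcript
    (5'->3') orientation; downstream classification relies on it.
    """
    if isinstance(models, dict):
        models = list(models.values())
    rows = []
    for gm in models:
        for i, r in enumerate(gm.regions):
            rows.append(
                (r.probeset_id, gm.gene_id, r.kind, r.tier, r.xhyb, r.gc_bin,
                 gm.chrom, r.start, r.end, gm.strand, i, r.subexon)
            )
    df = pd.DataFrame(rows, columns=["probeset_id"] + ANNOTATION_COLUMNS)
    if df["probeset_id"].duplicated().any():
        dups = df.loc[df["probeset_id"].duplicated(), "probeset_id"].tolist()
        raise AnnotationError(f"duplicate probe-set ids across genes: {dups[:5]}")
    return df.set_index("probeset_id")


@dataclass
class BackgroundPopulation:
    """Population of background-probe intensities with GC-bin labels.

    ``values`` are linear-scale intensities; ``gc_bins`` gives each value's
    GC bin so signals can be compared against a GC-matched null.
    """

    values: np.ndarray
    gc_bins: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gc_bins = np.asarray(self.gc_bins, dtype=int)
        if self.values.shape != self.gc_bins.shape:
            raise ConsistencyError("background values and gc_bins differ in length")
        if self.values.size == 0:
            raise ConsistencyError("background population is empty")
        if np.any(self.values <= 0):
            raise ConsistencyError("background intensities must be positive")

    def bin_values(self, gc_bin: int) -> np.ndarray:
        return self.values[self.gc_bins == gc_bin]


@dataclass
class ExpressionStudy:
    """Probe-set x sample intensity matrix plus design and annotation.

    ``matrix`` holds positive linear-scale intensities, one row per probe
    set; ``design`` maps sample name -> group label; ``models`` maps
    gene_id -> :class:`GeneModel`.
    """

    matrix: pd.DataFrame
    design: pd.Series
    background: BackgroundPopulation
    models: dict[str, GeneModel]
    _annotation: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.matrix.values <= 0).any():
            raise ConsistencyError("intensities must be strictly positive")
        missing = set(self.matrix.columns) - set(self.design.index)
        if missing:
            raise ConsistencyError(f"samples without a group: {sorted(missing)}")
        anno = self.annotation
        unknown = self.matrix.index.difference(anno.index)
        if len(unknown):
            raise ConsistencyError(
                f"matrix rows not found in any gene model: {list(unknown[:5])}"
            )

    @property
    def annotation(self) -> pd.DataFrame:
        if self._annotation is None:
            self._annotation = annotation_table(self.models)
        return self._annotation

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance among the columns."""
        seen: list[str] = []
        for s in self.matrix.columns:
            g = self.design[s]
            if g not in seen:
                seen.append(g)
        return seen

    def drop_samples(self, samples: list[str]) -> "ExpressionStudy":
        keep = [c for c in self.matrix.columns if c not in set(samples)]
        return ExpressionStudy(
            matrix=self.matrix[keep],
            design=self.design[keep],
            background=self.background,
            models=self.models,
            _annotation=self._annotation,
        )
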