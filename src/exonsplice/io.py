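"""Plain-text readers and writers for studies, annotations and results.

All tabular artifacts are TSV; gene structure is a BED-like table (0-based
half-open coordinates) plus a region-annotation table keyed by probe-set
id; simulation truth is JSON.  Everything written here is re-read by the
same module (round-trip identity is covered by tests).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .models import BackgroundPopulation, ExpressionStudy, GeneModel, Region
from .simulate import AseInjection, SimulationTruth


def write_gene_models(models: dict[str, GeneModel], bed_path, anno_path) -> None:
    bed_rows, anno_rows = [], []
    for gm in models.values():
        bed_rows.append((gm.chrom, gm.tx_start, gm.tx_end, gm.gene_id, gm.strand))
        for i, r in enumerate(gm.regions):
            anno_rows.append(
                (r.probeset_id, gm.gene_id, r.kind, r.tier, r.xhyb, r.gc_bin,
                 r.start, r.end, i, int(r.subexon))
            )
    pd.DataFrame(
        bed_rows, columns=["chrom", "tx_start", "tx_end", "gene_id", "strand"]
    ).to_csv(bed_path, sep="\t", index=False)
    pd.DataFrame(
        anno_rows,
        columns=["probeset_id", "gene_id", "kind", "tier", "xhyb", "gc_bin",
                 "start", "end", "order", "subexon"],
    ).to_csv(anno_path, sep="\t", index=False)


def read_gene_models(bed_path, anno_path) -> dict[str, GeneModel]:
    bed = pd.read_csv(bed_path, sep="\t")
    anno = pd.read_csv(anno_path, sep="\t")
    models: dict[str, GeneModel] = {}
    for _, row in bed.iterrows():
        sub = anno[anno["gene_id"] == row["gene_id"]].sort_values("order")
        regions = [
            Region(
                probeset_id=str(a["probeset_id"]), kind=a["kind"], tier=a["tier"],
                xhyb=int(a["xhyb"]), start=int(a["start"]), end=int(a["end"]),
                gc_bin=int(a["gc_bin"]), subexon=bool(a["subexon"]),
            )
            for _, a in sub.iterrows()
        ]
        models[row["gene_id"]] = GeneModel(
            gene_id=row["gene_id"], chrom=row["chrom"], strand=row["strand"],
            tx_start=int(row["tx_start"]), tx_end=int(row["tx_end"]),
            regions=regions,
        )
    return models


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: pd.Series, path) -> None:
    design.rename("group").to_frame().to_csv(path, sep="\t")


def read_design(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df["group"]


def write_background(background: BackgroundPopulation, path) -> None:
    pd.DataFrame(
        {"value": background.values, "gc_bin": background.gc_bins}
    ).to_csv(path, sep="\t", index=False)


def read_background(path) -> BackgroundPopulation:
    df = pd.read_csv(path, sep="\t")
    return BackgroundPopulation(df["value"].to_numpy(), df["gc_bin"].to_numpy())


def write_truth(truth: SimulationTruth, path) -> None:
    payload = {
        "seed": truth.seed,
        "noise_sd": truth.noise_sd,
        "baseline": truth.baseline,
        "gene_effects": truth.gene_effects,
        "gene_category": truth.gene_category,
        "ase": {
            ps: {"kind": inj.kind, "groups": list(inj.groups),
                 "effect": inj.effect}
            for ps, inj in truth.ase.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> SimulationTruth:
    payload = json.loads(Path(path).read_text())
    return SimulationTruth(
        seed=int(payload["seed"]),
        noise_sd=float(payload["noise_sd"]),
        baseline={k: float(v) for k, v in payload["baseline"].items()},
        gene_effects={
            g: {k: float(v) for k, v in d.items()}
            for g, d in payload["gene_effects"].items()
        },
        gene_category=dict(payload["gene_category"]),
        ase={
            ps: AseInjection(d["kind"], tuple(d["groups"]), float(d["effect"]))
            for ps, d in payload["ase"].items()
        },
    )


STUDY_FILES = {
    "matrix": "matrix.tsv",
    "design": "design.tsv",
    "background": "background.tsv",
    "bed": "genes.bed.tsv",
    "anno": "probesets.tsv",
    "truth": "truth.json",
}


def write_study(study: ExpressionStudy, out_dir,
                truth: SimulationTruth | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_matrix(study.matrix, out_dir / STUDY_FILES["matrix"])
    write_design(study.design, out_dir / STUDY_FILES["design"])
    write_background(study.background, out_dir / STUDY_FILES["background"])
    write_gene_models(
        study.models, out_dir / STUDY_FILES["bed"], out_dir / STUDY_FILES["anno"]
    )
    if truth is not None:
        write_truth(truth, out_dir / STUDY_FILES["truth"])
    return out_dir


def read_study(in_dir) -> ExpressionStudy:
    in_dir = Path(in_dir)
    return ExpressionStudy(
        matrix=read_matrix(in_dir / STUDY_FILES["matrix"]),
        design=read_design(in_dir / STUDY_FILES["design"]),
        background=read_background(in_dir / STUDY_FILES["background"]),
        models=read_gene_models(
            in_dir / STUDY_FILES["bed"], in_dir / STUDY_FILES["anno"]
        ),
    )


def write_stats_table(stats, path) -> None:
    """Probe-set statistics as one TSV row per probe set (Table-1 layout)."""
    stats.table.to_csv(path, sep="\t")


def read_stats_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
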