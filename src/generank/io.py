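"""TSV serialization for rank lists, fusion results, families and AUC tables."""

from __future__ import annotations

import os

import pandas as pd

from .evaluation import DiseaseFamily, ROCCurve
from .fusion import FusionResult
from .rwr import RankList


def save_rank_lists(rank_lists: list[RankList], path: str) -> None:
    """Write ``source_label<TAB>gene_id<TAB>rank`` rows."""
    rows = [
        (rl.source_label, g, r)
        for rl in rank_lists
        for g, r in sorted(rl.ranks.items(), key=lambda it: it[1])
    ]
    pd.DataFrame(rows, columns=["source_label", "gene_id", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def load_rank_lists(path: str) -> list[RankList]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "source_label": str})
    out = []
    for label, grp in df.groupby("source_label", sort=True):
        out.append(
            RankList(
                source_label=str(label),
                ranks=dict(zip(grp["gene_id"], grp["rank"].astype(int))),
            )
        )
    return out


def save_fusion_result(result: FusionResult, path: str) -> None:
    """Write ``gene_id<TAB>score<TAB>combined_rank<TAB>n_sources`` rows."""
    rows = [
        (g, result.scores[g], r, result.n_sources[g])
        for g, r in sorted(result.ranks.items(), key=lambda it: it[1])
    ]
    pd.DataFrame(
        rows, columns=["gene_id", "score", "combined_rank", "n_sources"]
    ).to_csv(path, sep="\t", index=False)


def load_family(path: str, name: str | None = None) -> DiseaseFamily:
    """One gene-id per line; family name defaults to the file stem."""
    genes = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.append(line.split()[0])
    if name is None:
        name = os.path.splitext(os.path.basename(path))[0]
    return DiseaseFamily(name=name, genes=genes)


def save_family(family: DiseaseFamily, path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(family.genes):
            fh.write(g + "\n")


def save_gene_list(genes: list[str], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")


def load_gene_list(path: str) -> list[str]:
    genes = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line and not line.startswith("#"):
                genes.append(line.split()[0])
    return genes


def save_auc_table(rows: list[tuple[str, str, float]], path: str) -> None:
    """Write ``family<TAB>method<TAB>auc`` rows."""
    pd.DataFrame(rows, columns=["family", "method", "auc"]).to_csv(
        path, sep="\t", index=False
    )


def save_roc_points(curve: ROCCurve, path: str) -> None:
    """Write ROC points as ``fpr<TAB>tpr`` for plotting."""
    pd.DataFrame({"fpr": curve.fpr, "tpr": curve.tpr}).to_csv(
        path, sep="\t", index=False
    )


def save_annotations(table, path: str) -> None:
    """Write ``gene_id<TAB>term_id`` rows."""
    with open(path, "w") as fh:
        for g in sorted(table.entries):
            for t in sorted(table.entries[g]):
                fh.write(f"{g}\t{t}\n")
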