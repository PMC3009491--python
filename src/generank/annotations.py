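"""Gene-term annotation tables and functional-similarity KNN graphs.

A sub-ontology's annotations (e.g. GO biological process) are held as a
mapping gene -> set of terms.  Each term carries an information content
IC(t) = log(n / n_t), where n is the number of annotated genes and n_t the
number annotated with t, so that rare (specific) terms weigh more than
ubiquitous ones.  The functional similarity of two genes is the dot product
of their IC-weighted binary annotation vectors, i.e. the sum of IC(t)^2
over co-annotated terms.  Connecting every gene to its K most similar
genes (edges weighted by that similarity) yields the K-nearest-neighbour
graph used as one ranking data source per sub-ontology.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

logger = logging.getLogger(__name__)

#: ontology codes accepted in the optional third column of annotation files
ONTOLOGY_CODES = {"P": "BP", "C": "CC", "F": "MF"}


@dataclass
class AnnotationTable:
    """Gene -> term-set annotations for one sub-ontology.

    Parameters
    ----------
    ontology_label:
        One of ``"BP"``, ``"CC"``, ``"MF"`` or any other label.
    entries:
        Mapping gene-id -> set of term-ids; every gene must carry at
        least one term.
    """

    ontology_label: str = "other"
    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, terms in self.entries.items():
            if not gene:
                raise ValueError("empty gene id in annotation table")
            if not terms:
                raise ValueError(f"gene {gene!r} has no annotation terms")
            if any(not t for t in terms):
                raise ValueError(f"gene {gene!r} carries an empty term id")

    @property
    def genes(self) -> list[str]:
        return sorted(self.entries)

    @property
    def terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.entries.values():
            out |= terms
        return out

    def __len__(self) -> int:
        return len(self.entries)


def compute_information_content(
    table: AnnotationTable, base: float | None = None
) -> dict[str, float]:
    """Information content IC(t) = log(n / n_t) for every term in *table*.

    ``n`` is the total number of annotated genes and ``n_t`` the number of
    genes annotated with term ``t``.  Natural log by default; the log base
    only rescales all IC values by a common factor, which downstream
    rankings are invariant to.

    Raises
    ------
    ValueError
        If the table is empty ("no annotations").
    """
    if len(table) == 0:
        raise ValueError("no annotations")
    n = len(table)
    counts: dict[str, int] = {}
    for terms in table.entries.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    log = math.log if base is None else (lambda x: math.log(x, base))
    return {t: log(n / n_t) for t, n_t in counts.items()}


def gene_similarity(
    g1: str, g2: str, table: AnnotationTable, ic: dict[str, float]
) -> float:
    """Functional similarity: sum of IC(t)^2 over terms annotating both genes.

    This is the dot product of the two genes' IC-weighted annotation
    vectors, and is symmetric in its gene arguments.
    """
    for g in (g1, g2):
        if g not in table.entries:
            raise KeyError(f"gene {g!r} not in annotation table")
    shared = table.entries[g1] & table.entries[g2]
    return sum(ic[t] ** 2 for t in shared)


def build_knn_graph(
    table: AnnotationTable,
    ic: dict[str, float],
    k: int = 5,
    source_label: str | None = None,
) -> nx.Graph:
    """K-nearest-neighbour functional-similarity graph.

    Each gene is connected to its ``k`` most similar genes (ties at the
    k-th similarity value are all included, making the result
    permutation-invariant); the union of the directed selections gives the
    undirected edge set.  Edge weight is the similarity itself.
    Zero-similarity pairs never create edges, so genes sharing no
    informative term with anyone remain isolated nodes.
    """
    genes = table.genes
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= len(genes):
        raise ValueError(
            f"k={k} must be smaller than the number of genes ({len(genes)})"
        )
    label = source_label if source_label is not None else table.ontology_label

    # invert gene->terms once so each gene only scores genes it can share
    # a term with; all other similarities are exactly zero
    by_term: dict[str, list[str]] = {}
    for g, terms in table.entries.items():
        for t in terms:
            by_term.setdefault(t, []).append(g)

    graph = nx.Graph(source_label=label)
    graph.add_nodes_from(genes)
    for g in genes:
        sims: dict[str, float] = {}
        for t in table.entries[g]:
            w = ic[t] ** 2
            if w == 0.0:
                continue
            for other in by_term[t]:
                if other != g:
                    sims[other] = sims.get(other, 0.0) + w
        if not sims:
            continue
        ordered = sorted(sims.items(), key=lambda it: (-it[1], it[0]))
        if len(ordered) > k:
            kth = ordered[k - 1][1]
            ordered = [it for it in ordered if it[1] >= kth]
        for other, w in ordered:
            graph.add_edge(g, other, weight=w)
    return graph


def load_annotations(path: str, ontology_label: str | None = None) -> AnnotationTable:
    """Read a TSV annotation file: ``gene_id<TAB>term_id[<TAB>ontology_code]``.

    The optional third column holds a GAF aspect code (P/C/F); when
    *ontology_label* is not given and the file carries a single consistent
    code, the matching sub-ontology label (BP/CC/MF) is used.
    Lines starting with ``#`` are comments.
    """
    entries: dict[str, set[str]] = {}
    seen_codes: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected gene and term columns")
            gene, term = fields[0], fields[1]
            if len(fields) >= 3 and fields[2]:
                seen_codes.add(fields[2])
            entries.setdefault(gene, set()).add(term)
    if ontology_label is None:
        if len(seen_codes) == 1:
            ontology_label = ONTOLOGY_CODES.get(next(iter(seen_codes)), "other")
        else:
            ontology_label = "other"
    return AnnotationTable(ontology_label=ontology_label, entries=entries)
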