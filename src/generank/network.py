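"""Weighted undirected gene networks and their edge-list serialization.

Networks are plain :class:`networkx.Graph` objects whose graph attribute
``source_label`` names the data source (e.g. ``"PPI"`` or ``"BP"``).  Edge
weights are strictly positive; self-loops are disallowed.
"""

from __future__ import annotations

import logging

import networkx as nx

logger = logging.getLogger(__name__)


def make_network(
    edges: list[tuple[str, str, float]] | list[tuple[str, str]],
    source_label: str,
    nodes: list[str] | None = None,
) -> nx.Graph:
    """Build a network from (gene_a, gene_b[, weight]) tuples."""
    g = nx.Graph(source_label=source_label)
    if nodes:
        g.add_nodes_from(nodes)
    for edge in edges:
        a, b = edge[0], edge[1]
        w = float(edge[2]) if len(edge) > 2 else 1.0
        if a == b:
            logger.warning("dropping self-loop on %s", a)
            continue
        if w <= 0:
            raise ValueError(f"non-positive edge weight {w} on ({a}, {b})")
        if g.has_edge(a, b):
            w = max(w, g[a][b]["weight"])
        g.add_edge(a, b, weight=w)
    return g


def load_network(path: str, source_label: str) -> nx.Graph:
    """Read a whitespace/tab-delimited edge list ``geneA geneB [weight]``.

    A missing weight column defaults to 1.0.  Duplicate pairs (in either
    orientation) are collapsed keeping the maximum weight; self-loops are
    dropped with a warning.  Lines starting with ``#`` are comments.

    Raises
    ------
    ValueError
        On a malformed line (with its line number) or a weight <= 0.
    """
    g = nx.Graph(source_label=source_label)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (2, 3):
                raise ValueError(
                    f"{path}:{lineno}: expected 'geneA geneB [weight]', got {line!r}"
                )
            a, b = fields[0], fields[1]
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: bad weight {fields[2]!r}"
                    ) from exc
            else:
                w = 1.0
            if w <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive weight {w}")
            if a == b:
                logger.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
                continue
            if g.has_edge(a, b):
                w = max(w, g[a][b]["weight"])
            g.add_edge(a, b, weight=w)
    return g


def save_network(graph: nx.Graph, path: str) -> None:
    """Write a network as a TSV edge list ``gene_a<TAB>gene_b<TAB>weight``."""
    with open(path, "w") as fh:
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):g}\n")
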