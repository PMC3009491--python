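"""Random walk with restart (RWR) over a gene network.

A walker starts uniformly on a set of source (seed) genes; at every step
it either moves to a neighbour with probability proportional to the edge
weight, or restarts at the seeds with probability ``gamma``.  The steady
state p solves p = (1-gamma) M p + gamma p0 with M column-stochastic, and
its entries measure proximity to the seeds: candidate genes are ranked by
steady-state probability, descending.

Isolated nodes are removed before the transition matrix is built — the
walker can never reach them, and a zero column would leak probability
mass — so genes isolated in a source are simply absent from that source's
rank list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

DEFAULT_GAMMA = 0.7
DEFAULT_TOL = 1e-10
MAX_ITER = 10_000


@dataclass
class TransitionModel:
    """Column-stochastic transition matrix over the non-isolated nodes."""

    matrix: sparse.csr_matrix
    nodes: list[str]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.nodes)}


@dataclass
class RankList:
    """Ranks 1..m of the test genes present in one data source."""

    source_label: str
    ranks: dict[str, int]

    def __post_init__(self) -> None:
        m = len(self.ranks)
        if m and sorted(self.ranks.values()) != list(range(1, m + 1)):
            raise ValueError(
                f"ranks of source {self.source_label!r} are not a permutation of 1..{m}"
            )

    @property
    def m(self) -> int:
        """Number of test genes available in this source."""
        return len(self.ranks)

    def __contains__(self, gene: str) -> bool:
        return gene in self.ranks

    def __len__(self) -> int:
        return len(self.ranks)


def build_transition(net: nx.Graph) -> TransitionModel:
    """Column-normalized transition matrix M(j,i) = A(j,i) / d(i).

    d(i) is the weighted degree (column sum) of node i, so each node's
    outgoing probabilities are proportional to its incident edge weights.
    Isolated nodes are dropped (see module docstring).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(g for g in net.nodes if net.degree(g) > 0)
    if not nodes:
        # degenerate edgeless network: the walker can only sit on the
        # restart vector, so keep all nodes with a zero transition matrix
        nodes = sorted(net.nodes)
        zero = sparse.csr_matrix((len(nodes), len(nodes)))
        return TransitionModel(matrix=zero, nodes=nodes)
    adj = nx.to_scipy_sparse_array(net, nodelist=nodes, weight="weight", format="csc")
    deg = np.asarray(adj.sum(axis=0)).ravel()
    inv = sparse.diags(1.0 / deg)
    m = (adj @ inv).tocsr()
    return TransitionModel(matrix=m, nodes=nodes)


def restart_vector(tm: TransitionModel, sources: set[str]) -> np.ndarray:
    """Uniform probability over the source genes present in the network."""
    idx = [tm.index[g] for g in sources if g in tm.index]
    if not idx:
        raise ValueError("no sources in network")
    p0 = np.zeros(len(tm.nodes))
    p0[idx] = 1.0 / len(idx)
    return p0


def rwr_steady_state(
    tm: TransitionModel,
    sources: set[str],
    gamma: float = DEFAULT_GAMMA,
    tol: float = DEFAULT_TOL,
) -> dict[str, float]:
    """Iterate p <- (1-gamma) M p + gamma p0 until the L1 change < tol.

    Returns the steady-state probability per node.  Raises if no source
    gene is present in the network, or on non-convergence within
    ``MAX_ITER`` iterations.
    """
    if not 0 < gamma < 1:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    p0 = restart_vector(tm, sources)
    p = p0.copy()
    m = tm.matrix
    for _ in range(MAX_ITER):
        p_next = (1.0 - gamma) * (m @ p) + gamma * p0
        # exact no-op when M is column-stochastic on the support; restores
        # conservation for the degenerate zero-matrix (edgeless) case
        p_next /= p_next.sum()
        if np.abs(p_next - p).sum() < tol:
            return dict(zip(tm.nodes, p_next))
        p = p_next
    raise RuntimeError(f"RWR did not converge within {MAX_ITER} iterations")


def rwr_solve_direct(
    tm: TransitionModel, sources: set[str], gamma: float = DEFAULT_GAMMA
) -> dict[str, float]:
    """Closed-form steady state p = gamma (I - (1-gamma) M)^{-1} p0.

    Dense linear solve; intended as an independent cross-check of the
    iterative solver on small graphs.
    """
    p0 = restart_vector(tm, sources)
    n = len(tm.nodes)
    a = np.eye(n) - (1.0 - gamma) * tm.matrix.toarray()
    p = gamma * np.linalg.solve(a, p0)
    p /= p.sum()
    return dict(zip(tm.nodes, p))


def rank_test_genes(
    p: dict[str, float], test_genes: list[str], source_label: str
) -> RankList:
    """Rank the test genes present in the network by probability, descending.

    Test genes absent from the probability vector (i.e. from the network)
    are omitted.  Ties are broken by lexicographic gene-id, ascending, so
    the ranking is deterministic and permutation-invariant.
    """
    present = [g for g in dict.fromkeys(test_genes) if g in p]
    if not present:
        logger.warning("no test gene present in source %r", source_label)
        return RankList(source_label=source_label, ranks={})
    ordered = sorted(present, key=lambda g: (-p[g], g))
    return RankList(
        source_label=source_label,
        ranks={g: r for r, g in enumerate(ordered, start=1)},
    )


def rank_with_rwr(
    net: nx.Graph,
    training_genes: set[str],
    test_genes: list[str],
    gamma: float = DEFAULT_GAMMA,
    tol: float = DEFAULT_TOL,
) -> RankList:
    """Convenience: transition matrix + steady state + ranking in one call."""
    tm = build_transition(net)
    p = rwr_steady_state(tm, training_genes, gamma=gamma, tol=tol)
    return rank_test_genes(p, test_genes, net.graph.get("source_label", "network"))
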