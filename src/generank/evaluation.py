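"""Leave-one-out cross-validation (LOOCV) and ROC/AUC evaluation.

For a disease family, each known disease gene is held out in turn; the
remaining family members seed a random walk with restart on every data
source, the held-out gene plus a set of control genes form the test set,
and the per-source rank lists are fused into one combined ranking.
Ideally the held-out gene ranks first.  Pooling all prioritizations
yields a ROC curve: sensitivity is the fraction of held-out disease genes
ranked above a threshold, specificity the fraction of control genes
ranked below it, and the area under the curve (AUC) summarizes
performance — 100% means every held-out gene was ranked first.

Control genes stand in for an artificial linkage interval.  When no
genomic-neighbour table is supplied, controls are sampled uniformly
(seeded) from the union of network nodes outside the family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from sklearn import metrics

from . import fusion as _fusion
from . import rwr as _rwr

logger = logging.getLogger(__name__)

DEFAULT_CONTROLS = 99


@dataclass
class DiseaseFamily:
    """A named set of known disease genes (>= 2 so LOOCV can train)."""

    name: str
    genes: frozenset[str]

    def __init__(self, name: str, genes) -> None:
        self.name = name
        self.genes = frozenset(genes)
        if len(self.genes) < 2:
            raise ValueError(f"family {name!r} needs >= 2 genes for LOOCV")


@dataclass
class PrioritizationRecord:
    """One LOOCV prioritization: the held-out gene's combined rank among m.

    ``combined`` holds the fused ranking over the test genes available in
    at least one source; the held-out gene is the single positive, all
    other test genes are negatives.
    """

    family: str
    held_out: str
    combined: _rwr.RankList
    source_rank_lists: dict[str, _rwr.RankList] = field(default_factory=dict)
    n_ops: int = 0

    def __post_init__(self) -> None:
        if self.held_out not in self.combined.ranks:
            raise ValueError(
                f"held-out gene {self.held_out!r} missing from combined ranking"
            )

    @property
    def rank(self) -> int:
        return self.combined.ranks[self.held_out]

    @property
    def m(self) -> int:
        return self.combined.m


@dataclass
class ROCCurve:
    """Pooled ROC points (1 - specificity, sensitivity) and the AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _default_control_sampler(
    networks: Sequence[nx.Graph], family: DiseaseFamily, controls_per_gene: int
) -> Callable[[str, np.random.Generator], list[str]]:
    pool = sorted(set().union(*(set(n.nodes) for n in networks)) - family.genes)

    def sample(held_out: str, rng: np.random.Generator) -> list[str]:
        k = min(controls_per_gene, len(pool))
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[i] for i in sorted(idx)]

    return sample


def loocv_run(
    family: DiseaseFamily,
    networks: Sequence[nx.Graph],
    controls_per_gene: int = DEFAULT_CONTROLS,
    method: str = "drs",
    *,
    levels: int = _fusion.DEFAULT_LEVELS,
    gamma: float = _rwr.DEFAULT_GAMMA,
    tol: float = _rwr.DEFAULT_TOL,
    weights: dict[str, float] | None = None,
    rng: np.random.Generator | int | None = None,
    control_provider: Callable[[str, np.random.Generator], list[str]] | None = None,
    extra_sources: Callable[
        [list[str], str, np.random.Generator], list[_rwr.RankList]
    ] | None = None,
) -> list[PrioritizationRecord]:
    """Run LOOCV for one family: one record per held-out disease gene.

    For each held-out gene the remaining family members are the RWR seed
    set; the test set is the held-out gene plus ``controls_per_gene``
    controls (from *control_provider*, or random non-family network genes).
    Per-source rankings cover only test genes present in that source;
    fusion is by *method* (``drs``/``wdrs``/``ndos``).  A held-out gene
    absent from every source is skipped with a warning.  *extra_sources*
    may inject additional (e.g. simulated) rank lists per run.
    """
    if len(family.genes) < 2:
        raise ValueError("family must contain at least 2 genes")
    rng = np.random.default_rng(rng)
    if control_provider is None:
        control_provider = _default_control_sampler(
            networks, family, controls_per_gene
        )
    # the transition matrix is seed-independent: build once per source
    transitions = [(_net_label(n), _rwr.build_transition(n)) for n in networks]

    records: list[PrioritizationRecord] = []
    for held_out in sorted(family.genes):
        training = set(family.genes) - {held_out}
        controls = [g for g in control_provider(held_out, rng) if g not in family.genes]
        test_genes = [held_out] + controls
        rank_lists: list[_rwr.RankList] = []
        for label, tm in transitions:
            if not any(g in tm.index for g in training):
                logger.warning(
                    "family %s: no training gene in source %s; source skipped",
                    family.name, label,
                )
                continue
            p = _rwr.rwr_steady_state(tm, training, gamma=gamma, tol=tol)
            rl = _rwr.rank_test_genes(p, test_genes, label)
            if len(rl):
                rank_lists.append(rl)
        if extra_sources is not None:
            rank_lists.extend(extra_sources(test_genes, held_out, rng))
        if not any(held_out in rl for rl in rank_lists):
            logger.warning(
                "family %s: held-out gene %s absent from every source; skipped",
                family.name, held_out,
            )
            continue
        fused = _fusion.combine(rank_lists, method, levels=levels, weights=weights)
        records.append(
            PrioritizationRecord(
                family=family.name,
                held_out=held_out,
                combined=fused.as_rank_list(),
                source_rank_lists={rl.source_label: rl for rl in rank_lists},
                n_ops=fused.n_ops,
            )
        )
    return records


def _net_label(net: nx.Graph) -> str:
    return net.graph.get("source_label", "network")


def roc_auc(records: Sequence[PrioritizationRecord]) -> ROCCurve:
    """Pooled ROC curve and AUC over a set of prioritization records.

    Every (gene, rank) pair from every record enters the pool with equal
    weight; the held-out gene of its record is the positive.  Scoring is
    by rank ratio rank/m so records with different coverage pool on a
    common scale (identical to pooling raw ranks when all m agree).  Ties
    count one half, the Mann-Whitney convention.
    """
    if not records:
        raise ValueError("no records to evaluate")
    labels: list[int] = []
    scores: list[float] = []
    for rec in records:
        for gene, rank in rec.combined.ranks.items():
            labels.append(1 if gene == rec.held_out else 0)
            scores.append(-rank / rec.m)  # higher score = better rank
    y = np.asarray(labels)
    s = np.asarray(scores)
    if (y == 0).sum() == 0:
        raise ValueError("records contain no negative genes")
    fpr, tpr, _ = metrics.roc_curve(y, s)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(metrics.auc(fpr, tpr)))


def per_source_auc(
    family: DiseaseFamily,
    network: nx.Graph,
    controls_per_gene: int = DEFAULT_CONTROLS,
    **kwargs,
) -> float:
    """Standalone AUC of a single data source on one family.

    LOOCV restricted to this source; disease genes absent from the source
    cannot be prioritized by it and contribute no record.
    """
    tm = _rwr.build_transition(network)
    present = [g for g in family.genes if g in tm.index]
    if not present:
        raise ValueError(
            f"no disease gene of family {family.name!r} present in source "
            f"{_net_label(network)!r}"
        )
    records = loocv_run(
        family, [network], controls_per_gene=controls_per_gene,
        method="drs", **kwargs,
    )
    return roc_auc(records).auc


def per_source_weights(
    family: DiseaseFamily,
    networks: Sequence[nx.Graph],
    floor: float = _fusion.DEFAULT_AUC_FLOOR,
    **kwargs,
) -> dict[str, float]:
    """AUC-derived WDRS weights, one standalone LOOCV AUC per source.

    Sources covering no family gene get AUC 0 (hence weight 0).
    """
    aucs: dict[str, float] = {}
    for net in networks:
        label = _net_label(net)
        try:
            aucs[label] = per_source_auc(family, net, **kwargs)
        except ValueError:
            aucs[label] = 0.0
    return _fusion.auc_based_weights(aucs, floor=floor)


def compare_methods(
    aucs_a: Sequence[float], aucs_b: Sequence[float]
) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-family AUCs.

    Identical vectors carry no signed differences and return p = 1.0.
    """
    if len(aucs_a) != len(aucs_b):
        raise ValueError("AUC vectors must be paired (same families)")
    if len(aucs_a) < 2:
        raise ValueError("need at least 2 paired families")
    diffs = np.asarray(aucs_a, dtype=float) - np.asarray(aucs_b, dtype=float)
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)
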