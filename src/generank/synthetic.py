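"""Seeded synthetic fixtures: modular gene networks, annotation tables,
disease families, and simulated extra rank-list sources.

The fixtures encode the modularity hypothesis behind network-based
prioritization: genes of one disease family co-locate in a network
module.  The interaction network is a planted partition — family pairs
connect with probability ``module_density``, everything else with
``background_density`` — and the annotation tables give family members a
set of shared enriched terms on top of random background terms, so the
KNN functional-similarity graphs built from them carry the same signal.
Each source covers only a fraction of genes, mirroring the incomplete
coverage of real interaction and annotation databases.

Simulated extra rank-list sources emulate adding further data sources at
fixed candidate-set size: m of the test genes are covered, their ranks
are a uniform random permutation of 1..m, and the known disease gene's
rank is overwritten by a draw from an empirical distribution of real
disease-gene rank positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .annotations import AnnotationTable, build_knn_graph, compute_information_content
from .evaluation import DiseaseFamily, loocv_run, roc_auc
from .network import make_network
from .rwr import RankList

#: per-source coverage of available test genes (out of 100) used when
#: simulating extra sources, cycled in order
DEFAULT_M_AVAILABLE = (66, 59, 57, 57)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study conditions.

    Defaults describe an informative four-source fixture: one
    planted-partition interaction network plus three annotation-derived
    5-NN graphs, with per-source gene coverage mirroring realistic
    database incompleteness.
    """

    seed: int = 0
    n_genes: int = 300
    n_families: int = 1
    family_size: int = 8
    module_density: float = 0.30
    background_density: float = 0.02
    n_terms: int = 150
    terms_per_family: int = 6
    enrichment: float = 0.9
    background_terms_per_gene: int = 8
    coverage: tuple[float, ...] = (0.93, 0.88, 0.84, 0.80)
    knn_k: int = 5

    def __post_init__(self) -> None:
        for name in ("module_density", "background_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if any(not 0.0 < c <= 1.0 for c in self.coverage):
            raise ValueError("coverage fractions must lie in (0, 1]")
        if self.n_families * self.family_size > self.n_genes:
            raise ValueError("families do not fit into n_genes")


@dataclass
class EmpiricalRankDistribution:
    """A distribution of disease-gene rank positions to sample from.

    Either an observed multiset of positions (uniform resampling) or a
    weighted table.  All positions are >= 1.
    """

    positions: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        if self.positions.size == 0:
            raise ValueError("empty rank distribution")
        if (self.positions < 1).any():
            raise ValueError("rank positions must be >= 1")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            self.weights = self.weights / self.weights.sum()

    def sample(self, rng: np.random.Generator, clip: int | None = None) -> int:
        r = int(rng.choice(self.positions, p=self.weights))
        return min(r, clip) if clip is not None else r


def default_rank_distribution(max_rank: int = 100, p: float = 0.25) -> EmpiricalRankDistribution:
    """Synthetic top-skewed stand-in for an observed rank distribution.

    A truncated geometric table over ranks 1..max_rank: most disease
    genes rank near the top of an informative source, with a long tail.
    This is a synthetic default, not an observed table; supply your own
    :class:`EmpiricalRankDistribution` to match real data.
    """
    ranks = np.arange(1, max_rank + 1)
    w = (1 - p) ** (ranks - 1) * p
    return EmpiricalRankDistribution(positions=ranks, weights=w)


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(1, n + 1)]


def _planted_partition(
    genes: list[str],
    families: list[DiseaseFamily],
    p_in: float,
    p_out: float,
    rng: np.random.Generator,
    label: str,
) -> nx.Graph:
    fam_of = {}
    for k, fam in enumerate(families):
        for g in fam.genes:
            fam_of[g] = k
    pairs = list(itertools.combinations(genes, 2))
    draws = rng.random(len(pairs))
    edges = []
    for (a, b), u in zip(pairs, draws):
        same = a in fam_of and b in fam_of and fam_of[a] == fam_of[b]
        if u < (p_in if same else p_out):
            edges.append((a, b, 1.0))
    return make_network(edges, source_label=label, nodes=genes)


def _annotation_table(
    genes: list[str],
    families: list[DiseaseFamily],
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    label: str,
) -> AnnotationTable:
    pool = [f"{label}:T{t:03d}" for t in range(cfg.n_terms)]
    entries: dict[str, set[str]] = {g: set() for g in genes}
    covered = set(genes)
    for k, fam in enumerate(families):
        fam_terms = [f"{label}:fam{k}:t{q}" for q in range(cfg.terms_per_family)]
        for g in sorted(fam.genes):
            if g not in covered:
                continue
            keep = rng.random(len(fam_terms)) < cfg.enrichment
            entries[g].update(t for t, kp in zip(fam_terms, keep) if kp)
    for g in genes:
        idx = rng.choice(cfg.n_terms, size=cfg.background_terms_per_gene, replace=False)
        entries[g].update(pool[i] for i in idx)
    return AnnotationTable(ontology_label=label, entries=entries)


def gen_fixture(
    cfg: SyntheticConfig,
) -> tuple[list[nx.Graph], list[AnnotationTable], list[DiseaseFamily]]:
    """Generate networks, annotation tables and disease families.

    Returns four networks — a planted-partition interaction network
    ("PPI") and three KNN functional-similarity graphs built from the
    generated annotation tables ("BP", "CC", "MF") — together with the
    tables themselves and the planted families.  Deterministic under a
    fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    families = []
    cursor = 0
    for k in range(cfg.n_families):
        fam_genes = genes[cursor:cursor + cfg.family_size]
        cursor += cfg.family_size
        families.append(DiseaseFamily(name=f"family{k}", genes=fam_genes))

    labels = ["PPI", "BP", "CC", "MF"]
    networks: list[nx.Graph] = []
    tables: list[AnnotationTable] = []
    for j, label in enumerate(labels):
        frac = cfg.coverage[j % len(cfg.coverage)]
        n_cov = max(cfg.family_size + cfg.knn_k + 1, round(frac * cfg.n_genes))
        idx = rng.choice(cfg.n_genes, size=min(n_cov, cfg.n_genes), replace=False)
        covered = sorted(genes[i] for i in idx)
        if label == "PPI":
            networks.append(
                _planted_partition(
                    covered, families, cfg.module_density,
                    cfg.background_density, rng, label,
                )
            )
        else:
            table = _annotation_table(covered, families, cfg, rng, label)
            tables.append(table)
            ic = compute_information_content(table)
            networks.append(build_knn_graph(table, ic, k=cfg.knn_k, source_label=label))
    return networks, tables, families


def simulate_extra_source(
    test_genes: list[str],
    m_available: int,
    positive_gene: str,
    rank_dist: EmpiricalRankDistribution,
    rng: np.random.Generator | int | None = None,
    source_label: str = "simulated",
) -> RankList:
    """Simulate one extra data source's rank list over the test set.

    ``m_available`` test genes are covered (the positive gene always is);
    their prioritization is a uniform random permutation of 1..m, after
    which the positive gene's rank is overwritten by a draw from
    *rank_dist* (clipped to m) and the displaced gene takes the
    positive's permuted rank, preserving the permutation.
    """
    rng = np.random.default_rng(rng)
    if positive_gene not in test_genes:
        raise ValueError("positive gene must belong to the test set")
    if not 1 <= m_available <= len(test_genes):
        raise ValueError(
            f"m_available={m_available} outside 1..{len(test_genes)}"
        )
    others = [g for g in test_genes if g != positive_gene]
    idx = rng.choice(len(others), size=m_available - 1, replace=False)
    selected = [positive_gene] + [others[i] for i in sorted(idx)]
    perm = rng.permutation(m_available) + 1
    ranks = dict(zip(selected, (int(r) for r in perm)))
    target = rank_dist.sample(rng, clip=m_available)
    for g, r in ranks.items():  # swap the positive into its drawn rank
        if r == target:
            ranks[g] = ranks[positive_gene]
            break
    ranks[positive_gene] = target
    return RankList(source_label=source_label, ranks=ranks)


def _extra_source_factory(
    n_extra: int,
    rank_dist: EmpiricalRankDistribution,
    m_cycle: tuple[int, ...] = DEFAULT_M_AVAILABLE,
):
    def provide(test_genes, held_out, rng):
        out = []
        for j in range(n_extra):
            m = min(m_cycle[j % len(m_cycle)], len(test_genes))
            out.append(
                simulate_extra_source(
                    test_genes, m, held_out, rank_dist, rng,
                    source_label=f"sim{j}",
                )
            )
        return out

    return provide


def scaling_experiment(
    n_sources: int,
    cfg: SyntheticConfig,
    method: str = "drs",
    rank_dist: EmpiricalRankDistribution | None = None,
    **loocv_kwargs,
) -> tuple[float, int]:
    """Pooled AUC and fusion operation count at ``n_sources`` data sources.

    Runs LOOCV over the fixture's families using the four fixture-derived
    sources plus ``n_sources - 4`` simulated sources (with top-skewed
    disease-gene ranks by default).  Returns (pooled AUC, total fusion
    operation count) — the operation counter, not wall-clock, carries the
    complexity comparison between DRS and NDOS.
    """
    if n_sources < 1:
        raise ValueError("need at least one data source")
    networks, _, families = gen_fixture(cfg)
    networks = networks[:min(n_sources, 4)]
    n_extra = max(0, n_sources - 4)
    extra = None
    if n_extra:
        if rank_dist is None:
            rank_dist = default_rank_distribution()
        extra = _extra_source_factory(n_extra, rank_dist)
    records = []
    rng = np.random.default_rng(cfg.seed + 1)
    for fam in families:
        records.extend(
            loocv_run(
                fam, networks, method=method, rng=rng,
                extra_sources=extra, **loocv_kwargs,
            )
        )
    curve = roc_auc(records)
    return curve.auc, sum(r.n_ops for r in records)
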