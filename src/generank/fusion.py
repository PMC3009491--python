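"""Rank fusion: discounted rating system (DRS), its AUC-weighted variant
(WDRS), and N-dimensional order statistics (NDOS).

Each of N data sources contributes a rank list over the candidate genes it
covers.  DRS bins each source's ranks into B equal-size rating levels
(rank 1 gets the top rating B), discounts each rating by log2(rank + 1) —
the discounted-cumulated-gain discount from document retrieval — and
averages the discounted ratings across the sources covering the gene.
WDRS replaces the mean with a weighted sum, the weights usually derived
from each source's standalone AUC.  NDOS instead converts the gene's rank
ratios into the joint probability Q, under independent uniform rankings,
of order statistics at least as extreme; smaller Q is stronger evidence.

Genes missing from some sources are handled by adjusting N per gene: only
the sources covering a gene enter its score.

Each fusion result carries ``n_ops``, a count of elementary per-gene score
operations: DRS/WDRS cost one operation per (gene, covering source), so
total work is linear in the number of sources, while the NDOS recursion
costs O(N^2) operations per gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .rwr import RankList

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = 5
DEFAULT_AUC_FLOOR = 0.7


@dataclass
class FusionResult:
    """Combined scores and ranks from one fusion run.

    ``scores`` maps gene -> combined score (higher is better for DRS/WDRS,
    lower for NDOS); ``ranks`` maps gene -> combined rank 1..n;
    ``n_sources`` maps gene -> number of sources covering it; ``n_ops``
    counts elementary fusion operations (see module docstring).
    """

    method: str
    scores: dict[str, float]
    ranks: dict[str, int]
    n_sources: dict[str, int]
    n_ops: int = 0

    def as_rank_list(self) -> RankList:
        return RankList(source_label=self.method, ranks=dict(self.ranks))


def assign_ratings(rl: RankList, levels: int = DEFAULT_LEVELS) -> dict[str, int]:
    """Bin a source's ranks 1..m into ``levels`` equal-size rating blocks.

    rating(r) = B - floor((r - 1) * B / m): the top block receives the
    highest rating B, the bottom block rating 1, with exactly equal block
    sizes whenever B divides m.
    """
    m = len(rl)
    if levels < 2:
        raise ValueError("need at least 2 rating levels")
    if m < 1:
        raise ValueError("empty rank list")
    if levels > m:
        raise ValueError("more rating levels than genes")
    return _ratings(rl, levels)


def _ratings(rl: RankList, levels: int) -> dict[str, int]:
    # rank 1 always maps to the top rating; for m < levels the blocks are
    # no longer equal-size but the formula stays monotone with range 1..B,
    # which is what fusion needs for sources covering very few test genes
    m = len(rl)
    return {g: levels - ((r - 1) * levels) // m for g, r in rl.ranks.items()}


def discounted_rating(rating: int, rank: int) -> float:
    """dr = rating / log2(rank + 1); no discount at rank 1."""
    if rating < 1 or rank < 1:
        raise ValueError("rating and rank must be >= 1")
    return rating / math.log2(rank + 1)


def _discounted_ratings(
    rank_lists: list[RankList], levels: int
) -> dict[str, dict[str, float]]:
    """Per source-label, gene -> discounted rating."""
    out: dict[str, dict[str, float]] = {}
    for rl in rank_lists:
        if len(rl) == 0:
            continue
        ratings = _ratings(rl, levels)
        out[rl.source_label] = {
            g: discounted_rating(ratings[g], r) for g, r in rl.ranks.items()
        }
    return out


def _ranked(scores: dict[str, float], descending: bool) -> dict[str, int]:
    sign = -1.0 if descending else 1.0
    ordered = sorted(scores, key=lambda g: (sign * scores[g], g))
    return {g: r for r, g in enumerate(ordered, start=1)}


def _union_genes(rank_lists: list[RankList]) -> list[str]:
    genes: set[str] = set()
    for rl in rank_lists:
        genes |= set(rl.ranks)
    return sorted(genes)


def drs_combine(
    rank_lists: list[RankList], levels: int = DEFAULT_LEVELS
) -> FusionResult:
    """DRS: combined score = mean discounted rating over covering sources."""
    if not rank_lists:
        raise ValueError("no rank lists to combine")
    dr = _discounted_ratings(rank_lists, levels)
    scores: dict[str, float] = {}
    n_sources: dict[str, int] = {}
    n_ops = 0
    for g in _union_genes(rank_lists):
        # accumulate in label order so the score is independent of the
        # order in which sources were supplied, bit for bit
        vals = [dr[s][g] for s in sorted(dr) if g in dr[s]]
        n_ops += len(vals)
        scores[g] = sum(vals) / len(vals)
        n_sources[g] = len(vals)
    return FusionResult(
        method="DRS",
        scores=scores,
        ranks=_ranked(scores, descending=True),
        n_sources=n_sources,
        n_ops=n_ops,
    )


def auc_based_weights(
    per_source_aucs: dict[str, float], floor: float = DEFAULT_AUC_FLOOR
) -> dict[str, float]:
    """Source weights proportional to standalone AUC, zeroed below *floor*.

    Sources whose AUC falls below the floor get weight 0 (filtered out);
    the remaining AUCs are normalized to sum to 1.
    """
    for label, auc in per_source_aucs.items():
        if not 0.0 <= auc <= 1.0:
            raise ValueError(f"AUC of source {label!r} outside [0, 1]: {auc}")
    raw = {s: (a if a >= floor else 0.0) for s, a in per_source_aucs.items()}
    total = sum(raw.values())
    if total == 0:
        raise ValueError("no source passes AUC floor")
    return {s: w / total for s, w in raw.items()}


def wdrs_combine(
    rank_lists: list[RankList],
    weights: dict[str, float],
    levels: int = DEFAULT_LEVELS,
) -> FusionResult:
    """Weighted DRS: combined score = sum of mu_i * dr_i over covering sources.

    Weights are renormalized per gene over the sources that cover it (the
    weighted analogue of DRS's adjusted N).  A gene covered only by
    zero-weight sources scores 0 and therefore ranks last.
    """
    if not rank_lists:
        raise ValueError("no rank lists to combine")
    missing = {rl.source_label for rl in rank_lists} - set(weights)
    if missing:
        raise KeyError(f"no weight for sources: {sorted(missing)}")
    dr = _discounted_ratings(rank_lists, levels)
    scores: dict[str, float] = {}
    n_sources: dict[str, int] = {}
    n_ops = 0
    for g in _union_genes(rank_lists):
        avail = [(s, dr[s][g]) for s in sorted(dr) if g in dr[s]]
        n_sources[g] = len(avail)
        n_ops += len(avail)
        wsum = sum(weights[s] for s, _ in avail)
        if wsum == 0:
            logger.warning("gene %s covered only by zero-weight sources", g)
            scores[g] = 0.0
        else:
            scores[g] = sum(weights[s] * v for s, v in avail) / wsum
    return FusionResult(
        method="WDRS",
        scores=scores,
        ranks=_ranked(scores, descending=True),
        n_sources=n_sources,
        n_ops=n_ops,
    )


def _ndos_q_counted(ratios: list[float]) -> tuple[float, int]:
    """Order-statistic Q from sorted rank ratios, plus an operation count.

    Implements the recursion V_0 = 1,
    V_k = sum_{i=1..k} (-1)^(i-1) * (rho_{N-k+1}^i / i!) * V_{k-i},
    Q = N! * V_N, where rho_1 <= ... <= rho_N are the sorted rank ratios.
    Q is the probability that N independent uniform order statistics are
    componentwise at most (rho_1, ..., rho_N).
    """
    n = len(ratios)
    rho = sorted(ratios)
    v = [1.0] + [0.0] * n
    ops = 0
    for k in range(1, n + 1):
        r = rho[n - k]
        acc = 0.0
        term = 1.0
        for i in range(1, k + 1):
            term *= r / i  # rho^i / i!
            acc += (-1) ** (i - 1) * term * v[k - i]
            ops += 1
        v[k] = acc
    return math.factorial(n) * v[n], ops


def ndos_q(rank_positions: list[int], list_sizes: list[int]) -> float:
    """NDOS Q-value for one gene's ranks across its covering sources.

    ``rank_positions[i]`` is the gene's rank in source i, whose rank list
    holds ``list_sizes[i]`` genes; ranks are converted to ratios
    r_i / m_i before the order-statistic recursion.  Lower Q means the
    ranks are jointly more extreme than chance.
    """
    if not rank_positions:
        raise ValueError("empty rank input")
    if len(rank_positions) != len(list_sizes):
        raise ValueError("rank and list-size vectors differ in length")
    ratios = []
    for r, m in zip(rank_positions, list_sizes):
        if r < 1 or m < 1:
            raise ValueError("ranks and list sizes must be >= 1")
        if r > m:
            raise ValueError(f"rank {r} exceeds list size {m}")
        ratios.append(r / m)
    q, _ = _ndos_q_counted(ratios)
    return q


def ndos_combine(rank_lists: list[RankList]) -> FusionResult:
    """NDOS: per-gene Q over covering sources; ranking by Q, ascending."""
    if not rank_lists:
        raise ValueError("no rank lists to combine")
    nonempty = [rl for rl in rank_lists if len(rl) > 0]
    scores: dict[str, float] = {}
    n_sources: dict[str, int] = {}
    n_ops = 0
    for g in _union_genes(nonempty):
        ratios = [rl.ranks[g] / rl.m for rl in nonempty if g in rl]
        q, ops = _ndos_q_counted(ratios)
        scores[g] = q
        n_sources[g] = len(ratios)
        n_ops += ops
    return FusionResult(
        method="NDOS",
        scores=scores,
        ranks=_ranked(scores, descending=False),
        n_sources=n_sources,
        n_ops=n_ops,
    )


FUSION_METHODS = {"drs", "wdrs", "ndos"}


def combine(
    rank_lists: list[RankList],
    method: str,
    levels: int = DEFAULT_LEVELS,
    weights: dict[str, float] | None = None,
) -> FusionResult:
    """Dispatch to the requested fusion method (``drs``, ``wdrs``, ``ndos``)."""
    method = method.lower()
    if method == "drs":
        return drs_combine(rank_lists, levels=levels)
    if method == "wdrs":
        if weights is None:
            raise ValueError("WDRS requires per-source weights")
        return wdrs_combine(rank_lists, weights, levels=levels)
    if method == "ndos":
        return ndos_combine(rank_lists)
    raise ValueError(f"unknown fusion method {method!r}")
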