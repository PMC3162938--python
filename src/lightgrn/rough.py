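"""Stage I: assembly of the rough regulatory network.

Starting from a seed list of target genes and a table of predicted
TF->target binding pairs (promoter-scan output from an upstream database,
treated here as a black box), the target pool is closed iteratively: any TF
predicted to regulate a pool member joins the pool so that its own
regulators can be looked up, until no new gene is added.  The pool is then
restricted to genes actually measured on the array, every surviving
candidate pair is scored by the absolute Pearson correlation between the
replicate-averaged expression profiles of TF and target, and the pairs in
the lowest decile of |r| are deleted.  The survivors constitute the rough
network handed to the dynamic-model refinement stage; the deliberately mild
filter only removes highly unlikely regulations, so that plausible edges
are not lost before the rigorous Stage II pruning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .dataset import ExpressionDataset, TimeSeriesExpression, normalize_gene_id
from .errors import UndefinedCorrelationError

__all__ = [
    "CandidateEdge",
    "RoughNetwork",
    "build_target_pool",
    "restrict_to_measured",
    "pearson_correlation",
    "score_edges",
    "rank_filter_pairs",
    "build_rough_network",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateEdge:
    """A predicted TF->target pair, scored by |Pearson r| during Stage I."""

    tf: str
    target: str
    score: float | None = None
    retained: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "tf", normalize_gene_id(self.tf))
        object.__setattr__(self, "target", normalize_gene_id(self.target))
        if self.score is not None and not (0.0 <= self.score <= 1.0 + 1e-12):
            raise ValueError(f"edge score must be |r| in [0, 1], got {self.score}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.tf, self.target)


@dataclass(frozen=True)
class RoughNetwork:
    """Retained candidate edges plus the measured gene pool, per condition."""

    condition: str
    edges: tuple[CandidateEdge, ...]
    genes: frozenset[str]

    def regulator_sets(self) -> dict[str, set[str]]:
        """Per-target candidate regulator sets (retained edges grouped by target)."""
        sets: dict[str, set[str]] = {}
        for e in self.edges:
            sets.setdefault(e.target, set()).add(e.tf)
        return sets

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def _dedupe(edges: Iterable[CandidateEdge]) -> list[CandidateEdge]:
    seen: dict[tuple[str, str], CandidateEdge] = {}
    dupes = 0
    for e in edges:
        if e.pair in seen:
            dupes += 1
            continue
        seen[e.pair] = e
    if dupes:
        logger.warning("collapsed %d duplicate candidate pairs", dupes)
    return list(seen.values())


def build_target_pool(
    seed_genes: Iterable[str], predictions: Iterable[CandidateEdge]
) -> set[str]:
    """Least fixed point of 'add every TF predicted to regulate a pool member'.

    Starting from the seed targets, any TF with a predicted binding to a
    pool member is added (so that its own regulators can be chased in turn);
    iteration stops when a pass adds nothing.  Terminates on any finite
    prediction table, cycles included.
    """
    pool = {normalize_gene_id(g) for g in seed_genes}
    by_target: dict[str, set[str]] = {}
    for e in predictions:
        by_target.setdefault(e.target, set()).add(e.tf)
    frontier = set(pool)
    while frontier:
        added: set[str] = set()
        for gene in frontier:
            added |= by_target.get(gene, set()) - pool
        pool |= added
        frontier = added
    return pool


def restrict_to_measured(pool: Iterable[str], dataset: ExpressionDataset) -> set[str]:
    """Intersect the pool with the genes carrying expression profiles."""
    pool = {normalize_gene_id(g) for g in pool}
    measured = {g for g in pool if g in dataset}
    dropped = pool - measured
    if dropped:
        logger.info(
            "removed %d pool genes absent from the expression data", len(dropped)
        )
    if pool and not measured:
        logger.warning("no pool gene is present in the expression data")
    return measured


def pearson_correlation(a: TimeSeriesExpression, b: TimeSeriesExpression) -> float:
    """Sample Pearson correlation of two replicate-averaged profiles."""
    if not np.array_equal(a.times, b.times):
        raise ValueError(f"{a.gene!r} and {b.gene!r} are not on a shared time grid")
    x = a.mean_profile()
    y = b.mean_profile()
    if x.size < 3:
        raise ValueError("at least three time points are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in {a.gene!r} or {b.gene!r}: correlation undefined"
        )
    return float(stats.pearsonr(x, y).statistic)


def score_edges(
    edges: Iterable[CandidateEdge], dataset: ExpressionDataset
) -> list[CandidateEdge]:
    """Fill each edge's |Pearson r| score from the expression data.

    Edges whose correlation is undefined (a zero-variance profile) cannot be
    ranked; they are deleted here and logged, per the Stage I contract.
    """
    scored: list[CandidateEdge] = []
    for e in edges:
        try:
            r = pearson_correlation(dataset[e.tf], dataset[e.target])
        except UndefinedCorrelationError:
            logger.warning("edge %s->%s unscorable (zero variance); deleted", e.tf, e.target)
            continue
        scored.append(replace(e, score=abs(r)))
    return scored


def rank_filter_pairs(
    edges: Sequence[CandidateEdge],
    fraction: float = 0.10,
    condition: str = "",
    genes: Iterable[str] = (),
) -> RoughNetwork:
    """Delete the lowest-|r| decile of candidate pairs (global ranking).

    Edges are ranked by |r| over the whole candidate list; the
    ``floor(fraction * n)`` weakest are deleted.  Ties are broken by a
    stable sort on (|r| ascending, TF id, target id), so the outcome is
    deterministic.  With ``fraction = 0.10`` and fewer than ten edges the
    floor removes nothing — the filter is intentionally mild.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    edges = list(edges)
    for e in edges:
        if e.score is None:
            raise ValueError(f"unscored edge {e.tf}->{e.target}: score all edges first")
    n_delete = math.floor(fraction * len(edges))
    ranked = sorted(edges, key=lambda e: (e.score, e.tf, e.target))
    kept = ranked[n_delete:]
    gene_pool = frozenset(normalize_gene_id(g) for g in genes) or frozenset(
        g for e in kept for g in e.pair
    )
    return RoughNetwork(condition=condition, edges=tuple(kept), genes=gene_pool)


def build_rough_network(
    seed_genes: Iterable[str],
    predictions: Iterable[CandidateEdge],
    dataset: ExpressionDataset,
    fraction: float = 0.10,
    allow_self_edges: bool = False,
) -> RoughNetwork:
    """Run Stage I end to end for one condition.

    Pool closure over the prediction table, restriction to measured genes,
    |Pearson r| scoring and the global rank filter.  Self-edges (a TF
    predicted to bind its own promoter) are excluded by default because the
    dynamic model already carries a self-term through the degradation rate.
    """
    predictions = _dedupe(predictions)
    pool = build_target_pool(seed_genes, predictions)
    measured = restrict_to_measured(pool, dataset)
    usable = [
        e
        for e in predictions
        if e.tf in measured
        and e.target in measured
        and (allow_self_edges or e.tf != e.target)
    ]
    logger.info(
        "condition %s: pool %d -> measured %d; %d usable candidate pairs",
        dataset.condition, len(pool), len(measured), len(usable),
    )
    scored = score_edges(usable, dataset)
    net = rank_filter_pairs(scored, fraction, condition=dataset.condition, genes=measured)
    logger.info(
        "condition %s: rank filter kept %d of %d scored pairs",
        dataset.condition, net.n_edges, len(scored),
    )
    return net
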