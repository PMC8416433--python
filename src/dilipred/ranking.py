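"""Rank signatures and Kruskal-ordered Borda ("Kru-Bor") merging.

A drug's signature in one cell line is the full permutation of the gene
universe ordered by perturbation z-score (rank 1 = most upregulated). When a
drug was profiled in several cell lines, the per-line rankings are merged
into a single consensus signature by greedy agglomeration: repeatedly find
the pair of current signatures with the smallest Spearman footrule distance
and replace it with their Borda merge (per-gene mean rank, re-ranked),
until one ranking remains. Merging closest pairs first and collapsing nodes
reproduces Kruskal's minimum-spanning edge order on the complete distance
graph. The merged signature is finally truncated to its extreme sets — the
top-N most up- and bottom-N most down-ranked genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MERGED_SOURCE = "merged"


@dataclass(frozen=True)
class GeneRanking:
    """A full rank permutation of the gene universe for one drug.

    ``ranks`` is a Series indexed by gene id (kept sorted ascending), with
    values forming a permutation of 1..G; rank 1 = most upregulated.
    """

    drug_id: str
    source: str
    ranks: pd.Series

    def __post_init__(self):
        r = self.ranks
        if not r.index.is_monotonic_increasing:
            object.__setattr__(self, "ranks", r.sort_index())
            r = self.ranks
        vals = np.sort(r.to_numpy())
        if not np.array_equal(vals, np.arange(1, len(r) + 1)):
            raise ValueError("ranks must be a permutation of 1..G")

    @property
    def genes(self) -> pd.Index:
        return self.ranks.index

    def __len__(self) -> int:
        return len(self.ranks)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GeneRanking)
            and self.drug_id == other.drug_id
            and self.source == other.source
            and self.ranks.equals(other.ranks)
        )


@dataclass(frozen=True)
class ExtremeSet:
    """The top-N and bottom-N gene ids of a merged signature."""

    drug_id: str
    n: int
    top: frozenset[str]
    bottom: frozenset[str]

    def __post_init__(self):
        if len(self.top) != self.n or len(self.bottom) != self.n:
            raise ValueError("top and bottom must each contain exactly n genes")
        if self.top & self.bottom:
            raise ValueError("top and bottom sets overlap (need 2N <= G)")

    @property
    def members(self) -> frozenset[str]:
        return self.top | self.bottom


def _rerank(values: np.ndarray) -> np.ndarray:
    """Rank ascending values to a 1..G permutation; ties keep array order.

    The array is assumed aligned to genes sorted ascending by identifier, so
    the stable sort realizes the gene-identifier tie-break.
    """
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=np.int64)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def zscores_to_ranking(zvector: pd.Series, drug_id: str, source: str) -> GeneRanking:
    """Rank a z-score vector: rank 1 = largest z; z-ties broken by gene id."""
    if zvector.isna().any():
        bad = list(zvector.index[zvector.isna()][:5])
        raise ValueError(f"z-scores contain missing values (e.g. {bad}) for {drug_id}/{source}")
    z = zvector.sort_index()
    ranks = _rerank(-z.to_numpy(dtype=float))
    return GeneRanking(drug_id=drug_id, source=source, ranks=pd.Series(ranks, index=z.index))


def _check_universe(r1: GeneRanking, r2: GeneRanking) -> None:
    if not r1.genes.equals(r2.genes):
        raise ValueError(f"gene universes differ between {r1.source} and {r2.source}")


def footrule_distance(r1: GeneRanking, r2: GeneRanking) -> int:
    """Spearman footrule: sum over genes of |rank1 - rank2|."""
    _check_universe(r1, r2)
    return int(np.abs(r1.ranks.to_numpy() - r2.ranks.to_numpy()).sum())


def spearman_distance(r1: GeneRanking, r2: GeneRanking) -> int:
    """Sum of squared rank deviations (config alternative to the footrule)."""
    _check_universe(r1, r2)
    d = r1.ranks.to_numpy() - r2.ranks.to_numpy()
    return int((d * d).sum())


DISTANCES = {"footrule": footrule_distance, "spearman": spearman_distance}


def borda_merge(r1: GeneRanking, r2: GeneRanking) -> GeneRanking:
    """Borda merge: per-gene mean of the two ranks, re-ranked to a permutation.

    Mean ties are broken by ascending gene identifier; the operation is
    exactly commutative.
    """
    _check_universe(r1, r2)
    means = (r1.ranks.to_numpy() + r2.ranks.to_numpy()) / 2.0
    ranks = _rerank(means)
    return GeneRanking(
        drug_id=r1.drug_id,
        source=MERGED_SOURCE,
        ranks=pd.Series(ranks, index=r1.genes),
    )


def krubor_merge(rankings: list[GeneRanking], metric: str = "footrule") -> GeneRanking:
    """Merge a drug's per-cell-line rankings into one consensus signature.

    Greedy agglomeration in Kruskal order: repeatedly merge the pair of
    current signatures at minimal distance until one remains. When several
    pairs tie at the minimal distance, the pair with the lexicographically
    smallest (origin-index, origin-index) wins, where a merged node carries
    the smallest origin index among its constituents. A singleton list is
    returned unchanged.
    """
    if not rankings:
        raise ValueError("krubor_merge requires at least one ranking")
    dist = DISTANCES[metric]
    if len(rankings) == 1:
        return rankings[0]
    for r in rankings[1:]:
        _check_universe(rankings[0], r)

    nodes: list[tuple[int, GeneRanking]] = list(enumerate(rankings))
    while len(nodes) > 1:
        best = None
        for a in range(len(nodes)):
            for b in range(a + 1, len(nodes)):
                d = dist(nodes[a][1], nodes[b][1])
                key = (d, min(nodes[a][0], nodes[b][0]), max(nodes[a][0], nodes[b][0]))
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        merged = borda_merge(nodes[a][1], nodes[b][1])
        idx = min(nodes[a][0], nodes[b][0])
        nodes = [nodes[i] for i in range(len(nodes)) if i not in (a, b)] + [(idx, merged)]
    result = nodes[0][1]
    if result.source != MERGED_SOURCE:
        result = GeneRanking(result.drug_id, MERGED_SOURCE, result.ranks)
    return result


def extreme_sets(ranking: GeneRanking, n: int) -> ExtremeSet:
    """Top-N (ranks 1..N) and bottom-N (ranks G-N+1..G) genes of a signature."""
    g = len(ranking)
    if 2 * n > g:
        raise ValueError(f"extreme half-size {n} too large for universe of {g} genes")
    r = ranking.ranks
    top = frozenset(r.index[r.to_numpy() <= n])
    bottom = frozenset(r.index[r.to_numpy() > g - n])
    return ExtremeSet(drug_id=ranking.drug_id, n=n, top=top, bottom=bottom)
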