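"""Binary extreme-set membership features and Fisher's-exact gene screening.

A drug's merged signature is reduced to a boolean fingerprint: gene g is 1
for drug d iff g lies in the top-N or bottom-N of d's ranking. Each gene
column is then crossed with the binary DILI label in a 2x2 table and tested
with a two-sided Fisher's exact test; genes with p below the significance
threshold (default 0.01, no multiple-testing adjustment) become the model's
predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.stats

from dilipred.prep import FeatureMatrix
from dilipred.ranking import ExtremeSet

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Gene-screening parameters: raw two-sided p-value cutoff."""

    alpha: float = 0.01

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def membership_matrix(
    extreme: dict[str, ExtremeSet], universe: list[str] | pd.Index
) -> pd.DataFrame:
    """Boolean drugs x genes matrix: cell true iff gene in top ∪ bottom of drug.

    Drugs mapped to None (no signature, e.g. zero cell-line coverage) are
    excluded and logged. Row sums equal 2N for every included drug.
    """
    universe = pd.Index(universe)
    rows = {}
    for drug, es in extreme.items():
        if es is None:
            log.warning("drug %s has no signature; excluded from membership matrix", drug)
            continue
        members = es.members
        if not members <= set(universe):
            raise ValueError(f"extreme set of {drug} contains genes outside the universe")
        rows[drug] = universe.isin(members)
    m = pd.DataFrame.from_dict(rows, orient="index", dtype=bool)
    m.columns = universe
    m.index.name = "drug"
    return m


@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    return float(scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Counts are (member ∧ positive, member ∧ negative, nonmember ∧ positive,
    nonmember ∧ negative). The p-value is the sum of hypergeometric
    probabilities, at fixed margins, of all tables no more probable than the
    observed one. Any zero margin yields p = 1 by convention.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    return _fisher_cached(a, b, c, d)


def select_genes(
    membership: pd.DataFrame, labels: pd.Series, cfg: SelectionConfig = SelectionConfig()
) -> list[tuple[str, float]]:
    """Genes whose extreme-set membership associates with the DILI label.

    Returns (gene, p) pairs with p < alpha, sorted ascending by p then by
    gene identifier. Genes with constant membership across drugs carry no
    information and are assigned p = 1 (never selected). If the labels
    contain a single class, an empty selection is returned with a warning.
    """
    labels = labels.reindex(membership.index)
    if labels.isna().any():
        raise ValueError("labels do not cover all drugs in the membership matrix")
    y = labels.to_numpy().astype(bool)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        log.warning("labels contain a single class; no genes can be selected")
        return []

    m = membership.to_numpy(dtype=bool)
    a = m[y].sum(axis=0)  # member & positive
    member_total = m.sum(axis=0)
    b = member_total - a  # member & negative

    selected = []
    for j, gene in enumerate(membership.columns):
        if member_total[j] == 0 or member_total[j] == len(y):
            continue  # constant membership: p = 1 by policy
        p = fisher_exact_2x2(int(a[j]), int(b[j]), n_pos - int(a[j]), n_neg - int(b[j]))
        if p < cfg.alpha:
            selected.append((gene, p))
    selected.sort(key=lambda t: (t[1], t[0]))
    return selected


def build_expression_features(
    membership: pd.DataFrame,
    selected: list[tuple[str, float]] | list[str],
    labels: pd.Series,
    name: str = "expression",
) -> FeatureMatrix:
    """Restrict the membership matrix to the selected genes as 0/1 features."""
    genes = [s[0] if isinstance(s, tuple) else s for s in selected]
    if not genes:
        raise ValueError(
            "empty gene selection: relax alpha or change the extreme-set size N"
        )
    missing = set(genes) - set(membership.columns)
    if missing:
        raise ValueError(f"selected genes not in membership matrix: {sorted(missing)[:5]}")
    x = membership[genes].astype(float)
    return FeatureMatrix(
        X=x,
        y=labels.reindex(membership.index),
        name=name,
        log=[f"selected {len(genes)} genes by Fisher's exact test"],
    )
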