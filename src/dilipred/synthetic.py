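"""Synthetic study generator.

Emulates the structure of a multi-source drug-safety challenge dataset:
several cell lines with L1000-style per-drug perturbation z-scores and only
partial drug coverage (a fraction of drugs measured in every line, the rest
hit-or-miss, some drugs with no expression at all); imbalanced binary DILI
labels under several classification schemes; and per-drug tabular feature
sets standing in for adverse-event reporting rates, 2D molecular descriptors
and concentration-response toxicity ranks — with planted informative genes
and features, missing cells, and highly correlated column pairs so every
downstream filter has real work to do.

All randomness flows from one root seed through named substreams
(coverage / labels / expression / tabular), so each piece can be regenerated
independently and the whole study is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dilipred import io

# Substream indices under the root SeedSequence; fixed so that regenerating
# one component never perturbs the others.
_STREAMS = {"coverage": 0, "labels": 1, "expression": 2, "tabular": 3}

#: Names of the binary classification schemes the generator produces.
#: "clinical" carries the planted signal (like a severity-score label);
#: "random_control" is independent of everything (negative control);
#: "threshold_control" is a deterministic function of one designated tabular
#: feature (positive control, like molecular weight > 320 g/mol).
LABEL_SCHEMES = ("clinical", "random_control", "threshold_control")

THRESHOLD_FEATURE = "mw_like"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study.

    Defaults are a desk-scale study: 150 drugs, 4 cell lines, 800 genes,
    with the clinical class imbalanced at the 96:326 ratio of the real
    severity-score label.
    """

    n_drugs: int = 150
    n_genes: int = 800
    n_cell_lines: int = 4
    #: per-cell-line probability that a non-"core" drug is tested in that line
    coverage_prob: float = 0.7
    #: fraction of drugs forced to be tested in every line (the "core" set)
    all_lines_fraction: float = 0.4
    n_informative_genes: int = 40
    #: z-score shift applied to informative genes in DILI-positive drugs
    gene_effect: float = 2.0
    n_tabular_features: int = 20
    n_informative_features: int = 5
    #: mean shift of informative tabular features in positives
    feature_effect: float = 1.0
    #: fraction of positive drugs in the clinical class
    pos_fraction: float = 96 / 422
    #: fraction of missing cells in the tox-like table
    missing_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        for name in ("n_drugs", "n_genes", "n_cell_lines", "n_informative_genes",
                     "n_tabular_features", "n_informative_features"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.pos_fraction < 1:
            raise ValueError("pos_fraction must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes exceeds n_genes")
        if self.n_informative_features > self.n_tabular_features:
            raise ValueError("n_informative_features exceeds n_tabular_features")
        if not 0 <= self.coverage_prob <= 1 or not 0 <= self.all_lines_fraction <= 1:
            raise ValueError("coverage probabilities must be in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream generator rooted at ``seed``."""
        ss = np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        return np.random.default_rng(ss)

    @property
    def drugs(self) -> list[str]:
        width = len(str(self.n_drugs - 1))
        return [f"drug{str(i).zfill(width)}" for i in range(self.n_drugs)]

    @property
    def genes(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{str(i).zfill(width)}" for i in range(self.n_genes)]

    @property
    def cell_lines(self) -> list[str]:
        return [f"CL{i}" for i in range(self.n_cell_lines)]


@dataclass
class SimulatedStudy:
    """One generated study: expression, labels, tabular sets and ground truth."""

    config: SimConfig
    coverage: pd.DataFrame  # drugs x cell lines, bool
    #: cell line -> genes x covered-drugs z-score matrix
    expression: dict[str, pd.DataFrame]
    #: drugs x label-scheme 0/1 matrix
    labels: pd.DataFrame
    #: table name -> drugs x features numeric DataFrame
    tabular: dict[str, pd.DataFrame]
    #: ground truth for recovery tests
    truth: dict = field(default_factory=dict)

    @property
    def uncovered_drugs(self) -> list[str]:
        """Drugs with no expression in any cell line (excluded from expression modeling)."""
        return list(self.coverage.index[~self.coverage.any(axis=1)])

    def write(self, outdir: str | Path, expression_format: str = "gct") -> None:
        """Write the study to disk: GCT/TSV expression, CSV labels and tables, JSON truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for line, mat in self.expression.items():
            if expression_format == "gct":
                io.write_gct(mat, outdir / f"expression_{line}.gct")
            else:
                io.write_long_tsv(mat, outdir / f"expression_{line}.tsv")
        self.labels.to_csv(outdir / "labels.csv")
        self.coverage.to_csv(outdir / "coverage.csv")
        for name, table in self.tabular.items():
            table.to_csv(outdir / f"tabular_{name}.csv")
        io.write_json(self.truth, outdir / "truth.json")


def simulate_coverage(config: SimConfig) -> pd.DataFrame:
    """Drug x cell-line boolean matrix of which drug was tested where.

    A deterministic count ``floor(all_lines_fraction * n_drugs)`` of drugs
    (chosen at random) is tested in every line; the rest are covered per line
    with probability ``coverage_prob``. Zero-coverage drugs are permitted.
    """
    rng = config.rng("coverage")
    n = config.n_drugs
    core_n = int(math.floor(config.all_lines_fraction * n + 1e-9))
    core = rng.choice(n, size=core_n, replace=False)
    cov = rng.random((n, config.n_cell_lines)) < config.coverage_prob
    cov[core, :] = True
    return pd.DataFrame(cov, index=config.drugs, columns=config.cell_lines)


def simulate_labels(config: SimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Binary labels under each scheme, plus the designated threshold feature.

    Positive counts are allocated deterministically (``floor(pos_fraction*n)``
    for the clinical class, ``floor(n/2)`` for the random control) and then
    shuffled by seed, so class counts never vary between runs.

    Returns ``(labels, threshold_feature)``; the feature is a per-drug
    molecular-weight-like value whose median split defines the
    threshold-control class, and is later embedded verbatim in one tabular set.
    """
    rng = config.rng("labels")
    n = config.n_drugs
    drugs = config.drugs

    def allocate(n_pos: int) -> np.ndarray:
        y = np.zeros(n, dtype=int)
        y[:n_pos] = 1
        return rng.permutation(y)

    clinical = allocate(int(math.floor(config.pos_fraction * n + 1e-9)))
    random_control = allocate(n // 2)

    # Threshold feature: lognormal-ish positive values; positives = above median.
    mw = pd.Series(np.exp(rng.normal(5.8, 0.4, size=n)), index=drugs, name=THRESHOLD_FEATURE)
    threshold_control = (mw > mw.median()).astype(int).to_numpy()

    labels = pd.DataFrame(
        {"clinical": clinical, "random_control": random_control,
         "threshold_control": threshold_control},
        index=drugs,
    )
    labels.index.name = "drug"
    return labels, mw


def simulate_expression(
    config: SimConfig, coverage: pd.DataFrame, labels: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Per-cell-line genes x drugs z-score matrices plus the gene ground truth.

    Background z-scores are standard normal. Each informative gene is shifted
    by ``±gene_effect`` (sign fixed per gene, half up and half down) in every
    covered cell line of each clinical-positive drug, so both the top and the
    bottom of a ranked signature carry signal. Untested drug/line pairs are
    simply absent (columns omitted).
    """
    if not coverage.index.equals(labels.index):
        raise ValueError("coverage and labels were built from different drug sets")
    rng = config.rng("expression")
    genes = np.array(config.genes)
    info_idx = rng.choice(config.n_genes, size=config.n_informative_genes, replace=False)
    info_idx.sort()
    signs = np.ones(config.n_informative_genes)
    signs[1::2] = -1.0  # alternate up/down: half in the top, half in the bottom
    positive = labels["clinical"].to_numpy().astype(bool)

    expression: dict[str, pd.DataFrame] = {}
    for line in coverage.columns:
        tested = coverage[line].to_numpy()
        drug_ids = coverage.index[tested]
        z = rng.normal(size=(config.n_genes, tested.sum()))
        pos_here = positive[tested]
        z[np.ix_(info_idx, np.flatnonzero(pos_here))] += (
            config.gene_effect * signs[:, None]
        )
        expression[line] = pd.DataFrame(z, index=genes, columns=drug_ids)

    truth = {
        "informative_genes": [genes[i] for i in info_idx],
        "gene_signs": {genes[i]: int(s) for i, s in zip(info_idx, signs)},
    }
    return expression, truth


def simulate_tabular(
    config: SimConfig, labels: pd.DataFrame, threshold_feature: pd.Series | None = None
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Named per-drug numeric feature tables plus the feature ground truth.

    Three tables mimic the real predictor families:

    * ``faers_like`` — reporting-percentage columns, including the four
      gender-stratified event-count columns the ratio derivation consumes;
    * ``mold2_like`` — descriptor-style columns, carrying the designated
      threshold feature verbatim;
    * ``tox21_like`` — toxicity-rank-style columns with missing cells at
      ``missing_rate``.

    Every table gets ``n_informative_features`` columns shifted by
    ``feature_effect`` in clinical positives, and one planted near-duplicate
    column pair (|r| > 0.82) for the correlation filter to find.
    """
    rng = config.rng("tabular")
    n = config.n_drugs
    drugs = config.drugs
    positive = labels["clinical"].to_numpy().astype(bool)
    k = config.n_tabular_features
    k_info = config.n_informative_features
    truth: dict[str, list[str]] = {}

    def base_table(prefix: str) -> pd.DataFrame:
        cols = [f"{prefix}_f{str(j).zfill(2)}" for j in range(k)]
        x = rng.normal(size=(n, k))
        x[positive, :k_info] += config.feature_effect
        df = pd.DataFrame(x, index=drugs, columns=cols)
        df.index.name = "drug"
        # planted correlated pair: last column becomes a noisy copy of the first
        df[cols[-1]] = df[cols[0]] * 1.0 + rng.normal(scale=0.25, size=n)
        truth[prefix] = cols[:k_info]
        return df

    faers = base_table("faers")
    # gender-stratified report percentages feeding derive_reporting_ratios
    for gender in ("male", "female"):
        all_ev = rng.uniform(10, 100, size=n)
        dili_ev = all_ev * rng.beta(2, 8, size=n)
        dili_ev[~positive] *= 0.5  # positives report proportionally more DILI events
        faers[f"all_events_{gender}"] = all_ev
        faers[f"dili_events_{gender}"] = dili_ev

    mold2 = base_table("mold2")
    if threshold_feature is not None:
        mold2[THRESHOLD_FEATURE] = threshold_feature.reindex(drugs)

    tox21 = base_table("tox21")
    if config.missing_rate > 0:
        mask = rng.random(tox21.shape) < config.missing_rate
        tox21 = tox21.mask(mask)

    tables = {"faers_like": faers, "mold2_like": mold2, "tox21_like": tox21}
    truth_out = {
        "informative_features": {
            "faers_like": truth["faers"],
            "mold2_like": truth["mold2"],
            "tox21_like": truth["tox21"],
        },
        "threshold_feature": THRESHOLD_FEATURE,
        "correlated_pairs": {
            name: [t.columns[0], t.columns[k - 1]] for name, t in
            (("faers_like", faers), ("mold2_like", mold2), ("tox21_like", tox21))
        },
    }
    return tables, truth_out


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a full study (coverage, labels, expression, tabular, truth)."""
    coverage = simulate_coverage(config)
    labels, mw = simulate_labels(config)
    expression, gene_truth = simulate_expression(config, coverage, labels)
    tabular, feature_truth = simulate_tabular(config, labels, mw)
    truth = {**gene_truth, **feature_truth}
    return SimulatedStudy(
        config=config,
        coverage=coverage,
        expression=expression,
        labels=labels,
        tabular=tabular,
        truth=truth,
    )
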