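"""Tabular predictor preprocessing and class-imbalance resampling.

The fixed pipeline order is: missing-row removal → zero-variance filter →
correlation filter → derived reporting ratios → (resampling) →
standardization with training-set statistics. Every transform appends to the
FeatureMatrix's provenance log.

Resamplers: random minority upsampling, SMOTE (synthetic points interpolated
between nearest minority neighbors) and a ROSE-style smoothed bootstrap
(bootstrap draws perturbed with Gaussian kernel noise at a Silverman-style
bandwidth). All resamplers append rows and never modify originals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Per-drug numeric features with binary labels and a provenance log."""

    X: pd.DataFrame
    y: pd.Series
    name: str = "features"
    log: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.X.index.has_duplicates:
            raise ValueError("duplicate drug ids in feature matrix")
        if not self.X.index.equals(self.y.index):
            self.y = self.y.reindex(self.X.index)
        if self.y.isna().any():
            raise ValueError("labels missing for some drugs")

    def with_update(self, X=None, y=None, entry: str | None = None) -> "FeatureMatrix":
        new = replace(
            self,
            X=self.X if X is None else X,
            y=self.y if y is None else y,
            log=list(self.log) + ([entry] if entry else []),
        )
        return new

    @property
    def n_pos(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n_neg(self) -> int:
        return int((self.y == 0).sum())


@dataclass(frozen=True)
class ResampleConfig:
    """How to correct class imbalance before fitting."""

    method: str = "none"  # none | upsample | smote | rose
    k_neighbors: int = 5
    seed: int = 0
    #: multiplier on the ROSE kernel bandwidth (0 = plain bootstrap)
    shrink: float = 1.0

    def __post_init__(self):
        if self.method not in ("none", "upsample", "smote", "rose"):
            raise ValueError(f"unknown resampling method {self.method!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def drop_missing_rows(fm: FeatureMatrix) -> FeatureMatrix:
    """Remove rows containing any missing cell (no imputation is attempted)."""
    keep = ~fm.X.isna().any(axis=1)
    n_drop = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all rows contain missing values")
    return fm.with_update(
        X=fm.X.loc[keep], y=fm.y.loc[keep], entry=f"dropped {n_drop} rows with missing values"
    )


def drop_zero_variance(fm: FeatureMatrix) -> FeatureMatrix:
    """Remove columns with zero sample variance."""
    variances = fm.X.var(axis=0, ddof=1)
    keep = variances > 0
    dropped = list(fm.X.columns[~keep])
    return fm.with_update(
        X=fm.X.loc[:, keep], entry=f"dropped {len(dropped)} zero-variance columns: {dropped}"
    )


def correlation_filter(fm: FeatureMatrix, cutoff: float = 0.82) -> FeatureMatrix:
    """Greedy removal of highly correlated columns.

    While any column pair has |Pearson r| > cutoff, take the worst pair
    (largest |r|; ties by column-name order) and drop the member with the
    larger mean absolute correlation to all remaining columns (ties: drop the
    lexicographically larger name).
    """
    if len(fm.X) < 2:
        raise ValueError("correlation filter needs at least 2 rows")
    x = fm.X.copy()
    dropped: list[str] = []
    while x.shape[1] >= 2:
        corr = x.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        if corr.loc[worst] <= cutoff:
            break
        c1, c2 = sorted(worst)
        mean1 = corr[c1].drop([c1, c2]).mean() if x.shape[1] > 2 else 0.0
        mean2 = corr[c2].drop([c1, c2]).mean() if x.shape[1] > 2 else 0.0
        victim = c2 if mean2 >= mean1 else c1
        x = x.drop(columns=[victim])
        dropped.append(victim)
    return fm.with_update(
        X=x, entry=f"correlation filter at {cutoff}: dropped {len(dropped)} columns: {dropped}"
    )


def standardize(train_fm: FeatureMatrix, apply_fm: FeatureMatrix) -> FeatureMatrix:
    """Scale apply_fm columns to zero mean / unit sd using train_fm statistics."""
    means = train_fm.X.mean(axis=0)
    sds = train_fm.X.std(axis=0, ddof=1)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ValueError(f"zero-sd columns (run drop_zero_variance first): {bad}")
    x = (apply_fm.X[train_fm.X.columns] - means) / sds
    return apply_fm.with_update(
        X=x, entry=f"standardized with training statistics of {train_fm.name!r}"
    )


DEFAULT_RATIO_MAPPING = {
    "male": ("dili_events_male", "all_events_male"),
    "female": ("dili_events_female", "all_events_female"),
}


def derive_reporting_ratios(
    fm: FeatureMatrix, mapping: dict[str, tuple[str, str]] | None = None
) -> FeatureMatrix:
    """Add per-gender DILI reporting ratios (DILI-event reports / all reports).

    ``mapping`` names, per gender, the (DILI-event, all-event) report columns.
    0/0 cells become 0 with a log entry.
    """
    mapping = mapping or DEFAULT_RATIO_MAPPING
    x = fm.X.copy()
    zeros = 0
    for gender, (dili_col, all_col) in mapping.items():
        for col in (dili_col, all_col):
            if col not in x.columns:
                raise ValueError(
                    f"column {col!r} required for the {gender} reporting ratio is absent"
                )
        denom = x[all_col]
        ratio = x[dili_col] / denom
        zero_over_zero = (x[dili_col] == 0) & (denom == 0)
        zeros += int(zero_over_zero.sum())
        ratio[zero_over_zero] = 0.0
        x[f"{gender}_ratio"] = ratio
    entry = f"derived reporting ratios for {sorted(mapping)}"
    if zeros:
        entry += f" ({zeros} zero-over-zero cells set to 0)"
    return fm.with_update(X=x, entry=entry)


def _classes(fm: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    y = fm.y.to_numpy()
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("resampling requires both classes present")
    return pos, neg


def _append_rows(fm: FeatureMatrix, rows: np.ndarray, label: int, tag: str, entry: str) -> FeatureMatrix:
    new_idx = [f"{tag}{i}" for i in range(len(rows))]
    x_new = pd.DataFrame(rows, index=new_idx, columns=fm.X.columns)
    y_new = pd.Series(label, index=new_idx)
    return FeatureMatrix(
        X=pd.concat([fm.X, x_new]),
        y=pd.concat([fm.y, y_new]),
        name=fm.name,
        log=list(fm.log) + [entry],
    )


def upsample_minority(fm: FeatureMatrix, cfg: ResampleConfig) -> FeatureMatrix:
    """Resample minority rows with replacement until class counts are equal."""
    pos, neg = _classes(fm)
    minority, label = (pos, 1) if len(pos) < len(neg) else (neg, 0)
    n_add = abs(len(pos) - len(neg))
    if n_add == 0:
        return fm.with_update(entry="upsample: classes already balanced")
    rng = np.random.default_rng(cfg.seed)
    picks = rng.choice(minority, size=n_add, replace=True)
    rows = fm.X.to_numpy()[picks]
    return _append_rows(fm, rows, label, "up", f"upsampled minority by {n_add} rows")


def smote(fm: FeatureMatrix, cfg: ResampleConfig) -> FeatureMatrix:
    """SMOTE: synthetic minority rows interpolated toward k-nearest neighbors.

    Each synthetic row is x_i + u * (x_nn - x_i) with u ~ Uniform(0, 1) and
    x_nn one of the k nearest minority neighbors of x_i (Euclidean). Classes
    end exactly balanced. A minority class of one row is an error; if the
    minority count is <= k_neighbors, k is reduced with a warning.
    """
    pos, neg = _classes(fm)
    minority, label = (pos, 1) if len(pos) < len(neg) else (neg, 0)
    n_add = abs(len(pos) - len(neg))
    if n_add == 0:
        return fm.with_update(entry="smote: classes already balanced")
    if len(minority) == 1:
        raise ValueError("SMOTE needs at least 2 minority rows")
    k = cfg.k_neighbors
    if len(minority) <= k:
        k = len(minority) - 1
        log.warning("minority count %d <= k_neighbors; reducing k to %d", len(minority), k)
    x_min = fm.X.to_numpy()[minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x_min)
    _, neighbor_idx = nn.kneighbors(x_min)  # column 0 is the point itself
    rng = np.random.default_rng(cfg.seed)
    base = rng.integers(0, len(minority), size=n_add)
    pick = rng.integers(1, k + 1, size=n_add)
    u = rng.random(n_add)
    x_nn = x_min[neighbor_idx[base, pick]]
    rows = x_min[base] + u[:, None] * (x_nn - x_min[base])
    return _append_rows(fm, rows, label, "sm", f"SMOTE added {n_add} synthetic rows (k={k})")


def rose_bandwidth(x_class: np.ndarray) -> np.ndarray:
    """Silverman-style per-feature kernel bandwidth for one class.

    h_j = (4 / ((d + 2) n))^(1 / (d + 4)) * sigma_j, with d the feature count
    and n the class size; sigma_j the per-feature sample sd within the class.
    """
    n, d = x_class.shape
    factor = (4.0 / ((d + 2) * n)) ** (1.0 / (d + 4))
    return factor * x_class.std(axis=0, ddof=1)


def rose_resample(fm: FeatureMatrix, cfg: ResampleConfig, n_out: int | None = None) -> FeatureMatrix:
    """ROSE-style smoothed bootstrap balancing the classes in expectation.

    Each output row draws its class with probability 1/2, a seed row
    uniformly from that class, and adds N(0, h_j^2) noise per feature, where
    h_j is a Silverman-style bandwidth scaled by ``cfg.shrink`` (0 gives a
    plain bootstrap). The output consists purely of smoothed-bootstrap draws
    (size ``n_out``, default the input size); the input FeatureMatrix is
    never mutated.
    """
    pos, neg = _classes(fm)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("ROSE needs at least 2 rows per class")
    n_out = n_out if n_out is not None else len(fm.X)
    rng = np.random.default_rng(cfg.seed)
    x = fm.X.to_numpy()
    h = {1: cfg.shrink * rose_bandwidth(x[pos]), 0: cfg.shrink * rose_bandwidth(x[neg])}
    cls = rng.integers(0, 2, size=n_out)  # 1 = positive with prob 1/2
    rows = np.empty((n_out, x.shape[1]))
    for label, members in ((1, pos), (0, neg)):
        idx = np.flatnonzero(cls == label)
        seeds = rng.choice(members, size=len(idx), replace=True)
        rows[idx] = x[seeds] + rng.normal(size=(len(idx), x.shape[1])) * h[label]
    out_x = pd.DataFrame(rows, index=[f"rose{i}" for i in range(n_out)], columns=fm.X.columns)
    out_y = pd.Series(cls, index=out_x.index)
    return FeatureMatrix(
        X=out_x, y=out_y, name=fm.name,
        log=list(fm.log) + [f"ROSE smoothed bootstrap, {n_out} rows, shrink={cfg.shrink}"],
    )


def resample(fm: FeatureMatrix, cfg: ResampleConfig) -> FeatureMatrix:
    """Dispatch on cfg.method; 'none' passes through with a log entry."""
    if cfg.method == "none":
        return fm.with_update(entry="no resampling")
    if cfg.method == "upsample":
        return upsample_minority(fm, cfg)
    if cfg.method == "smote":
        return smote(fm, cfg)
    return rose_resample(fm, cfg)
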