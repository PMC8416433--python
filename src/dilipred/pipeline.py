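"""End-to-end orchestration of the DILI analysis.

One run: simulate (or load) a study; make one stratified train/test split
per DILI class; run the expression branch (Kru-Bor merge → extreme sets →
membership → Fisher selection → classifiers) and the tabular branches
(prep chain → each resampling setting → classifiers); rank models by
cross-validated AUC; combine the top k by hard, soft and weighted voting;
and emit a performance table (TSV rounded 2-dec half-up, JSON unrounded)
plus a run manifest tracing every result row to its seeds and filters.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from dilipred import prep
from dilipred.metrics import EvalReport, reports_to_frame
from dilipred.modeling import (
    ALGORITHMS,
    CVConfig,
    TrainedModel,
    predict_proba,
    random_search_cv,
    rank_models,
)
from dilipred.prep import FeatureMatrix, ResampleConfig
from dilipred.ranking import extreme_sets, krubor_merge, zscores_to_ranking
from dilipred.selection import SelectionConfig, build_expression_features, membership_matrix, select_genes
from dilipred.synthetic import SimConfig, SimulatedStudy, simulate_study
from dilipred.voting import EnsembleInput, hard_vote, soft_vote, weighted_vote

log = logging.getLogger(__name__)

#: desk-scale default algorithm panel: one representative per family (linear,
#: discriminant, tree, Bayes, kernel) keeps a full pipeline run in the minutes
#: range; the full registry — random forest and neural net included — is
#: available via config
DEFAULT_ALGORITHMS = ["logistic_regression", "lda", "decision_tree", "naive_bayes", "svm_rbf"]


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    dili_classes: list[str] = field(default_factory=lambda: ["clinical"])
    signature_sizes: list[int] = field(default_factory=lambda: [50, 100])
    alpha: float = 0.01
    cv: CVConfig = field(default_factory=lambda: CVConfig(folds=5, repeats=2, n_candidates=3))
    algorithms: list[str] = field(default_factory=lambda: list(DEFAULT_ALGORITHMS))
    resample_methods: list[str] = field(default_factory=lambda: ["none", "upsample", "smote", "rose"])
    corr_cutoff: float = 0.82
    top_k: int = 3
    test_fraction: float = 0.3
    #: resample before (True, the leakage-prone protocol) or within (False) CV folds
    leaky: bool = False
    #: run Fisher selection on all drugs instead of the training split only
    whole_data_selection: bool = False
    #: additionally run each cell line unmerged through the expression chain
    per_cell_line: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.signature_sizes:
            raise ValueError("signature_sizes must be non-empty")
        if self.top_k < 2:
            raise ValueError("top_k must be >= 2 for voting")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise ValueError(f"unknown algorithms: {sorted(unknown)}")


@dataclass
class PipelineResult:
    reports: list[EvalReport]
    models: list[TrainedModel]
    votes: dict[tuple[str, str], pd.Series]  # (dili_class, method) -> labels
    manifest: dict

    def report_frame(self, rounded: bool = True) -> pd.DataFrame:
        return reports_to_frame(self.reports, rounded=rounded)


def _derive_seed(root: int, *names) -> int:
    """Stable per-stage seed below 2**31."""
    tag = "/".join(str(n) for n in names)
    return (root * 1_000_003 + zlib.crc32(tag.encode())) % (2**31)


def split_drugs(
    labels: pd.Series, test_fraction: float, seed: int
) -> tuple[pd.Index, pd.Index]:
    """One stratified train/test split of the drug list."""
    train, test = train_test_split(
        labels.index,
        test_size=test_fraction,
        stratify=labels.to_numpy(),
        random_state=seed % (2**31),
    )
    return pd.Index(train), pd.Index(test)


def merge_signatures(study: SimulatedStudy, metric: str = "footrule") -> dict:
    """Kru-Bor-merge each covered drug's per-cell-line rankings.

    Drugs with zero coverage are excluded (logged); the result maps drug id
    to its merged GeneRanking.
    """
    merged = {}
    excluded = study.uncovered_drugs
    if excluded:
        log.info("%d drugs have no expression in any cell line; excluded", len(excluded))
    for drug in study.coverage.index:
        rankings = [
            zscores_to_ranking(study.expression[line][drug], drug, line)
            for line in study.coverage.columns
            if study.coverage.at[drug, line]
        ]
        if rankings:
            merged[drug] = krubor_merge(rankings, metric=metric)
    return merged


def _train_and_evaluate(
    train_fm: FeatureMatrix,
    test_fm: FeatureMatrix,
    dataset: str,
    dili_class: str,
    cfg: PipelineConfig,
    rs: ResampleConfig,
) -> tuple[list[TrainedModel], list[EvalReport]]:
    models, reports = [], []
    for alg in cfg.algorithms:
        cv = CVConfig(
            folds=cfg.cv.folds,
            repeats=cfg.cv.repeats,
            n_candidates=cfg.cv.n_candidates,
            seed=_derive_seed(cfg.seed, dataset, dili_class, alg),
        )
        model = random_search_cv(train_fm, alg, cv=cv, rs=rs, leaky=cfg.leaky)
        model.dataset = dataset
        model.dili_class = dili_class
        probs = predict_proba(model, test_fm.X)
        pred = (probs["p_positive"] > probs["p_negative"]).astype(int)
        reports.append(
            EvalReport.from_predictions(
                dataset, dili_class, alg, test_fm.y, pred, probs["p_positive"]
            )
        )
        models.append(model)
    return models, reports


def run_expression_branch(
    study: SimulatedStudy,
    dili_class: str,
    train_idx: pd.Index,
    test_idx: pd.Index,
    cfg: PipelineConfig,
    merged: dict | None = None,
) -> tuple[list[TrainedModel], list[EvalReport], dict]:
    """Merge → extreme sets → membership → Fisher selection → classifiers.

    Returns models, test-set reports, and per-N selection info (selected
    gene lists for recovery checks). Signature sizes exceeding half the
    universe, and sizes yielding an empty selection, are skipped with a
    warning.
    """
    labels = study.labels[dili_class]
    merged = merged if merged is not None else merge_signatures(study)
    universe = study.expression[next(iter(study.expression))].index
    models, reports, selections = [], [], {}
    for n in cfg.signature_sizes:
        if 2 * n > len(universe):
            log.warning("signature size N=%d exceeds half the universe; skipped", n)
            continue
        sets = {drug: extreme_sets(r, n) for drug, r in merged.items()}
        m = membership_matrix(sets, universe)
        sel_drugs = m.index if cfg.whole_data_selection else m.index.intersection(train_idx)
        selected = select_genes(
            m.loc[sel_drugs], labels.loc[sel_drugs], SelectionConfig(alpha=cfg.alpha)
        )
        selections[n] = selected
        if not selected:
            log.warning("empty gene selection at N=%d; skipped", n)
            continue
        dataset = f"expression_N{n}"
        fm_all = build_expression_features(m, selected, labels.loc[m.index], name=dataset)
        tr = m.index.intersection(train_idx)
        te = m.index.intersection(test_idx)
        train_fm = FeatureMatrix(X=fm_all.X.loc[tr], y=fm_all.y.loc[tr], name=dataset)
        test_fm = FeatureMatrix(X=fm_all.X.loc[te], y=fm_all.y.loc[te], name=dataset)
        mods, reps = _train_and_evaluate(
            train_fm, test_fm, dataset, dili_class, cfg, ResampleConfig(method="none")
        )
        models += mods
        reports += reps
    return models, reports, selections


def run_per_cell_line(
    study: SimulatedStudy,
    dili_class: str,
    train_idx: pd.Index,
    test_idx: pd.Index,
    cfg: PipelineConfig,
) -> tuple[list[TrainedModel], list[EvalReport]]:
    """Unmerged mode: the expression chain on each single cell line's drugs."""
    labels = study.labels[dili_class]
    models, reports = [], []
    for line, expr in study.expression.items():
        universe = expr.index
        rankings = {
            drug: zscores_to_ranking(expr[drug], drug, line) for drug in expr.columns
        }
        for n in cfg.signature_sizes:
            if 2 * n > len(universe):
                continue
            sets = {d: extreme_sets(r, n) for d, r in rankings.items()}
            m = membership_matrix(sets, universe)
            tr = m.index.intersection(train_idx)
            te = m.index.intersection(test_idx)
            y_tr = labels.loc[tr]
            if y_tr.nunique() < 2 or min((y_tr == 1).sum(), (y_tr == 0).sum()) < cfg.cv.folds:
                continue
            selected = select_genes(m.loc[tr], y_tr, SelectionConfig(alpha=cfg.alpha))
            if not selected:
                continue
            dataset = f"{line}_N{n}"
            fm_all = build_expression_features(m, selected, labels.loc[m.index], name=dataset)
            train_fm = FeatureMatrix(X=fm_all.X.loc[tr], y=fm_all.y.loc[tr], name=dataset)
            test_fm = FeatureMatrix(X=fm_all.X.loc[te], y=fm_all.y.loc[te], name=dataset)
            mods, reps = _train_and_evaluate(
                train_fm, test_fm, dataset, dili_class, cfg, ResampleConfig(method="none")
            )
            models += mods
            reports += reps
    return models, reports


def prepare_table(table: pd.DataFrame, labels: pd.Series, name: str, cfg: PipelineConfig) -> FeatureMatrix:
    """Fixed prep order: missing rows → zero variance → correlation filter
    (→ derived reporting ratios for the adverse-event table)."""
    fm = FeatureMatrix(X=table, y=labels.reindex(table.index), name=name)
    fm = prep.drop_missing_rows(fm)
    fm = prep.drop_zero_variance(fm)
    fm = prep.correlation_filter(fm, cutoff=cfg.corr_cutoff)
    if name.startswith("faers"):
        fm = prep.derive_reporting_ratios(fm)
    return fm


def run_tabular_branch(
    study: SimulatedStudy,
    table_name: str,
    dili_class: str,
    train_idx: pd.Index,
    test_idx: pd.Index,
    cfg: PipelineConfig,
) -> tuple[list[TrainedModel], list[EvalReport]]:
    """Prep chain, then training under every configured resampling setting."""
    if table_name not in study.tabular:
        raise ValueError(f"unknown tabular dataset {table_name!r}")
    labels = study.labels[dili_class]
    fm = prepare_table(study.tabular[table_name], labels, table_name, cfg)
    tr = fm.X.index.intersection(train_idx)
    te = fm.X.index.intersection(test_idx)
    train_fm = FeatureMatrix(X=fm.X.loc[tr], y=fm.y.loc[tr], name=fm.name, log=list(fm.log))
    test_fm = FeatureMatrix(X=fm.X.loc[te], y=fm.y.loc[te], name=fm.name, log=list(fm.log))
    # training-set statistics only; resampling happens later, inside the CV
    test_std = prep.standardize(train_fm, test_fm)
    train_std = prep.standardize(train_fm, train_fm)
    models, reports = [], []
    for method in cfg.resample_methods:
        rs = ResampleConfig(
            method=method, seed=_derive_seed(cfg.seed, table_name, dili_class, method)
        )
        dataset = f"{table_name}_{method}"
        train_named = FeatureMatrix(
            X=train_std.X, y=train_std.y, name=dataset, log=list(train_std.log)
        )
        test_named = FeatureMatrix(
            X=test_std.X, y=test_std.y, name=dataset, log=list(test_std.log)
        )
        mods, reps = _train_and_evaluate(train_named, test_named, dataset, dili_class, cfg, rs)
        models += mods
        reports += reps
    return models, reports


def run_ensemble(
    models: list[TrainedModel],
    dili_class: str,
    feature_tables: dict[str, tuple[pd.DataFrame, pd.Series]],
    cfg: PipelineConfig,
) -> tuple[dict[str, pd.Series], list[EvalReport]]:
    """Hard/soft/weighted votes of the top-k models on the shared test drugs.

    ``feature_tables`` maps dataset name to that dataset's (test features,
    test labels). Members vote only on drugs present in every member's test
    table; fewer than 2 available models skips the ensemble with a warning.
    """
    cls_models = [m for m in models if m.dili_class == dili_class]
    if len(cls_models) < 2:
        log.warning("fewer than 2 models for %s; ensemble skipped", dili_class)
        return {}, []
    top = rank_models(cls_models, cfg.top_k)
    common = None
    for m in top:
        idx = feature_tables[m.dataset][0].index
        common = idx if common is None else common.intersection(idx)
    if len(common) == 0:
        log.warning("no common test drugs across ensemble members; skipped")
        return {}, []
    probs, weights, ids = [], [], []
    for m in top:
        x_test, _ = feature_tables[m.dataset]
        p = predict_proba(m, x_test.loc[common])
        probs.append(p)
        weights.append(float(np.clip(m.cv_auc, 1e-6, 1 - 1e-6)))
        ids.append(f"{m.dataset}/{m.algorithm}")
    inp = EnsembleInput(probabilities=probs, weights=weights, member_ids=ids)
    y_true = feature_tables[top[0].dataset][1].loc[common]
    votes, reports = {}, []
    for method, fn in (("hard", hard_vote), ("soft", soft_vote), ("weighted", weighted_vote)):
        vp = fn(inp)
        votes[method] = vp.labels
        reports.append(
            EvalReport.from_predictions(
                "ensemble", dili_class, f"{method}_voting",
                y_true, vp.labels, vp.scores["p_positive"],
            )
        )
    return votes, reports


def run_pipeline(cfg: PipelineConfig, study: SimulatedStudy | None = None) -> PipelineResult:
    """Execute the full analysis for every configured DILI class."""
    t0 = time.time()
    study = study if study is not None else simulate_study(cfg.sim)
    manifest: dict = {
        "config": _config_snapshot(cfg),
        "version": _version(),
        "stages": {},
        "started": t0,
    }
    merged = merge_signatures(study)
    manifest["stages"]["merge"] = {
        "n_merged": len(merged),
        "n_uncovered": len(study.uncovered_drugs),
    }
    all_models: list[TrainedModel] = []
    all_reports: list[EvalReport] = []
    votes: dict[tuple[str, str], pd.Series] = {}
    for dili_class in cfg.dili_classes:
        labels = study.labels[dili_class]
        split_seed = _derive_seed(cfg.seed, "split", dili_class)
        train_idx, test_idx = split_drugs(labels, cfg.test_fraction, split_seed)
        manifest["stages"][f"split/{dili_class}"] = {
            "seed": split_seed, "n_train": len(train_idx), "n_test": len(test_idx),
        }
        feature_tables: dict[str, tuple[pd.DataFrame, pd.Series]] = {}

        models, reports, _ = run_expression_branch(
            study, dili_class, train_idx, test_idx, cfg, merged=merged
        )
        for m in models:
            if m.dataset not in feature_tables:
                n = int(m.dataset.split("N")[-1])
                sets = {d: extreme_sets(r, n) for d, r in merged.items()}
                mm = membership_matrix(sets, study.expression[next(iter(study.expression))].index)
                te = mm.index.intersection(test_idx)
                feature_tables[m.dataset] = (
                    mm.loc[te, m.columns].astype(float), labels.loc[te],
                )
        all_models += models
        all_reports += reports

        if cfg.per_cell_line:
            mods, reps = run_per_cell_line(study, dili_class, train_idx, test_idx, cfg)
            all_reports += reps  # per-line models inform Table-4-style reports only

        for table_name in study.tabular:
            mods, reps = run_tabular_branch(
                study, table_name, dili_class, train_idx, test_idx, cfg
            )
            # rebuild each resampling setting's standardized test table once
            fm = prepare_table(study.tabular[table_name], labels, table_name, cfg)
            tr = fm.X.index.intersection(train_idx)
            te = fm.X.index.intersection(test_idx)
            train_fm = FeatureMatrix(X=fm.X.loc[tr], y=fm.y.loc[tr], name=fm.name)
            test_fm = FeatureMatrix(X=fm.X.loc[te], y=fm.y.loc[te], name=fm.name)
            test_std = prep.standardize(train_fm, test_fm)
            for method in cfg.resample_methods:
                feature_tables[f"{table_name}_{method}"] = (test_std.X, test_std.y)
            all_models += mods
            all_reports += reps
            manifest["stages"][f"prep/{table_name}/{dili_class}"] = {
                "log": list(fm.log), "n_rows": len(fm.X), "n_features": fm.X.shape[1],
            }

        cls_votes, vote_reports = run_ensemble(all_models, dili_class, feature_tables, cfg)
        for method, lab in cls_votes.items():
            votes[(dili_class, method)] = lab
        all_reports += vote_reports

    manifest["stages"]["models"] = [m.metadata() for m in all_models]
    manifest["elapsed_s"] = time.time() - t0
    return PipelineResult(reports=all_reports, models=all_models, votes=votes, manifest=manifest)


def write_report(result: PipelineResult, outdir: str | Path) -> None:
    """Performance table as TSV (2-dec half-up) and JSON (unrounded) + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.report_frame(rounded=True).to_csv(outdir / "performance.tsv", sep="\t", index=False)
    unrounded = [r.to_row(rounded=False) for r in result.reports]
    (outdir / "performance.json").write_text(json.dumps(unrounded, indent=2))
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, default=str))


def _config_snapshot(cfg: PipelineConfig) -> dict:
    snap = asdict(cfg)
    snap["sim"] = asdict(cfg.sim)
    snap["cv"] = asdict(cfg.cv)
    return snap


def _version() -> str:
    from dilipred import __version__

    return __version__
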