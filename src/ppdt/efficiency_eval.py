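"""Efficiency evaluation of gene sets as classification features.

A gene set is judged by how well the probe-averaged expression of its genes
separates sample statuses under a soft-margin linear SVM with repeated
stratified five-fold cross-validation.  Two binary tasks mirror the
evaluated study design: normal vs disease, and disease vs treated.  Metrics
are sensitivity, specificity, accuracy, Matthews correlation coefficient at
the zero decision threshold, and AUC from the held-out decision scores.

A Wilcoxon signed-rank consistency filter can remove samples whose
expression deviates from their status group (each sample is tested against
the leave-one-out per-gene median of its group, with BH-FDR across
samples); classification is then repeated on the consistent subset.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ppdt.enrichment import bh_fdr
from ppdt.network_io import ExpressionMatrix

logger = logging.getLogger(__name__)

TASKS = {
    # task -> (negative status, positive status)
    "normal_vs_disease": ("normal", "disease"),
    "disease_vs_treated": ("disease", "treated"),
}

METRIC_NAMES = ("sensitivity", "specificity", "auc", "accuracy", "mcc")


@dataclass(frozen=True)
class FeatureMatrix:
    """Samples x gene features for one binary task (labels 1 = positive status)."""

    X: pd.DataFrame  # samples x genes
    y: np.ndarray  # 0/1 per sample
    task: str

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if len(set(self.y.tolist())) < 2:
            raise ValueError("both classes must be present")


@dataclass(frozen=True)
class ClassificationReport:
    per_repeat: pd.DataFrame  # repeats x METRIC_NAMES
    means: dict[str, float]
    roc_points: pd.DataFrame  # pooled over repeats: fpr, tpr
    n_repeats: int
    folds: int
    seed: int


@dataclass(frozen=True)
class ConsistencyResult:
    table: pd.DataFrame  # sample, status, p_value, q_value, consistent
    alpha: float


def build_features(
    expr: ExpressionMatrix, genes, task: str
) -> FeatureMatrix:
    """One feature per gene: the mean of all probe rows mapping to it.

    Samples are restricted to the task's two statuses; genes with no probe
    on the platform are dropped with a warning.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    neg, pos = TASKS[task]
    keep = [s for s in expr.samples if expr.status[s] in (neg, pos)]
    cols: dict[str, np.ndarray] = {}
    dropped = []
    for gene in sorted(set(genes)):
        rows = expr.gene_values(gene)
        if rows.empty:
            dropped.append(gene)
            continue
        cols[gene] = rows[keep].mean(axis=0).to_numpy()
    if dropped:
        logger.warning("%d genes have no expression rows: %s", len(dropped), dropped[:10])
    if not cols:
        raise ValueError("no gene of the feature set maps to any expression row")
    X = pd.DataFrame(cols, index=keep)
    y = np.asarray([1 if expr.status[s] == pos else 0 for s in keep])
    for label, status in ((0, neg), (1, pos)):
        if int((y == label).sum()) < 2:
            raise ValueError(f"task {task!r}: status {status!r} has fewer than 2 samples")
    return FeatureMatrix(X=X, y=y, task=task)


def metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float, float]:
    """(sensitivity, specificity, accuracy, MCC) from a confusion matrix.

    MCC is defined as 0 when any marginal factor is zero.
    """
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present (tp+fn > 0 and tn+fp > 0)")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + tn + fp + fn)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)
    return sens, spec, acc, mcc


def auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg), ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve (fpr, tpr) over descending score thresholds."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # keep one point per distinct threshold
    distinct = np.r_[np.diff(s) != 0, True]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def cv_classify(
    fm: FeatureMatrix,
    folds: int = 5,
    repeats: int = 1000,
    seed: int = 17,
    C: float = 1.0,
) -> ClassificationReport:
    """Repeated stratified k-fold linear-SVM cross-validation.

    Per repeat r a deterministic sub-seed (seed + r) drives the stratified
    fold assignment; per fold, features are z-scored on the training data,
    a linear SVM (C = 1 by default) is fitted and held-out samples are
    scored with the decision function.  Sensitivity, specificity, accuracy
    and MCC are taken at the zero decision threshold over the repeat's
    pooled held-out predictions; AUC from its pooled held-out scores.  If a
    class has fewer samples than folds, the fold count is reduced with a
    warning.  Identical inputs and seed give identical reports.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = fm.y
    X = fm.X.to_numpy()
    min_class = int(min((y == 1).sum(), (y == 0).sum()))
    if min_class < folds:
        logger.warning("class of size %d < %d folds; reducing folds", min_class, folds)
        folds = min_class
    rows = []
    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    for r in range(repeats):
        sub_seed = seed + r
        while True:
            skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=sub_seed)
            try:
                scores = np.empty(len(y))
                pred = np.empty(len(y), dtype=int)
                for train, test in skf.split(X, y):
                    if len(set(y[train].tolist())) < 2:
                        raise RuntimeError("single-class training fold")
                    scaler = StandardScaler().fit(X[train])
                    clf = SVC(kernel="linear", C=C)
                    clf.fit(scaler.transform(X[train]), y[train])
                    s = clf.decision_function(scaler.transform(X[test]))
                    scores[test] = s
                    pred[test] = (s > 0).astype(int)
                break
            except RuntimeError:
                logger.warning("degenerate fold at sub-seed %d; redrawing", sub_seed)
                sub_seed += 7919
        tp = int(((pred == 1) & (y == 1)).sum())
        tn = int(((pred == 0) & (y == 0)).sum())
        fp = int(((pred == 1) & (y == 0)).sum())
        fn = int(((pred == 0) & (y == 1)).sum())
        sens, spec, acc, mcc = metrics(tp, tn, fp, fn)
        rows.append((sens, spec, auc(scores, y), acc, mcc))
        all_scores.append(scores)
        all_labels.append(y)
    per_repeat = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    pooled = roc_points(np.concatenate(all_scores), np.concatenate(all_labels))
    return ClassificationReport(
        per_repeat=per_repeat,
        means={m: float(per_repeat[m].mean()) for m in METRIC_NAMES},
        roc_points=pooled,
        n_repeats=repeats,
        folds=folds,
        seed=seed,
    )


def _deviation_p(expr: ExpressionMatrix, sample: str, reference: list[str]) -> float:
    ref = expr.values[reference].median(axis=1)
    diffs = (expr.values[sample] - ref).to_numpy()
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(diffs, alternative="two-sided").pvalue)


def consistency_check(expr: ExpressionMatrix, alpha: float = 0.05) -> ConsistencyResult:
    """Flag samples whose expression deviates from their status group.

    Each sample's per-row values are compared with the per-row median of
    the *other* samples of its status group by a two-sided Wilcoxon
    signed-rank test; p-values are BH-adjusted across all tested samples
    and a sample is consistent iff q >= alpha (not significantly deviant).

    The test is applied sequentially: the single most deviant significant
    sample is removed from the reference pool and the remaining samples are
    re-tested, until none is significant.  A gross outlier would otherwise
    contaminate the group median and make every clean group member look
    deviant.  Groups smaller than 3 cannot provide a reference and are an
    error; removal stops once a reference would drop below 2 samples.
    """
    for status, count in expr.status_counts().items():
        if count < 3:
            raise ValueError(f"status group {status!r} has {count} samples (< 3)")
    removed: dict[str, tuple[float, float]] = {}  # sample -> (p, q) at removal
    while True:
        surviving = [s for s in expr.samples if s not in removed]
        p_values = {}
        for sample in surviving:
            reference = [
                s for s in surviving
                if s != sample and expr.status[s] == expr.status[sample]
            ]
            if len(reference) < 2:
                p_values[sample] = 1.0
                continue
            p_values[sample] = _deviation_p(expr, sample, reference)
        q_values = dict(zip(surviving, bh_fdr([p_values[s] for s in surviving])))
        flagged = [s for s in surviving if q_values[s] < alpha]
        if not flagged:
            break
        worst = min(flagged, key=lambda s: (p_values[s], s))
        removed[worst] = (p_values[worst], q_values[worst])
        logger.info("consistency: removed deviant sample %s (p=%.3g)", worst, p_values[worst])
    records = []
    for sample in expr.samples:
        if sample in removed:
            p, q = removed[sample]
            records.append((sample, expr.status[sample], p, q, False))
        else:
            records.append(
                (sample, expr.status[sample], p_values[sample], q_values[sample], True)
            )
    table = pd.DataFrame(
        records, columns=["sample", "status", "p_value", "q_value", "consistent"]
    )
    return ConsistencyResult(table=table.set_index("sample"), alpha=alpha)


def select_consistent_pairs(
    cr: ConsistencyResult, expr: ExpressionMatrix
) -> ExpressionMatrix:
    """Restrict to consistent samples, keeping disease/treated pairs intact.

    Consistent normal samples are kept; a disease/treated pair is kept as a
    whole iff its treated member is consistent (the treated samples that
    reached the common post-treatment state define the usable pairs).
    """
    if expr.pair_id is None:
        raise ValueError("pair ids are required to select consistent pairs")
    consistent = set(cr.table.index[cr.table["consistent"]])
    keep: list[str] = []
    for s in expr.samples:
        st = expr.status[s]
        if st == "normal":
            if s in consistent:
                keep.append(s)
        elif st == "treated":
            if s in consistent and pd.notna(expr.pair_id[s]):
                keep.append(s)
    treated_pairs = {expr.pair_id[s] for s in keep if expr.status[s] == "treated"}
    for s in expr.samples:
        if expr.status[s] == "disease" and expr.pair_id[s] in treated_pairs:
            keep.append(s)
    return expr.subset_samples(keep)


def write_report_tsv(report: ClassificationReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("repeat\t" + "\t".join(METRIC_NAMES) + "\n")
        for i, row in report.per_repeat.iterrows():
            fh.write(f"{i}\t" + "\t".join(f"{row[m]:.6g}" for m in METRIC_NAMES) + "\n")
        fh.write("mean\t" + "\t".join(f"{report.means[m]:.6g}" for m in METRIC_NAMES) + "\n")


def write_consistency_tsv(cr: ConsistencyResult, path) -> None:
    out = cr.table.copy()
    out["consistent"] = out["consistent"].astype(int)
    out.to_csv(path, sep="\t")
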