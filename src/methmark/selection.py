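"""Resampled elastic-net consensus feature selection.

The discovery cohort is split many times (default 1,000) into
stratified 70/30 train/test partitions. For each split a multinomial
logistic model with an elastic-net penalty

    (1/n) * sum_i NLL_i + lambda * sum_j [ (1-alpha)/2 * b_j^2 + alpha * |b_j| ]

is tuned on the training part: lambda by k-fold cross-validated
deviance along a log-spaced path, alpha over a grid; features are
standardized on the training samples only. Models whose held-out
accuracy exceeds the gate (default 80%) are "successful"; the consensus
set keeps every CpG selected (nonzero coefficient in any class) in at
least a threshold fraction (default 10%) of successful models. Per-class
selection frequencies (nonzero support per class coefficient vector)
are recorded to support downstream cluster-specificity calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from ._enet import enet_path, lambda_max, multinomial_deviance, predict_proba
from .config import PipelineConfig
from .io import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SplitSpec",
    "EnetModelRecord",
    "ConsensusSet",
    "ConsensusError",
    "stratified_split",
    "fit_enet",
    "evaluate_classifier",
    "run_consensus_selection",
]


class ConsensusError(RuntimeError):
    """No resampled model passed the accuracy gate."""


@dataclass(frozen=True)
class SplitSpec:
    split_id: int
    train_ids: tuple
    test_ids: tuple

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def stratified_split(
    sample_ids, labels, train_fraction: float, rng: np.random.Generator, split_id: int = 0
) -> SplitSpec:
    """One stratified train/test split with largest-remainder rounding.

    The total training size is ``round(train_fraction * n)``; it is
    apportioned to clusters proportionally (floors first, remaining
    slots by largest fractional remainder) so that every cluster
    appears in both partitions.
    """
    sample_ids = np.asarray(sample_ids, dtype=object)
    labels = np.asarray(labels)
    n = len(sample_ids)
    clusters = sorted(set(labels.tolist()))
    counts = {c: int((labels == c).sum()) for c in clusters}
    if any(v < 2 for v in counts.values()):
        small = [c for c, v in counts.items() if v < 2]
        raise ValueError(f"clusters with fewer than 2 samples: {small}")

    n_train_total = int(round(train_fraction * n))
    quota = {c: train_fraction * counts[c] for c in clusters}
    alloc = {c: int(np.floor(quota[c])) for c in clusters}
    # keep both partitions non-empty per cluster
    for c in clusters:
        alloc[c] = min(max(alloc[c], 1), counts[c] - 1)
    remaining = n_train_total - sum(alloc.values())
    remainders = sorted(
        clusters, key=lambda c: (-(quota[c] - np.floor(quota[c])), c)
    )
    i = 0
    while remaining > 0 and i < 10 * len(clusters):
        c = remainders[i % len(clusters)]
        if alloc[c] < counts[c] - 1:
            alloc[c] += 1
            remaining -= 1
        i += 1

    train, test = [], []
    for c in clusters:
        idx = np.flatnonzero(labels == c)
        perm = rng.permutation(idx)
        train.extend(sample_ids[perm[: alloc[c]]].tolist())
        test.extend(sample_ids[perm[alloc[c] :]].tolist())
    return SplitSpec(split_id, tuple(train), tuple(test))


@dataclass(frozen=True)
class EnetModelRecord:
    split_id: int
    alpha: float
    lam: float
    selected_cpgs_overall: frozenset
    selected_cpgs_per_class: dict
    accuracy: float
    balanced_accuracy: float
    per_class: dict
    successful: bool


@dataclass(frozen=True)
class ConsensusSet:
    frequencies_overall: dict
    frequencies_per_class: dict  # cluster -> {cpg -> freq}
    retained: frozenset
    n_successful: int

    def to_frame(self) -> pd.DataFrame:
        clusters = sorted(self.frequencies_per_class)
        rows = []
        for g in sorted(self.frequencies_overall, key=lambda g: (-self.frequencies_overall[g], g)):
            row = {"cpg_id": g, "frequency": self.frequencies_overall[g]}
            for c in clusters:
                row[f"frequency_cluster_{c}"] = self.frequencies_per_class[c].get(g, 0.0)
            row["retained"] = g in self.retained
            rows.append(row)
        return pd.DataFrame(rows)


def evaluate_classifier(pred, truth, classes=None) -> dict:
    """Accuracy, balanced accuracy and per-class one-vs-rest metrics.

    Balanced accuracy averages per-class recall over classes present in
    ``truth``; classes absent from the truth vector have undefined
    recall and are excluded (logged). F1 is defined as 0 when precision
    and recall are both 0.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth vectors differ in length")
    if classes is None:
        classes = sorted(set(truth.tolist()) | set(pred.tolist()))
    accuracy = float((pred == truth).mean())
    recalls = []
    per_class = {}
    for c in classes:
        tp = int(((pred == c) & (truth == c)).sum())
        fp = int(((pred == c) & (truth != c)).sum())
        fn = int(((pred != c) & (truth == c)).sum())
        tn = int(((pred != c) & (truth != c)).sum())
        if tp + fn == 0:
            logger.info("class %r absent from truth; excluded from balanced accuracy", c)
            per_class[c] = {"sensitivity": np.nan, "specificity": np.nan, "f1": np.nan}
            continue
        sens = tp / (tp + fn)
        spec = tn / (tn + fp) if tn + fp > 0 else np.nan
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        f1 = 0.0 if prec + sens == 0 else 2 * prec * sens / (prec + sens)
        per_class[c] = {"sensitivity": sens, "specificity": spec, "f1": f1}
        recalls.append(sens)
    balanced = float(np.mean(recalls)) if recalls else np.nan
    return {"accuracy": accuracy, "balanced_accuracy": balanced, "per_class": per_class}


def fit_enet(
    m: BetaMatrix,
    labels,
    split: SplitSpec,
    alpha_grid,
    cv_folds: int,
    rng: np.random.Generator,
    accuracy_gate: float = 0.80,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-3,
    max_outer: int = 5,
    max_pass: int = 30,
) -> EnetModelRecord:
    """Tune and fit one elastic-net multinomial model on one split.

    (alpha, lambda) minimise the mean cross-validated deviance over the
    alpha grid x a log-spaced lambda path from lambda_max down by
    ``lambda_min_ratio``; the winning pair is refit on the full training
    part and evaluated on the held-out test part. Features are
    standardized on the training samples; zero-variance features in the
    training part are dropped for this split (logged). Ties in CV
    deviance go to the sparser model (larger lambda, then larger alpha).
    """
    labels = np.asarray(labels)
    label_of = dict(zip(m.sample_ids, labels))
    train_ids = list(split.train_ids)
    test_ids = list(split.test_ids)
    y_train_lab = np.array([label_of[s] for s in train_ids])
    y_test_lab = np.array([label_of[s] for s in test_ids])
    classes = np.array(sorted(set(y_train_lab.tolist())))
    if classes.size < 2:
        raise ValueError("training partition needs at least two classes")
    K = classes.size
    class_idx = {c: i for i, c in enumerate(classes)}
    y_train = np.array([class_idx[c] for c in y_train_lab], dtype=np.int64)

    X_all = m.select_samples(train_ids).values
    X_test_all = m.select_samples(test_ids).values
    mu = X_all.mean(axis=0)
    sd = X_all.std(axis=0)
    keep = sd > 0
    if not keep.all():
        logger.info(
            "split %d: dropping %d zero-variance features",
            split.split_id,
            int((~keep).sum()),
        )
    cpgs = np.asarray(m.cpg_ids, dtype=object)[keep]
    X_train = np.ascontiguousarray((X_all[:, keep] - mu[keep]) / sd[keep])
    X_test = np.ascontiguousarray((X_test_all[:, keep] - mu[keep]) / sd[keep])

    cv = StratifiedKFold(
        n_splits=cv_folds,
        shuffle=True,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    folds = list(cv.split(X_train, y_train))

    best = None  # (mean deviance, path index, alpha, lambda)
    for alpha in alpha_grid:
        lam_hi = lambda_max(X_train, y_train, K, alpha)
        path = np.geomspace(lam_hi, lam_hi * lambda_min_ratio, n_lambda)
        dev = np.zeros(n_lambda)
        for tr_idx, va_idx in folds:
            B0, B = enet_path(
                np.ascontiguousarray(X_train[tr_idx]),
                y_train[tr_idx],
                K,
                path,
                float(alpha),
                tol,
                max_outer,
                max_pass,
            )
            for j in range(n_lambda):
                dev[j] += multinomial_deviance(
                    X_train[va_idx], y_train[va_idx], B0[j], B[j]
                )
        dev /= len(folds)
        j_best = int(np.argmin(dev))  # first minimum = largest lambda
        if best is None or dev[j_best] < best[0] - 1e-12:
            best = (float(dev[j_best]), j_best, float(alpha), float(path[j_best]))
    _, j_star, alpha_star, lam_star = best

    # refit the winning path on the full training part, stop at lam_star
    lam_hi = lambda_max(X_train, y_train, K, alpha_star)
    final_path = np.geomspace(lam_hi, lam_hi * lambda_min_ratio, n_lambda)[: j_star + 1]
    B0, B = enet_path(X_train, y_train, K, final_path, alpha_star, tol, max_outer, max_pass)
    b0, b = B0[-1], B[-1]

    selected_per_class = {
        int(c): frozenset(cpgs[b[i] != 0].tolist()) for i, c in enumerate(classes)
    }
    selected_overall = frozenset().union(*selected_per_class.values())

    prob = predict_proba(X_test, b0, b)
    pred = classes[prob.argmax(axis=1)]
    metrics = evaluate_classifier(pred, y_test_lab, classes=list(classes))
    return EnetModelRecord(
        split_id=split.split_id,
        alpha=alpha_star,
        lam=lam_star,
        selected_cpgs_overall=selected_overall,
        selected_cpgs_per_class=selected_per_class,
        accuracy=metrics["accuracy"],
        balanced_accuracy=metrics["balanced_accuracy"],
        per_class=metrics["per_class"],
        successful=metrics["accuracy"] > accuracy_gate,
    )


def consensus_from_records(records, threshold: float) -> ConsensusSet:
    """Selection frequencies over successful models; retain >= threshold."""
    successful = [r for r in records if r.successful]
    if not successful:
        raise ConsensusError(
            "no model passed the accuracy gate; the signal may be too weak "
            "for the configured gate, or the gate too strict"
        )
    n = len(successful)
    overall: dict = {}
    per_class: dict = {}
    for r in sorted(successful, key=lambda r: r.split_id):
        for g in r.selected_cpgs_overall:
            overall[g] = overall.get(g, 0) + 1
        for c, sel in r.selected_cpgs_per_class.items():
            bucket = per_class.setdefault(c, {})
            for g in sel:
                bucket[g] = bucket.get(g, 0) + 1
    freq_overall = {g: k / n for g, k in overall.items()}
    freq_per_class = {
        c: {g: k / n for g, k in bucket.items()} for c, bucket in per_class.items()
    }
    retained = frozenset(g for g, f in freq_overall.items() if f >= threshold)
    return ConsensusSet(freq_overall, freq_per_class, retained, n)


def run_consensus_selection(
    m: BetaMatrix, labels, dmp_features, cfg: PipelineConfig
) -> tuple[list, ConsensusSet]:
    """The full resampling loop over ``cfg.n_splits`` splits.

    ``m`` is restricted to ``dmp_features`` (order-stable); each split
    draws from its own seed substream so the result is independent of
    execution order. Returns all model records plus the consensus set.
    """
    dmp_features = sorted(dmp_features)
    if not dmp_features:
        raise ValueError("dmp_features must be non-empty")
    sub = m.select_cpgs(dmp_features)
    labels = np.asarray(labels)
    records = []
    for i in range(cfg.n_splits):
        split = stratified_split(
            sub.sample_ids, labels, cfg.train_fraction, cfg.rng("split", i), split_id=i
        )
        rec = fit_enet(
            sub,
            labels,
            split,
            cfg.alpha_grid,
            cfg.cv_folds,
            cfg.rng("enet-cv", i),
            accuracy_gate=cfg.accuracy_gate,
            n_lambda=cfg.n_lambda,
            lambda_min_ratio=cfg.lambda_min_ratio,
        )
        records.append(rec)
    consensus = consensus_from_records(records, cfg.consensus_threshold)
    return records, consensus


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "split_id": r.split_id,
                "alpha": r.alpha,
                "lambda": r.lam,
                "n_selected": len(r.selected_cpgs_overall),
                "accuracy": r.accuracy,
                "balanced_accuracy": r.balanced_accuracy,
                "successful": r.successful,
            }
        )
    return pd.DataFrame(rows)
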