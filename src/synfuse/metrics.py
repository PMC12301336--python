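"""The eight-metric evaluation panel and cross-validation driver.

Binary synergy classifiers here are scored with AUROC, AUPR, accuracy,
balanced accuracy, precision, recall (TPR), Cohen's kappa, and F1.
Rank metrics use the predicted synergy probability directly; thresholded
metrics binarize at 0.5 by default.  When the test truth contains a single
class the rank metrics are undefined and reported as NaN with an explicit
flag rather than silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import (average_precision_score, cohen_kappa_score,
                             confusion_matrix, roc_auc_score)


@dataclass
class MetricReport:
    """One evaluation panel; NaN + flag marks undefined rank metrics."""

    auroc: float
    aupr: float
    acc: float
    bacc: float
    prec: float
    tpr: float
    kappa: float
    f1: float
    n_test: int
    threshold: float = 0.5
    rank_metrics_defined: bool = True

    METRICS = ("auroc", "aupr", "acc", "bacc", "prec", "tpr", "kappa", "f1")

    def as_dict(self) -> dict:
        return asdict(self)

    def values(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in self.METRICS])


def compute_metrics(y_true, y_prob, threshold: float = 0.5) -> MetricReport:
    """Evaluate predicted synergy probabilities against binary truth.

    AUROC is the Mann–Whitney rank statistic (ties count one half); AUPR
    is step-integrated average precision; BACC = (TPR + TNR) / 2; KAPPA is
    the chance-corrected agreement (p_o − p_e) / (1 − p_e).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("labels and probabilities must have equal length")
    single_class = len(np.unique(y_true)) < 2
    if single_class:
        auroc = aupr = float("nan")
    else:
        auroc = float(roc_auc_score(y_true, y_prob))
        aupr = float(average_precision_score(y_true, y_prob))
    y_hat = (y_prob >= threshold).astype(int)
    tn, fp, fn, tp = confusion_matrix(y_true, y_hat, labels=[0, 1]).ravel()
    acc = (tp + tn) / len(y_true)
    tpr = tp / (tp + fn) if tp + fn else 0.0
    tnr = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * tpr / (prec + tpr) if prec + tpr else 0.0
    kappa = float(cohen_kappa_score(y_true, y_hat))
    return MetricReport(
        auroc=auroc, aupr=aupr, acc=float(acc), bacc=float((tpr + tnr) / 2),
        prec=float(prec), tpr=float(tpr), kappa=kappa, f1=float(f1),
        n_test=len(y_true), threshold=threshold,
        rank_metrics_defined=not single_class,
    )


@dataclass
class CVSummary:
    """Per-fold panels plus mean ± sample standard deviation."""

    reports: list[MetricReport]
    mean: dict[str, float]
    std: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "folds": [r.as_dict() for r in self.reports],
            "mean": self.mean,
            "std": self.std,
        }

    def to_frame(self):
        """One row per fold (plus mean/std rows), metrics as columns."""
        import pandas as pd

        rows = [dict(fold=i, **{m: getattr(r, m) for m in MetricReport.METRICS},
                     n_test=r.n_test)
                for i, r in enumerate(self.reports)]
        rows.append(dict(fold="mean", **self.mean, n_test=""))
        rows.append(dict(fold="std", **self.std, n_test=""))
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def summarize_reports(reports: list[MetricReport]) -> CVSummary:
    values = np.stack([r.values() for r in reports])
    mean = {m: float(np.nanmean(values[:, i]))
            for i, m in enumerate(MetricReport.METRICS)}
    std = {m: float(np.nanstd(values[:, i], ddof=1)) if len(reports) > 1 else 0.0
           for i, m in enumerate(MetricReport.METRICS)}
    return CVSummary(reports=reports, mean=mean, std=std)


def run_cross_validation(triplets, expression, ppi_table, split_plan,
                         config=None, variant: str = "full",
                         threshold: float = 0.5) -> CVSummary:
    """Retrain from scratch on every fold of a split plan and evaluate.

    Group-exclusion is re-asserted inside the loop for group-out schemes:
    no held-out group member may appear in a fold's training set.
    """
    from .model import predict_batch, train_model

    reports = []
    n = len(triplets)
    for fold_id, (train_idx, test_idx) in enumerate(split_plan):
        if np.max(train_idx, initial=-1) >= n or np.max(test_idx, initial=-1) >= n:
            raise IndexError(f"fold {fold_id} indexes outside the dataset")
        if np.intersect1d(train_idx, test_idx).size:
            raise ValueError(f"fold {fold_id} has overlapping train/test sets")
        _assert_group_exclusion(triplets, train_idx, test_idx, split_plan.scheme)
        train = [triplets[i] for i in train_idx]
        test = [triplets[i] for i in test_idx]
        try:
            model = train_model(train, expression, ppi_table, config, variant)
        except Exception as err:
            raise RuntimeError(f"training failed in fold {fold_id}") from err
        preds = predict_batch(model, test)
        reports.append(
            compute_metrics([t.label for t in test],
                            [p.probability for p in preds], threshold)
        )
    return summarize_reports(reports)


def _assert_group_exclusion(triplets, train_idx, test_idx, scheme: str) -> None:
    if scheme == "leave_drug":
        train_drugs = {d for i in train_idx
                       for d in (triplets[i].drug_a, triplets[i].drug_b)}
        # every held-out triplet must contain at least one unseen drug
        for i in test_idx:
            t = triplets[i]
            if t.drug_a in train_drugs and t.drug_b in train_drugs:
                raise ValueError(
                    f"test triplet ({t.drug_a}, {t.drug_b}, {t.cell_line}) "
                    "contains no held-out drug"
                )
    elif scheme == "leave_cell_line":
        test_cells = {triplets[i].cell_line for i in test_idx}
        train_cells = {triplets[i].cell_line for i in train_idx}
        overlap = test_cells & train_cells
        if overlap:
            raise ValueError(f"cell lines leaked into training: {sorted(overlap)}")
    elif scheme == "leave_combination":
        test_pairs = {triplets[i].pair_key() for i in test_idx}
        train_pairs = {triplets[i].pair_key() for i in train_idx}
        overlap = test_pairs & train_pairs
        if overlap:
            raise ValueError(f"drug pairs leaked into training: {sorted(overlap)}")
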