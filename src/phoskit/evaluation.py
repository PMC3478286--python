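"""Performance assessment: Sn, Sp, Ac, MCC, ROC/AUC and cross-validation.

Sensitivity Sn = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
Ac = (TP+TN)/total (all reported as percentages), and the Matthews
correlation coefficient

    MCC = (TP·TN − FP·FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

defined as 0 when any marginal is zero.  ROC curves sweep the decision
threshold over all distinct scores (ties grouped into one step) and AUC
is the trapezoid-rule area, equal to the Mann-Whitney concordance
probability.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .classifier import ModelBundle, ModelConfig, grid_search, predict
from .dataset import SiteFragment
from .encoding import DEFAULT_K_MAX, cksaap_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_calls(cls, labels, calls) -> "ConfusionCounts":
        labels = np.asarray(labels).astype(bool)
        calls = np.asarray(calls).astype(bool)
        return cls(
            TP=int((labels & calls).sum()),
            TN=int((~labels & ~calls).sum()),
            FP=int((~labels & calls).sum()),
            FN=int((labels & ~calls).sum()),
        )


@dataclass(frozen=True)
class MetricReport:
    """Sn/Sp/Ac as percentages, MCC in [-1, 1], optional ROC curve and AUC."""

    sn: float
    sp: float
    ac: float
    mcc: float
    auc: float | None = None
    roc_points: tuple | None = None

    def to_dict(self, decimals: int = 2) -> dict:
        d = {
            "Sn": round(self.sn, decimals),
            "Sp": round(self.sp, decimals),
            "Ac": round(self.ac, decimals),
            "MCC": round(self.mcc, 4),
        }
        if self.auc is not None:
            d["AUC"] = round(self.auc, 4)
        return d


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """The four confusion-table statistics (no ROC)."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero evaluated fragments")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sn = 100.0 * tp / (tp + fn) if tp + fn else 0.0
    sp = 100.0 * tn / (tn + fp) if tn + fp else 0.0
    ac = 100.0 * (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricReport(sn=sn, sp=sp, ac=ac, mcc=mcc)


def roc_and_auc(scores, labels) -> tuple[tuple, float]:
    """ROC points (FPR, TPR) over all distinct scores, and trapezoid AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return tuple(zip(fpr.tolist(), tpr.tolist())), auc


def _report_from_scores(probs, labels, threshold: float) -> MetricReport:
    counts = ConfusionCounts.from_calls(labels, probs >= threshold)
    base = compute_metrics(counts)
    roc, auc = roc_and_auc(probs, labels)
    return MetricReport(
        sn=base.sn, sp=base.sp, ac=base.ac, mcc=base.mcc, auc=auc, roc_points=roc
    )


def cross_validate(
    fragments: list[SiteFragment],
    labels,
    config: ModelConfig = ModelConfig(),
    seed: int = 0,
    k_max: int = DEFAULT_K_MAX,
) -> tuple[list[MetricReport], MetricReport]:
    """Stratified k-fold cross-validation of an RBF SVM on CKSAAP vectors.

    Each fold trains on the remainder (grid-searching C/gamma there when
    the config leaves them unset) and is scored on the held-out fold; the
    summary is the unweighted mean of the per-fold reports.
    """
    labels = np.asarray(labels)
    if min(np.bincount(labels.astype(int))) < config.cv_folds:
        raise ValueError(
            f"a class has fewer samples than cv_folds={config.cv_folds}; "
            "cannot stratify"
        )
    X = cksaap_matrix([f.window for f in fragments], k_max).astype(np.float64)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    reports = []
    for fold_i, (tr, te) in enumerate(skf.split(X, labels)):
        if config.C is None or config.gamma is None:
            gs = grid_search(X[tr], labels[tr], config, seed=seed + fold_i)
            C, gamma = gs.C, gs.gamma
        else:
            C, gamma = config.C, config.gamma
        clf = CalibratedClassifierCV(
            SVC(kernel="rbf", C=C, gamma=gamma),
            method="sigmoid",
            cv=StratifiedKFold(
                n_splits=config.cv_folds, shuffle=True, random_state=seed
            ),
            ensemble=False,
        )
        clf.fit(X[tr], labels[tr])
        probs = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
        reports.append(_report_from_scores(probs, labels[te], config.threshold))
    mean = MetricReport(
        sn=float(np.mean([r.sn for r in reports])),
        sp=float(np.mean([r.sp for r in reports])),
        ac=float(np.mean([r.ac for r in reports])),
        mcc=float(np.mean([r.mcc for r in reports])),
        auc=float(np.mean([r.auc for r in reports])),
    )
    return reports, mean


def evaluate_independent(
    bundle: ModelBundle, fragments: list[SiteFragment], labels
) -> MetricReport:
    """Score an independent test set with the ensemble at its threshold.

    Overlap with the bundle's training provenance (same protein id and
    position) is reported as a warning, not an error — redundancy
    reduction is an upstream responsibility.
    """
    if not fragments:
        raise ValueError("empty test set")
    labels = np.asarray(labels)
    overlap = [
        (f.protein_id, f.position)
        for f in fragments
        if (f.protein_id, f.position) in bundle.train_keys
    ]
    if overlap:
        logger.warning(
            "%d test fragments overlap the bundle's training provenance "
            "(e.g. %s)",
            len(overlap),
            overlap[0],
        )
    probs, _ = predict(bundle, fragments)
    return _report_from_scores(probs, labels, bundle.threshold)


def write_metrics_json(report: MetricReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_metrics_tsv(report: MetricReport, path) -> None:
    d = report.to_dict()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(d.keys()) + "\n")
        fh.write("\t".join(str(v) for v in d.values()) + "\n")


def write_roc(report: MetricReport, path) -> None:
    """ROC points as two-column TSV (FPR, TPR), ready for plotting."""
    if report.roc_points is None:
        raise ValueError("report carries no ROC points")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("fpr\ttpr\n")
        for fpr, tpr in report.roc_points:
            fh.write(f"{fpr:.6f}\t{tpr:.6f}\n")
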