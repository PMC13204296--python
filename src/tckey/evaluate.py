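"""Evaluation analyses: confusion, per-class metrics, one-vs-rest ROC/AUC,
confidence split, reliability-diagram calibration, confused-pair mining,
group-wise accuracy with one-way ANOVA, and pooled-embedding PCA."""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "EvalReport",
    "CalibrationTable",
    "ConfidenceSummary",
    "confusion_matrix",
    "precision_recall_f1",
    "roc_auc_ovr",
    "confidence_summary",
    "calibration_curve",
    "top_confused_pairs",
    "groupwise_accuracy",
    "anova_oneway",
    "pca_project",
    "extract_embeddings",
    "two_proportion_z_test",
    "evaluate_model",
]


# ---------------------------------------------------------------- primitives
def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts matrix: entry (i, j) = number of true-i windows predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for name, arr in (("true", y_true), ("predicted", y_pred)):
        bad = np.where((arr < 0) | (arr >= n_classes))[0]
        if bad.size:
            raise ValueError(f"{name} label {arr[bad[0]]} at index {int(bad[0])} outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def normalize_confusion(cm: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Row-normalized view; all-zero rows stay zero and are flagged."""
    sums = cm.sum(axis=1, keepdims=True)
    empty = [int(i) for i in np.where(sums.ravel() == 0)[0]]
    out = np.divide(cm, sums, out=np.zeros(cm.shape, dtype=np.float64), where=sums > 0)
    return out, empty


def precision_recall_f1(cm: np.ndarray) -> dict:
    """Per-class precision/recall/F1 from a counts matrix, plus macro means.

    Zero-denominator cells yield 0 and are listed under ``flags``.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    tp = np.diag(cm).astype(np.float64)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    flags = []
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1.0), 0.0)
    for c in np.where(tp + fp == 0)[0]:
        flags.append(f"class {int(c)}: never predicted (precision set to 0)")
    for c in np.where(tp + fn == 0)[0]:
        flags.append(f"class {int(c)}: no true windows (recall set to 0)")
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
        "flags": flags,
    }


def _binary_roc(scores: np.ndarray, positives: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC points and trapezoidal AUC with tied scores grouped."""
    order = np.argsort(-scores, kind="stable")
    scores, positives = scores[order], positives[order]
    n_pos = int(positives.sum())
    n_neg = len(positives) - n_pos
    tps = np.cumsum(positives)
    fps = np.cumsum(1 - positives)
    # keep only the last point of each tied-score run
    distinct = np.r_[np.diff(scores) != 0, True]
    tps, fps = tps[distinct], fps[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def roc_auc_ovr(proba: np.ndarray, y_true) -> dict:
    """One-vs-rest ROC per class from probability rows.

    Classes absent from ``y_true`` (or covering all of it) get
    ``auc = None`` and appear under ``missing``.
    """
    proba = np.asarray(proba, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.int64)
    if not np.allclose(proba.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    n_classes = proba.shape[1]
    roc: dict[int, dict] = {}
    missing: list[int] = []
    for c in range(n_classes):
        positives = (y_true == c).astype(np.int64)
        if positives.sum() in (0, len(positives)):
            roc[c] = {"fpr": None, "tpr": None, "auc": None}
            missing.append(c)
            continue
        fpr, tpr, auc = _binary_roc(proba[:, c], positives)
        roc[c] = {"fpr": fpr, "tpr": tpr, "auc": auc}
    aucs = [v["auc"] for v in roc.values() if v["auc"] is not None]
    return {"per_class": roc, "missing": missing, "macro_auc": float(np.mean(aucs)) if aucs else None}


@dataclass(frozen=True)
class ConfidenceSummary:
    mean_confidence_correct: float | None
    mean_confidence_incorrect: float | None
    separation: float | None
    accuracy_above_threshold: float | None
    accuracy_below_threshold: float | None
    threshold: float
    n_above: int
    n_below: int


def confidence_summary(confidences, correct, threshold: float = 0.9) -> ConfidenceSummary:
    """Group means and above/below-threshold accuracies; empty groups are
    reported as None, never as 0."""
    confidences = np.asarray(confidences, dtype=np.float64)
    correct = np.asarray(correct, dtype=bool)
    if confidences.shape != correct.shape:
        raise ValueError("confidences and correctness flags must have equal length")
    if confidences.size and (confidences.min() < 0 or confidences.max() > 1):
        raise ValueError("confidences must lie in [0, 1]")

    def _mean(mask_vals):
        return float(np.mean(mask_vals)) if len(mask_vals) else None

    mc = _mean(confidences[correct])
    mi = _mean(confidences[~correct])
    above = confidences > threshold
    return ConfidenceSummary(
        mean_confidence_correct=mc,
        mean_confidence_incorrect=mi,
        separation=(mc - mi) if mc is not None and mi is not None else None,
        accuracy_above_threshold=_mean(correct[above]),
        accuracy_below_threshold=_mean(correct[~above]),
        threshold=threshold,
        n_above=int(above.sum()),
        n_below=int((~above).sum()),
    )


@dataclass(frozen=True)
class CalibrationTable:
    """Reliability diagram over equal-width confidence bins."""

    bin_edges: np.ndarray  # n_bins + 1
    counts: np.ndarray
    mean_confidence: np.ndarray  # NaN for empty bins
    accuracy: np.ndarray  # NaN for empty bins
    ece: float  # count-weighted |confidence - accuracy|

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def calibration_curve(confidences, correct, n_bins: int = 10) -> CalibrationTable:
    """Bins [0, 0.1), ..., [0.9, 1.0] (last bin right-closed so confidence
    1.0 is counted); per-bin count, mean confidence, and empirical accuracy."""
    confidences = np.asarray(confidences, dtype=np.float64)
    correct = np.asarray(correct, dtype=bool)
    if confidences.size and (confidences.min() < 0 or confidences.max() > 1):
        raise ValueError("confidences must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.minimum((confidences * n_bins).astype(int), n_bins - 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    conf_sum = np.zeros(n_bins)
    acc_sum = np.zeros(n_bins)
    np.add.at(counts, idx, 1)
    np.add.at(conf_sum, idx, confidences)
    np.add.at(acc_sum, idx, correct.astype(np.float64))
    with np.errstate(invalid="ignore"):
        mean_conf = np.where(counts > 0, conf_sum / np.maximum(counts, 1), np.nan)
        acc = np.where(counts > 0, acc_sum / np.maximum(counts, 1), np.nan)
    nonempty = counts > 0
    total = counts.sum()
    ece = float(np.sum(counts[nonempty] * np.abs(mean_conf[nonempty] - acc[nonempty])) / total) if total else 0.0
    return CalibrationTable(bin_edges=edges, counts=counts, mean_confidence=mean_conf, accuracy=acc, ece=ece)


def top_confused_pairs(cm: np.ndarray, k: int = 10) -> list[tuple[int, int, int]]:
    """Off-diagonal cells ranked by count (descending), ties broken by
    (row, col); directional, so L->O and O->L are distinct entries."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    pairs = [
        (int(i), int(j), int(cm[i, j]))
        for i in range(cm.shape[0])
        for j in range(cm.shape[1])
        if i != j and cm[i, j] > 0
    ]
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    return pairs[:k]


def groupwise_accuracy(y_true, y_pred, group_ids) -> dict:
    """Accuracy per group plus mean/SD/min/max across groups."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    group_ids = np.asarray(group_ids)
    if not (len(y_true) == len(y_pred) == len(group_ids)):
        raise ValueError("all inputs must have equal length")
    per_group: dict[str, float] = {}
    for g in np.unique(group_ids):
        mask = group_ids == g
        per_group[str(g)] = float(np.mean(y_true[mask] == y_pred[mask]))
    accs = np.array(list(per_group.values()))
    return {
        "per_group": per_group,
        "mean": float(accs.mean()),
        "sd": float(accs.std(ddof=0)),
        "min": float(accs.min()),
        "max": float(accs.max()),
    }


def anova_oneway(groups: list) -> dict:
    """Classic one-way ANOVA: between/within mean squares, F(k-1, n-k), and
    the upper-tail p-value from the F distribution."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 replicates")
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, n - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        return {
            "F": None,
            "df_between": df_between,
            "df_within": df_within,
            "p": None,
            "note": "zero within-group variance; F undefined",
        }
    F = float(ms_between / ms_within)
    p = float(stats.f.sf(F, df_between, df_within))
    return {"F": F, "df_between": df_between, "df_within": df_within, "p": p}


def two_proportion_z_test(k1: int, n1: int, k2: int, n2: int) -> dict:
    """Two-tailed z-test for a difference in accuracies on two evaluation
    sets (the variant-vs-baseline significance check)."""
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return {"z": None, "p": None, "note": "degenerate proportions"}
    z = float((p1 - p2) / se)
    return {"z": z, "p": float(2 * stats.norm.sf(abs(z)))}


# --------------------------------------------------------------- embeddings
def pca_project(X: np.ndarray, n_components: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Center, eigendecompose the covariance, project onto the top
    eigenvectors.  Returns (projection, explained-variance fractions)."""
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:n_components]
    components = evecs[:, order]
    explained = evals[order] / max(evals.sum(), 1e-300)
    return Xc @ components, explained


def extract_embeddings(model, ws, n_components: int = 2, batch_size: int = 256) -> dict:
    """Pooled embeddings for every window plus their 2-D PCA projection."""
    from .nn import Tensor

    was_training = model.training
    model.eval()
    chunks = []
    for start in range(0, len(ws), batch_size):
        chunks.append(model.embed(Tensor(ws.data[start : start + batch_size])).data)
    model.train(was_training)
    emb = np.concatenate(chunks) if chunks else np.zeros((0, 1))
    proj, explained = pca_project(emb, n_components=n_components)
    return {"embeddings": emb, "projection": proj, "explained_variance": explained}


# -------------------------------------------------------------------- report
@dataclass
class EvalReport:
    accuracy: float
    confusion: np.ndarray
    confusion_normalized: np.ndarray
    empty_rows: list[int]
    per_class: dict
    roc: dict
    confidence: ConfidenceSummary
    calibration: CalibrationTable
    confused_pairs: list[tuple[int, int, int]]
    groups: dict | None = None
    n_windows: int = 0

    def to_json_dict(self) -> dict:
        def _clean(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {str(k): _clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_clean(v) for v in x]
            return x

        d = {
            "accuracy": self.accuracy,
            "n_windows": self.n_windows,
            "confusion": self.confusion,
            "confusion_normalized": self.confusion_normalized,
            "empty_rows": self.empty_rows,
            "per_class": self.per_class,
            "roc": {
                "macro_auc": self.roc["macro_auc"],
                "missing": self.roc["missing"],
                "auc_per_class": {c: v["auc"] for c, v in self.roc["per_class"].items()},
            },
            "confidence": asdict(self.confidence),
            "calibration": {
                "bin_edges": self.calibration.bin_edges,
                "counts": self.calibration.counts,
                "mean_confidence": np.nan_to_num(self.calibration.mean_confidence, nan=-1.0),
                "accuracy": np.nan_to_num(self.calibration.accuracy, nan=-1.0),
                "ece": self.calibration.ece,
            },
            "confused_pairs": self.confused_pairs,
            "groups": self.groups,
        }
        return _clean(d)

    def save(self, report_dir) -> None:
        report_dir = Path(report_dir)
        report_dir.mkdir(parents=True, exist_ok=True)
        (report_dir / "report.json").write_text(json.dumps(self.to_json_dict(), indent=2))
        np.savetxt(report_dir / "confusion.csv", self.confusion, fmt="%d", delimiter=",")
        pc = self.per_class
        rows = ["class,precision,recall,f1"]
        for c in range(len(pc["precision"])):
            rows.append(f"{c},{pc['precision'][c]:.6f},{pc['recall'][c]:.6f},{pc['f1'][c]:.6f}")
        (report_dir / "per_class.csv").write_text("\n".join(rows) + "\n")
        cal = self.calibration
        rows = ["bin_low,bin_high,count,mean_confidence,accuracy"]
        for b in range(len(cal.counts)):
            rows.append(
                f"{cal.bin_edges[b]:.2f},{cal.bin_edges[b + 1]:.2f},{cal.counts[b]},"
                f"{cal.mean_confidence[b]:.6f},{cal.accuracy[b]:.6f}"
            )
        (report_dir / "calibration.csv").write_text("\n".join(rows) + "\n")


def evaluate_model(model, ws, threshold: float = 0.9, group_by: str | None = "subject") -> EvalReport:
    """Run the full analysis battery for a trained model on a window set."""
    from .train import predict_with_confidence

    pred, conf, proba = predict_with_confidence(model, ws)
    n_classes = model.cfg.head.n_classes
    cm = confusion_matrix(ws.labels, pred, n_classes)
    cm_norm, empty = normalize_confusion(cm)
    correct = pred == ws.labels
    groups = None
    if group_by is not None:
        ids = ws.subject_ids if group_by == "subject" else ws.session_ids
        if len(np.unique(ids)) > 1:
            groups = groupwise_accuracy(ws.labels, pred, ids)
    return EvalReport(
        accuracy=float(np.mean(correct)) if len(ws) else float("nan"),
        confusion=cm,
        confusion_normalized=cm_norm,
        empty_rows=empty,
        per_class=precision_recall_f1(cm),
        roc=roc_auc_ovr(proba, ws.labels),
        confidence=confidence_summary(conf, correct, threshold=threshold),
        calibration=calibration_curve(conf, correct),
        confused_pairs=top_confused_pairs(cm),
        groups=groups,
        n_windows=len(ws),
    )
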