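"""Model application: per-class probability prediction, multi-class ROC and
precision–recall evaluation (one-vs-rest per class plus micro-averaging), and
exports.

No decision threshold is ever applied — predictions are exported as per-class
probabilities with the argmax merely highlighted, since a single 'predicted
class' would depend on a subjective threshold choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_curve as _sk_pr
from sklearn.metrics import roc_curve as _sk_roc

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .genomic_io import read_fasta
from .nn import BranchNetwork, softmax
from .preprocessing import EncodedSample, encode_sequence, encode_structure, fold_structure


@dataclass
class PredictionRecord:
    """Per-class probabilities for one sample; ``top_class`` is the argmax
    (ties go to the lowest class index)."""

    sample_id: str
    probabilities: np.ndarray
    top_class: str


@dataclass
class EvaluationReport:
    accuracy: float
    mean_loss: float
    class_names: list[str]
    roc_curves: dict[str, np.ndarray] = field(default_factory=dict)   # (n, 2): FPR, TPR
    pr_curves: dict[str, np.ndarray] = field(default_factory=dict)    # (n, 2): recall, precision
    auroc: dict[str, float] = field(default_factory=dict)
    auprc: dict[str, float] = field(default_factory=dict)
    micro_roc: np.ndarray | None = None
    micro_pr: np.ndarray | None = None
    micro_auroc: float | None = None
    micro_auprc: float | None = None


# ---------------------------------------------------------------------------
# Curves


def roc_curve(labels, scores) -> np.ndarray:
    """(FPR, TPR) points at every distinct score threshold, descending, with
    (0,0) prepended and (1,1) as the final point."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes present in the labels")
    fpr, tpr, _ = _sk_roc(labels, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def pr_curve(labels, scores) -> np.ndarray:
    """(recall, precision) points, one per distinct threshold, thresholds
    descending so recall is non-decreasing along the list."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() < 1:
        raise ValueError("PR curve requires at least one positive label")
    precision, recall, _ = _sk_pr(labels, scores)
    # scikit-learn appends a final (precision=1, recall=0) anchor with no
    # threshold and orders by ascending threshold; drop the anchor and flip.
    precision, recall = precision[:-1][::-1], recall[:-1][::-1]
    return np.column_stack([recall, precision])


def auc_trapezoid(points: np.ndarray) -> float:
    """Trapezoidal area under points sorted by their x coordinate."""
    points = np.asarray(points, dtype=float)
    x, y = points[:, 0], points[:, 1]
    if np.any(np.diff(x) < 0):
        raise ValueError("points must be sorted by x")
    return float(np.trapezoid(y, x))


# ---------------------------------------------------------------------------
# Prediction


def _stack(samples) -> dict[str, np.ndarray]:
    if isinstance(samples, dict):
        return samples
    branch_names = list(samples[0].branches)
    return {b: np.stack([s.branches[b] for s in samples]) for b in branch_names}


def _sample_ids(samples, n: int) -> list[str]:
    if isinstance(samples, dict):
        return [str(i) for i in range(n)]
    return [
        f"{s.source.chrom}:{s.source.start}-{s.source.end}({s.source.strand})"
        for s in samples
    ]


def predict(model: BranchNetwork, samples, class_names: list[str] | None = None,
            ) -> list[PredictionRecord]:
    """One record of per-class probabilities per sample (no thresholding)."""
    inputs = _stack(samples)
    probs = model.predict_proba(inputs)
    if class_names is None:
        class_names = [f"class_{k}" for k in range(probs.shape[1])]
    ids = _sample_ids(samples, probs.shape[0])
    return [
        PredictionRecord(ids[i], probs[i], class_names[int(np.argmax(probs[i]))])
        for i in range(probs.shape[0])
    ]


def predict_from_fasta(model: BranchNetwork, fasta_path,
                       class_names: list[str] | None = None,
                       fold_engine="builtin") -> list[PredictionRecord]:
    """Predict directly from a plain FASTA of fixed-length sequences.

    Only valid for models without a conservation branch (a FASTA carries no
    conservation scores); the structure branch, if present, is folded on the
    fly. Every record must have exactly the model's input length.
    """
    if "conservation" in model.branches:
        raise ValueError(
            "this model uses a conservation branch; FASTA-only prediction "
            "is available only for models without one"
        )
    genome = read_fasta(fasta_path)
    L = next(iter(model.input_shapes.values()))[0]
    seq_mats, struct_mats, ids = [], [], []
    for name, seq in genome.sequences.items():
        if len(seq) != L:
            raise ValueError(
                f"record '{name}' has length {len(seq)}, expected {L}"
            )
        ids.append(name)
        if "sequence" in model.branches:
            seq_mats.append(encode_sequence(seq))
        if "structure" in model.branches:
            struct_mats.append(encode_structure(fold_structure(seq, fold_engine)))
    inputs = {}
    if seq_mats:
        inputs["sequence"] = np.stack(seq_mats)
    if struct_mats:
        inputs["structure"] = np.stack(struct_mats)
    records = predict(model, inputs, class_names)
    for rec, rid in zip(records, ids):
        rec.sample_id = rid
    return records


# ---------------------------------------------------------------------------
# Evaluation


def evaluate(model: BranchNetwork, samples, labels: np.ndarray | None = None,
             class_names: list[str] | None = None) -> EvaluationReport:
    """Accuracy, mean categorical cross-entropy, and per-class one-vs-rest
    ROC/PR curves with AUROC/AUPRC, plus micro-averages over the pooled
    (label, score) pairs of all classes.

    ``samples`` is a list of labelled EncodedSamples, or a dict of stacked
    branch arrays with ``labels`` given explicitly as a one-hot matrix.
    """
    inputs = _stack(samples)
    if labels is None:
        labels = np.stack([s.label for s in samples])
    logits = model.logits(inputs, batch_size=256)
    probs = softmax(logits)
    K = probs.shape[1]
    if class_names is None:
        class_names = [f"class_{k}" for k in range(K)]
    present = np.unique(labels.argmax(axis=1))
    if len(present) < 2:
        raise ValueError("evaluation requires at least 2 classes present in the labels")

    loss = float(-np.mean(np.sum(labels * np.log(np.clip(probs, 1e-12, None)), axis=1)))
    accuracy = float(np.mean(probs.argmax(axis=1) == labels.argmax(axis=1)))
    report = EvaluationReport(accuracy, loss, list(class_names))

    for k, name in enumerate(class_names):
        if k not in present:
            warnings.warn(f"class '{name}' absent from the labels; curves skipped")
            continue
        y, s = labels[:, k], probs[:, k]
        report.roc_curves[name] = roc_curve(y, s)
        report.pr_curves[name] = pr_curve(y, s)
        report.auroc[name] = auc_trapezoid(report.roc_curves[name])
        report.auprc[name] = auc_trapezoid(report.pr_curves[name])

    pooled_y, pooled_s = labels.ravel(), probs.ravel()
    report.micro_roc = roc_curve(pooled_y, pooled_s)
    report.micro_pr = pr_curve(pooled_y, pooled_s)
    report.micro_auroc = auc_trapezoid(report.micro_roc)
    report.micro_auprc = auc_trapezoid(report.micro_pr)
    return report


# ---------------------------------------------------------------------------
# Exports


def export_predictions(records: list[PredictionRecord], out_path,
                       class_names: list[str] | None = None) -> None:
    """One TSV row per sample: id, K probability columns (6 decimals), and
    the highlighted top class."""
    if class_names is None and records:
        class_names = [f"class_{k}" for k in range(len(records[0].probabilities))]
    cols = ["sample_id"] + [f"p_{c}" for c in (class_names or [])] + ["top_class"]
    rows = [
        [r.sample_id] + [f"{p:.6f}" for p in r.probabilities] + [r.top_class]
        for r in records
    ]
    pd.DataFrame(rows, columns=cols).to_csv(out_path, sep="\t", index=False)


def export_evaluation(report: EvaluationReport, out_dir) -> dict[str, Path]:
    """Metrics TSV, per-curve point TSVs, and ROC/PR plot images."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    metrics = [{"metric": "accuracy", "value": report.accuracy},
               {"metric": "mean_loss", "value": report.mean_loss}]
    for name in report.auroc:
        metrics.append({"metric": f"auroc_{name}", "value": report.auroc[name]})
        metrics.append({"metric": f"auprc_{name}", "value": report.auprc[name]})
    metrics.append({"metric": "auroc_micro", "value": report.micro_auroc})
    metrics.append({"metric": "auprc_micro", "value": report.micro_auprc})
    paths["metrics"] = out_dir / "metrics.tsv"
    pd.DataFrame(metrics).to_csv(paths["metrics"], sep="\t", index=False)

    curve_sets = [
        ("roc", report.roc_curves | {"micro": report.micro_roc}, ("fpr", "tpr")),
        ("pr", report.pr_curves | {"micro": report.micro_pr}, ("recall", "precision")),
    ]
    for kind, curves, (xl, yl) in curve_sets:
        fig, ax = plt.subplots(figsize=(5, 5))
        for name, pts in curves.items():
            frame = pd.DataFrame(pts, columns=[xl, yl])
            path = out_dir / f"{kind}_{name}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            paths[f"{kind}_{name}"] = path
            area = (report.micro_auroc if kind == "roc" else report.micro_auprc) \
                if name == "micro" else \
                (report.auroc[name] if kind == "roc" else report.auprc[name])
            ax.plot(pts[:, 0], pts[:, 1], label=f"{name} (area={area:.3f})")
        if kind == "roc":
            ax.plot([0, 1], [0, 1], "k--", lw=0.5)
        ax.set_xlabel(xl)
        ax.set_ylabel(yl)
        ax.legend(loc="lower right" if kind == "roc" else "lower left", fontsize=8)
        fig.tight_layout()
        paths[f"{kind}_plot"] = out_dir / f"{kind}.png"
        fig.savefig(paths[f"{kind}_plot"])
        plt.close(fig)
    return paths
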