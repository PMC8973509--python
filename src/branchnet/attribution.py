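"""Integrated Gradients over all branches of a trained model.

Attribution of input element i is ``(x_i − x'_i) · (1/m) Σ_{k=1..m}
∂F(x' + ((k − ½)/m)(x − x')) / ∂x_i`` — a midpoint Riemann approximation of
the path integral from the baseline x' (all zeros by default) to the input x,
computed simultaneously over all branches along a shared path. F is the
pre-softmax logit of the target class: the softmax saturates, so its gradient
can vanish exactly where the model is most confident, while the logit path
integral stays informative.

The completeness axiom (the attributions sum to F(x) − F(x')) is checked on
every call and the residual delta is reported, so the user always sees the
approximation quality at the chosen m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .config import AttributionConfig
from .evaluation import PredictionRecord


@dataclass
class AttributionResult:
    """Per-branch L×C attribution matrices for one sample, the channel-summed
    per-position profile, and the completeness diagnostic."""

    sample_id: str
    target_class: int
    branch_scores: dict[str, np.ndarray]        # branch -> (L, C)
    per_position: dict[str, np.ndarray]         # branch -> (L,)
    output_at_input: float                      # F_target(x)
    output_at_baseline: float                   # F_target(x')
    completeness_delta: float


def aggregate_positions(matrix: np.ndarray) -> np.ndarray:
    """Per-position attribution: sum each row across its channels."""
    return np.asarray(matrix).sum(axis=-1)


def normalize_for_display(vector: np.ndarray) -> np.ndarray:
    """Scale into [−1, 1] by the max absolute value, preserving sign (positive
    renders red, negative blue). An all-zero vector is returned unchanged."""
    vector = np.asarray(vector, dtype=float)
    peak = np.max(np.abs(vector)) if vector.size else 0.0
    return vector if peak == 0 else vector / peak


def integrated_gradients(model, sample, config: AttributionConfig | None = None,
                         sample_id: str = "") -> AttributionResult:
    """Integrated Gradients for one sample (all branches along a shared path).

    ``sample`` is a dict of per-branch (L, C) matrices or an EncodedSample;
    the baseline is all-zero in every branch (zero is also the neutral value
    of the conservation score). The target is the configured class index or,
    by default, the sample's predicted class.
    """
    if config is None:
        config = AttributionConfig()
    branches = sample.branches if hasattr(sample, "branches") else sample
    missing = set(model.branches) - set(branches)
    if missing:
        raise ValueError(f"sample lacks branch(es) {sorted(missing)} the model requires")
    x = {name: np.asarray(branches[name], dtype=float) for name in model.branches}
    baseline = {name: np.zeros_like(mat) for name, mat in x.items()}

    single = {name: mat[None] for name, mat in x.items()}
    logits_x = model.logits(single)[0]
    if config.target_class is not None:
        if not 0 <= config.target_class < model.n_classes:
            raise ValueError(f"target class {config.target_class} out of range")
        target = config.target_class
    else:
        target = int(np.argmax(logits_x))
    logits_base = model.logits({name: b[None] for name, b in baseline.items()})[0]

    m = config.m_steps
    # Midpoint rule: sampling the path at (k - 1/2)/m cancels the O(1/m)
    # endpoint term a one-sided Riemann sum carries, so the completeness
    # residual falls orders of magnitude faster at the same cost.
    alphas = (np.arange(m) + 0.5) / m
    path = {
        name: baseline[name][None] + alphas[:, None, None] * (mat - baseline[name])[None]
        for name, mat in x.items()
    }
    grads = model.input_gradients(path, target)
    scores = {name: (x[name] - baseline[name]) * grads[name].mean(axis=0)
              for name in x}

    f_x, f_base = float(logits_x[target]), float(logits_base[target])
    total = sum(float(s.sum()) for s in scores.values())
    delta = abs(total - (f_x - f_base))
    tol = max(config.completeness_tolerance * abs(f_x - f_base), 1e-4)
    if delta > tol:
        warnings.warn(
            f"IG completeness delta {delta:.3e} exceeds tolerance {tol:.3e} at "
            f"m={m}; consider increasing m_steps"
        )
    return AttributionResult(
        sample_id=sample_id,
        target_class=target,
        branch_scores=scores,
        per_position={name: aggregate_positions(s) for name, s in scores.items()},
        output_at_input=f_x,
        output_at_baseline=f_base,
        completeness_delta=delta,
    )


def top_k_per_class(records: list[PredictionRecord], k: int = 10) -> dict[int, list[int]]:
    """Indices of the k samples with the highest probability for each class,
    descending; ties at the boundary go to the lower sample index. Returns all
    samples when fewer than k exist."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not records:
        return {}
    K = len(records[0].probabilities)
    probs = np.array([r.probabilities for r in records])
    out = {}
    for c in range(K):
        order = np.argsort(-probs[:, c], kind="stable")
        out[c] = [int(i) for i in order[:k]]
    return out


def export_attribution_report(results: list[AttributionResult], out_dir,
                              class_names: list[str] | None = None,
                              top_k: int = 10) -> dict[str, Path]:
    """Per-sample TSVs of raw per-channel and per-position scores, plus one
    red/blue heatmap per class of the display-normalised per-position profiles
    of its top-k samples."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for i, res in enumerate(results):
        cols: dict[str, np.ndarray] = {}
        for branch, mat in res.branch_scores.items():
            for c in range(mat.shape[1]):
                cols[f"{branch}_ch{c}"] = mat[:, c]
            cols[f"{branch}_position"] = res.per_position[branch]
        frame = pd.DataFrame(cols)
        frame.insert(0, "position", np.arange(len(frame)))
        path = out_dir / f"attribution_{i:04d}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
        paths[f"sample_{i}"] = path

    by_class: dict[int, list[tuple[int, AttributionResult]]] = {}
    for i, res in enumerate(results):
        by_class.setdefault(res.target_class, []).append((i, res))
    for cls, members in sorted(by_class.items()):
        members = sorted(members, key=lambda t: -t[1].output_at_input)[:top_k]
        branch_names = list(members[0][1].per_position)
        rows = [
            normalize_for_display(res.per_position[b])
            for _, res in members
            for b in branch_names
        ]
        matrix = np.vstack(rows)
        fig, ax = plt.subplots(figsize=(10, 0.35 * len(rows) + 1.2))
        ax.imshow(matrix, aspect="auto", cmap="RdBu_r", vmin=-1, vmax=1,
                  interpolation="nearest")
        labels = [f"#{i} {b}" for i, res in members for b in branch_names]
        ax.set_yticks(range(len(rows)), labels, fontsize=6)
        ax.set_xlabel("position")
        name = class_names[cls] if class_names else f"class_{cls}"
        ax.set_title(f"Integrated Gradients, top {len(members)} samples: {name}")
        fig.tight_layout()
        path = out_dir / f"report_{name}.png"
        fig.savefig(path)
        plt.close(fig)
        paths[f"report_{name}"] = path
    return paths
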