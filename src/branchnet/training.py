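"""Mini-batch training with the three optimizers, the two SGD learning-rate
schedules, early stopping on validation loss, and artifact export.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import nn
from .architecture import save_model, summarize_model
from .config import ModelSpec, RunConfig, TrainingConfig
from .genomic_io import append_session_ledger, logger
from .preprocessing import DatasetBundle


def make_optimizer(config: TrainingConfig) -> nn.optimizers.Optimizer:
    """SGD is preset with Nesterov momentum 0.9; RMSprop and Adam keep their
    standard defaults apart from the configured learning rate."""
    return nn.make_optimizer(config.optimizer, config.learning_rate)


def lr_at(config: TrainingConfig, epoch: int, total_epochs: int,
          step: int = 0, total_steps: int = 1) -> float:
    """Learning rate under the configured schedule.

    * ``constant``: the configured rate throughout.
    * ``scheduler``: step decay in thirds of the run,
      ``lr0 * 0.1 ** floor(epoch / ceil(E / 3))``.
    * ``one_cycle``: over global step fraction f = step / total_steps, a
      linear ramp lr0/10 -> lr0 for f in [0, 0.45], linear decay back to
      lr0/10 for f in (0.45, 0.9], then linear annealing to lr0/1000.
    """
    lr0 = config.learning_rate
    if config.lr_mode == "constant":
        return lr0
    if config.lr_mode == "scheduler":
        third = -(-total_epochs // 3)  # ceil
        return lr0 * 0.1 ** (epoch // third)
    f = step / total_steps
    low, peak, floor_ = lr0 / 10, lr0, lr0 / 1000
    if f <= 0.45:
        return low + (peak - low) * (f / 0.45)
    if f <= 0.9:
        return peak - (peak - low) * ((f - 0.45) / 0.45)
    return low - (low - floor_) * ((f - 0.9) / 0.1)


@dataclass
class TrainingHistory:
    """Per-epoch metrics plus where the best validation loss occurred."""

    table: pd.DataFrame  # epoch, train_loss, train_accuracy, val_loss, val_accuracy, lr
    best_epoch: int      # 0-based index into the table
    stopped_early: bool

    @property
    def n_epochs(self) -> int:
        return len(self.table)


def _accuracy(logits: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(logits.argmax(axis=1) == labels.argmax(axis=1)))


def train(model: nn.BranchNetwork, bundle: DatasetBundle,
          config: TrainingConfig) -> tuple[nn.BranchNetwork, TrainingHistory]:
    """Train on bundle.train, monitoring bundle.validation.

    Early stopping (when enabled) watches the validation loss: if it fails to
    improve on the running best by more than ``min_delta`` for ``patience``
    consecutive epochs, training stops and the parameters of the best epoch
    are restored. Epoch-level shuffling is seeded, so a run is fully
    reproducible from (data, spec, config, seed).
    """
    if not bundle.train or not bundle.validation:
        raise ValueError("bundle.train and bundle.validation must be non-empty")
    X, Y = bundle.arrays("train")
    Xval, Yval = bundle.arrays("validation")
    n = Y.shape[0]
    optimizer = make_optimizer(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 21]))
    steps_per_epoch = -(-n // config.batch_size)
    total_steps = steps_per_epoch * config.epochs

    rows = []
    best_loss = np.inf
    best_epoch = 0
    best_weights = model.get_weights()
    wait = 0
    stopped_early = False
    global_step = 0

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0.0
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            xb = {k: v[idx] for k, v in X.items()}
            yb = Y[idx]
            lr = lr_at(config, epoch, config.epochs, global_step, total_steps)
            optimizer.learning_rate = lr
            logits = model.forward(xb, training=True)
            loss, dlogits = model.loss_and_grad(logits, yb)
            model.zero_grad()
            model.backward(dlogits)
            optimizer.step(model.parameters(), model.gradients())
            epoch_loss += loss * len(idx)
            epoch_correct += _accuracy(logits, yb) * len(idx)
            global_step += 1

        val_logits = model.logits(Xval, batch_size=256)
        val_loss, _ = model.loss_and_grad(val_logits, Yval)
        rows.append({
            "epoch": epoch,
            "train_loss": epoch_loss / n,
            "train_accuracy": epoch_correct / n,
            "val_loss": float(val_loss),
            "val_accuracy": _accuracy(val_logits, Yval),
            "lr": lr_at(config, epoch, config.epochs, global_step - 1, total_steps),
        })

        if val_loss < best_loss - (config.min_delta if config.early_stopping else 0):
            wait = 0
        else:
            wait += 1
        if val_loss < best_loss:
            best_loss = float(val_loss)
            best_epoch = epoch
            best_weights = model.get_weights()
        if config.early_stopping and wait >= config.patience:
            stopped_early = True
            model.set_weights(best_weights)
            logger.info("early stopping at epoch %d; restored epoch %d", epoch, best_epoch)
            break

    history = TrainingHistory(pd.DataFrame(rows), best_epoch, stopped_early)
    return model, history


def export_training_artifacts(model: nn.BranchNetwork, spec: ModelSpec,
                              history: TrainingHistory, session_dir,
                              run_config: RunConfig | None = None,
                              metrics: dict | None = None,
                              ledger_path=None, session_id: str = "",
                              seed: int = 0) -> dict[str, Path]:
    """Write the model + spec sidecar, architecture summary, history table,
    loss/accuracy plots, and append one row to the shared session ledger."""
    session_dir = Path(session_dir)
    session_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["model"] = session_dir / "model.npz"
    save_model(model, spec, paths["model"], seed=seed)
    paths["summary"] = session_dir / "architecture.txt"
    paths["summary"].write_text(summarize_model(spec) + "\n")

    paths["history"] = session_dir / "history.tsv"
    history.table.to_csv(paths["history"], sep="\t", index=False)

    for metric, fname in (("loss", "loss.png"), ("accuracy", "accuracy.png")):
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(history.table["epoch"], history.table[f"train_{metric}"], label="train")
        ax.plot(history.table["epoch"], history.table[f"val_{metric}"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel(metric)
        ax.legend()
        fig.tight_layout()
        paths[fname] = session_dir / fname
        fig.savefig(paths[fname])
        plt.close(fig)

    if ledger_path is None:
        ledger_path = session_dir.parent / "sessions.tsv"
    headline = {
        "epochs_run": history.n_epochs,
        "best_epoch": history.best_epoch,
        "stopped_early": history.stopped_early,
        "final_val_loss": round(float(history.table["val_loss"].iloc[-1]), 6),
        "final_val_accuracy": round(float(history.table["val_accuracy"].iloc[-1]), 6),
    }
    headline.update(metrics or {})
    append_session_ledger(ledger_path, run_config or RunConfig(), headline,
                          session_id=session_id or session_dir.name)
    paths["ledger"] = Path(ledger_path)
    return paths
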