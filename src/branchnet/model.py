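"""High-level modelling interface.

:class:`MultiBranchClassifier` is built from a preprocessed
:class:`~branchnet.preprocessing.DatasetBundle` and a declarative
:class:`~branchnet.config.ModelSpec`; ``fit()`` runs training and returns a
:class:`ClassifierResults` carrying the trained network, the training history,
evaluation, prediction and attribution methods, and a ``summary()`` table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .architecture import build_model, load_model, summarize_model, validate_model_spec
from .attribution import AttributionResult, integrated_gradients, top_k_per_class
from .config import AttributionConfig, ModelSpec, RunConfig, TrainingConfig
from .evaluation import EvaluationReport, PredictionRecord, evaluate, predict
from .preprocessing import DatasetBundle, build_dataset
from .training import TrainingHistory, export_training_artifacts, train


class MultiBranchClassifier:
    """A multi-branch sequence classifier bound to a dataset.

    Parameters
    ----------
    bundle : DatasetBundle
        Output of the preprocessing stage (train/validation/evaluation/
        blackbox subsets of encoded samples).
    model_spec : ModelSpec
        Declarative architecture; validated on construction.
    training : TrainingConfig, optional
        Optimisation settings; defaults match the package defaults.
    seed : int
        Drives weight initialisation, dropout and batch shuffling.
    """

    def __init__(self, bundle: DatasetBundle, model_spec: ModelSpec,
                 training: TrainingConfig | None = None, seed: int = 0):
        violations = validate_model_spec(model_spec)
        if violations:
            raise ValueError("invalid model spec:\n  - " + "\n  - ".join(violations))
        missing = set(model_spec.branch_sections) - set(bundle.train[0].branches) \
            if bundle.train else set()
        if missing:
            raise ValueError(f"dataset lacks branches {sorted(missing)} the spec requires")
        self.bundle = bundle
        self.model_spec = model_spec
        self.training = training or TrainingConfig(seed=seed)
        self.seed = seed

    @classmethod
    def from_config(cls, config: RunConfig, bundle: DatasetBundle | None = None,
                    ) -> "MultiBranchClassifier":
        """Build from a run config, preprocessing the inputs it names unless a
        ready bundle is supplied."""
        if config.model is None:
            raise ValueError("run config carries no model spec")
        if bundle is None:
            bundle = build_dataset(config)
        return cls(bundle, config.model, config.training, seed=config.seed)

    def fit(self) -> "ClassifierResults":
        network = build_model(self.model_spec, seed=self.seed)
        network, history = train(network, self.bundle, self.training)
        return ClassifierResults(self, network, history)


class ClassifierResults:
    """Trained-model results: history, metrics, prediction and attribution."""

    def __init__(self, model: MultiBranchClassifier, network, history: TrainingHistory):
        self.model = model
        self.network = network
        self.history = history
        self._reports: dict[str, EvaluationReport] = {}

    @property
    def class_names(self) -> list[str]:
        return self.model.bundle.class_names

    def evaluate(self, subset: str = "evaluation") -> EvaluationReport:
        """ROC/PR evaluation on a labelled subset ('evaluation' by default;
        'blackbox' for the final, truly left-out check)."""
        if subset not in self._reports:
            samples = getattr(self.model.bundle, subset)
            self._reports[subset] = evaluate(self.network, samples,
                                             class_names=self.class_names)
        return self._reports[subset]

    def predict(self, samples) -> list[PredictionRecord]:
        return predict(self.network, samples, class_names=self.class_names)

    def attribute(self, sample, config: AttributionConfig | None = None,
                  ) -> AttributionResult:
        return integrated_gradients(self.network, sample, config)

    def attribute_top_k(self, subset: str = "evaluation", k: int = 10,
                        config: AttributionConfig | None = None,
                        ) -> list[AttributionResult]:
        """Integrated Gradients for the top-k predicted samples of each class."""
        samples = getattr(self.model.bundle, subset)
        records = self.predict(samples)
        picks = top_k_per_class(records, k=k)
        results = []
        for cls, indices in picks.items():
            cfg = (config or AttributionConfig()).model_copy(update={"target_class": cls})
            for i in indices:
                results.append(integrated_gradients(self.network, samples[i], cfg,
                                                    sample_id=records[i].sample_id))
        return results

    def save(self, session_dir, run_config: RunConfig | None = None,
             session_id: str = "") -> dict[str, Path]:
        """Export all training artifacts (model, history, plots, ledger row)."""
        metrics = {}
        if "evaluation" in self._reports:
            rep = self._reports["evaluation"]
            metrics = {"eval_accuracy": round(rep.accuracy, 6),
                       "eval_auroc_micro": round(rep.micro_auroc, 6)}
        return export_training_artifacts(
            self.network, self.model.model_spec, self.history, session_dir,
            run_config=run_config, metrics=metrics, session_id=session_id,
            seed=self.model.seed,
        )

    def summary(self) -> str:
        """Human-readable run summary: architecture, training trajectory tail
        and headline evaluation metrics."""
        h = self.history.table
        lines = [
            "Multi-branch sequence classifier",
            "=" * 40,
            summarize_model(self.model.model_spec),
            "-" * 40,
            f"epochs run: {self.history.n_epochs} "
            f"(best epoch {self.history.best_epoch}, "
            f"early stop: {self.history.stopped_early})",
            f"final train loss {h['train_loss'].iloc[-1]:.4f}, "
            f"val loss {h['val_loss'].iloc[-1]:.4f}, "
            f"val accuracy {h['val_accuracy'].iloc[-1]:.4f}",
        ]
        if "evaluation" in self._reports:
            rep = self._reports["evaluation"]
            lines.append(f"evaluation accuracy {rep.accuracy:.4f}, "
                         f"mean loss {rep.mean_loss:.4f}")
            for name in rep.auroc:
                lines.append(f"  {name}: AUROC {rep.auroc[name]:.4f}, "
                             f"AUPRC {rep.auprc[name]:.4f}")
            lines.append(f"  micro: AUROC {rep.micro_auroc:.4f}, "
                         f"AUPRC {rep.micro_auprc:.4f}")
        return "\n".join(lines)

    @classmethod
    def from_saved(cls, model_path, bundle: DatasetBundle) -> "ClassifierResults":
        """Re-attach a saved model to a dataset for re-evaluation or
        prediction (history is not persisted in the model file)."""
        import pandas as pd

        network, spec = load_model(model_path)
        model = MultiBranchClassifier(bundle, spec)
        empty = TrainingHistory(pd.DataFrame(
            columns=["epoch", "train_loss", "train_accuracy",
                     "val_loss", "val_accuracy", "lr"]), 0, False)
        return cls(model, network, empty)
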