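"""ROC/PR curves against the pairwise (Mann–Whitney) oracle, prediction
records, and report exports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import branchnet as bn
from branchnet.architecture import build_model
from branchnet.evaluation import (
    auc_trapezoid,
    evaluate,
    export_evaluation,
    export_predictions,
    pr_curve,
    predict,
    predict_from_fasta,
    roc_curve,
)


def mann_whitney_auc(labels, scores) -> float:
    """Independent oracle: fraction of (positive, negative) pairs ranked
    correctly, ties counted half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_separation_passes_through_0_1(self):
        pts = roc_curve([1, 1, 0, 0], [0.9, 0.8, 0.4, 0.3])
        assert any(np.allclose(p, (0, 1)) for p in pts)

    def test_reversed_scores_pass_through_1_0(self):
        pts = roc_curve([0, 0, 1, 1], [0.9, 0.8, 0.4, 0.3])
        assert any(np.allclose(p, (1, 0)) for p in pts)

    def test_tied_scores_collapse_to_one_point(self):
        pts = roc_curve([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert len(pts) == 2  # (0,0) anchor + single threshold point (1,1)

    def test_endpoints_and_monotonicity(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        pts = roc_curve(labels, rng.random(30))
        np.testing.assert_allclose(pts[0], (0, 0))
        np.testing.assert_allclose(pts[-1], (1, 1))
        assert (np.diff(pts[:, 0]) >= 0).all() and (np.diff(pts[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1, 1, 1], [0.1, 0.2, 0.3])


class TestPrCurve:
    def test_low_threshold_point_is_prevalence(self):
        pts = pr_curve([1, 0, 1, 0, 0], [0.9, 0.8, 0.7, 0.6, 0.5])
        recall, precision = pts[-1]
        assert recall == 1.0 and precision == pytest.approx(2 / 5)

    def test_tied_pair_single_point(self):
        pts = pr_curve([1, 0], [0.7, 0.7])
        assert pts.shape == (1, 2)
        np.testing.assert_allclose(pts[0], (1.0, 0.5))

    def test_recall_non_decreasing(self, rng):
        labels = rng.integers(0, 2, size=40)
        labels[0] = 1
        pts = pr_curve(labels, rng.random(40))
        assert (np.diff(pts[:, 0]) >= 0).all()

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pr_curve([0, 0], [0.1, 0.9])


class TestAucTrapezoid:
    def test_perfect_and_antiperfect(self):
        assert auc_trapezoid(roc_curve([1, 1, 0], [0.9, 0.8, 0.1])) == pytest.approx(1.0)
        assert auc_trapezoid(roc_curve([0, 0, 1], [0.9, 0.8, 0.1])) == pytest.approx(0.0)

    def test_worked_three_of_four_pairs(self):
        # positives scored (0.9, 0.4), negatives (0.8, 0.3): 3 of 4 pairs ordered
        labels = [1, 0, 1, 0]
        scores = [0.9, 0.8, 0.4, 0.3]
        assert auc_trapezoid(roc_curve(labels, scores)) == pytest.approx(0.75)
        assert mann_whitney_auc(labels, scores) == pytest.approx(0.75)

    def test_unsorted_points_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            auc_trapezoid(np.array([[0.5, 0.5], [0.2, 0.1], [1, 1]]))

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_equals_mann_whitney_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        # discretised scores force plenty of ties
        scores = rng.integers(0, 6, size=n) / 5.0
        auc = auc_trapezoid(roc_curve(labels, scores))
        assert auc == pytest.approx(mann_whitney_auc(labels, scores), abs=1e-9)

    def test_permutation_invariance(self, rng):
        labels = rng.integers(0, 2, size=25)
        labels[:2] = [0, 1]
        scores = rng.random(25)
        perm = rng.permutation(25)
        a = auc_trapezoid(roc_curve(labels, scores))
        b = auc_trapezoid(roc_curve(labels[perm], scores[perm]))
        assert a == pytest.approx(b, abs=1e-12)


class TestPredict:
    def _model(self, K=3):
        spec = bn.ModelSpec(
            input_length=10, n_classes=K,
            branch_sections={"sequence": [bn.LayerSpec(kind="dense", units=4)]},
            common_section=[])
        return build_model(spec, seed=1), spec

    def test_probabilities_sum_to_one(self, rng):
        model, spec = self._model(K=3)
        records = predict(model, {"sequence": rng.random((5, 10, 4))})
        assert len(records) == 5
        for r in records:
            assert r.probabilities.sum() == pytest.approx(1.0, abs=1e-6)

    def test_top_class_is_argmax_lowest_index_on_ties(self):
        rec = bn.EncodedSample({"sequence": np.zeros((10, 4))},
                               np.array([1.0, 0.0]), None)
        model, _ = self._model(K=2)
        # all-zero input gives identical logits: the tie must go to class 0
        records = predict(model, {"sequence": np.zeros((1, 10, 4))},
                          class_names=["a", "b"])
        assert records[0].top_class == "a"

    def test_evaluate_uniform_scores_give_half_auc(self, rng):
        model, _ = self._model(K=2)
        for p in model.parameters():
            p[...] = 0.0  # uniform 1/K output everywhere
        labels = np.eye(2)[rng.integers(0, 2, size=20)]
        report = evaluate(model, {"sequence": rng.random((20, 10, 4))}, labels=labels)
        assert report.accuracy == pytest.approx(labels[:, 0].mean())  # tie-break class
        for auc in report.auroc.values():
            assert auc == pytest.approx(0.5)

    def test_binary_class_aurocs_equal(self, trained_results):
        report = trained_results.evaluate("evaluation")
        aurocs = list(report.auroc.values())
        assert aurocs[0] == pytest.approx(aurocs[1], abs=1e-9)
        for a in list(report.auroc.values()) + [report.micro_auroc, report.micro_auprc]:
            assert 0.0 <= a <= 1.0

    def test_micro_equals_class_auc_for_calibrated_scorer(self, rng):
        """For a scorer consistent with the 0.5 threshold (all positives above,
        all negatives below), pooled micro-averaging reproduces the class AUC."""
        p_pos = 0.5 + 0.5 * rng.random(15)
        p_neg = 0.5 * rng.random(12)
        labels = np.array([1] * 15 + [0] * 12)
        p0 = np.concatenate([p_pos, p_neg])
        class_auc = auc_trapezoid(roc_curve(labels, p0))
        pooled_labels = np.concatenate([labels, 1 - labels])
        pooled_scores = np.concatenate([p0, 1 - p0])
        micro = auc_trapezoid(roc_curve(pooled_labels, pooled_scores))
        assert micro == pytest.approx(class_auc, abs=1e-9)


class TestPredictFromFasta:
    def test_sequence_only_model_accepts_fasta(self, tmp_path):
        spec = bn.ModelSpec(
            input_length=12, n_classes=2,
            branch_sections={"sequence": [bn.LayerSpec(kind="conv", filters=4, kernel_size=3)]},
            common_section=[bn.LayerSpec(kind="dense", units=4)])
        model = build_model(spec, seed=2)
        fasta = tmp_path / "q.fa"
        fasta.write_text(">s1\nACGTACGTACGT\n>s2\nTTTTACGTAAAA\n")
        records = predict_from_fasta(model, fasta)
        assert [r.sample_id for r in records] == ["s1", "s2"]

    def test_conservation_model_refused(self, tmp_path):
        spec = bn.ModelSpec(
            input_length=12, n_classes=2,
            branch_sections={"sequence": [bn.LayerSpec(kind="dense", units=4)],
                             "conservation": [bn.LayerSpec(kind="dense", units=4)]},
            common_section=[])
        model = build_model(spec, seed=2)
        fasta = tmp_path / "q.fa"
        fasta.write_text(">s1\nACGTACGTACGT\n")
        with pytest.raises(ValueError, match="conservation"):
            predict_from_fasta(model, fasta)

    def test_wrong_length_names_record(self, tmp_path):
        spec = bn.ModelSpec(
            input_length=12, n_classes=2,
            branch_sections={"sequence": [bn.LayerSpec(kind="dense", units=4)]},
            common_section=[])
        model = build_model(spec, seed=2)
        fasta = tmp_path / "q.fa"
        fasta.write_text(">short_one\nACGTACGTACG\n")
        with pytest.raises(ValueError, match="short_one"):
            predict_from_fasta(model, fasta)


class TestExports:
    def test_predictions_tsv_shape_and_precision(self, tmp_path, rng):
        from branchnet.evaluation import PredictionRecord
        records = [PredictionRecord(f"s{i}", np.array([0.25, 0.75]), "b")
                   for i in range(10)]
        out = tmp_path / "pred.tsv"
        export_predictions(records, out, class_names=["a", "b"])
        frame = pd.read_csv(out, sep="\t", dtype=str)
        assert frame.shape == (10, 4)
        assert frame["p_b"].iloc[0] == "0.750000"

    def test_empty_records_header_only(self, tmp_path):
        out = tmp_path / "pred.tsv"
        export_predictions([], out, class_names=["a", "b"])
        assert pd.read_csv(out, sep="\t").empty

    def test_evaluation_export_files(self, trained_results, tmp_path):
        report = trained_results.evaluate("evaluation")
        paths = export_evaluation(report, tmp_path)
        for key in ("metrics", "roc_plot", "pr_plot", "roc_micro", "pr_micro"):
            assert paths[key].exists()
        metrics = pd.read_csv(paths["metrics"], sep="\t")
        assert {"accuracy", "mean_loss"} <= set(metrics["metric"])
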