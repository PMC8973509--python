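"""Shared test fixtures: a small synthetic study system and a model trained
on it, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

import branchnet as bn


@pytest.fixture(scope="session")
def small_spec() -> bn.FixtureSpec:
    return bn.FixtureSpec(n_chroms=4, chrom_length=20_000, n_per_class=60,
                          window=150, motif="TGCATGC", seed=7)


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    return bn.make_fixture(small_spec)


@pytest.fixture(scope="session")
def seq_bundle(small_fixture) -> bn.DatasetBundle:
    """Sequence-only dataset from the small fixture, default 70/15/10/5 split."""
    cfg = bn.RunConfig()
    cfg.preprocessing.branches = ["sequence"]
    return bn.build_dataset(cfg, reference=small_fixture.genome,
                            intervals=small_fixture.intervals)


@pytest.fixture(scope="session")
def conv_spec() -> bn.ModelSpec:
    return bn.ModelSpec(
        input_length=150,
        n_classes=2,
        branch_sections={"sequence": [bn.LayerSpec(kind="conv", filters=16, kernel_size=8)]},
        common_section=[bn.LayerSpec(kind="dense", units=16)],
    )


@pytest.fixture(scope="session")
def trained_results(seq_bundle, conv_spec) -> bn.ClassifierResults:
    """A small convolutional model trained on the planted-motif data."""
    clf = bn.MultiBranchClassifier(
        seq_bundle, conv_spec,
        bn.TrainingConfig(epochs=15, batch_size=16, optimizer="adam",
                          learning_rate=1e-3, seed=3),
        seed=3,
    )
    return clf.fit()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
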