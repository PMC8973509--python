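"""Build a trainable multi-branch classifier from a declarative ModelSpec.

The grammar per section is convolutional layers first, then recurrent, then
dense; the common section (applied after the flattened branch outputs are
concatenated) admits dense and recurrent layers only. A softmax output layer
with one unit per class is appended automatically and categorical
cross-entropy is the fixed training loss.

Layer internals follow documented conventions so builds are reproducible:
convolutions use 'same' padding with stride 1 and ReLU; hidden dense layers
use ReLU; batch normalisation (when flagged) sits before the activation and
dropout after it; recurrent layers return the full sequence except the last
recurrent layer of a section; weights are Glorot-uniform initialised from the
run seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .config import BRANCH_NAMES, LayerSpec, ModelSpec
from .nn import (
    BatchNorm,
    Bidirectional,
    BranchNetwork,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    GRU,
    LSTM,
    ReLU,
    Reshape3D,
    Sequential,
)
from .preprocessing import BRANCH_CHANNELS

_KIND_RANK = {"conv": 0, "recurrent": 1, "dense": 2}


def validate_model_spec(spec: ModelSpec) -> list[str]:
    """Return the list of grammar violations (empty means valid)."""
    violations: list[str] = []
    if spec.n_classes < 2:
        violations.append(f"n_classes must be >= 2, got {spec.n_classes}")
    if spec.input_length < 1:
        violations.append("input_length must be positive")
    if not spec.branch_sections:
        violations.append("at least one branch section is required")
    unknown = set(spec.branch_sections) - set(BRANCH_NAMES)
    if unknown:
        violations.append(f"unknown branch name(s) {sorted(unknown)}; allowed: {BRANCH_NAMES}")

    def check_order(name: str, layers: list[LayerSpec]):
        ranks = [_KIND_RANK[l.kind] for l in layers]
        if any(a > b for a, b in zip(ranks, ranks[1:])):
            violations.append(
                f"section '{name}': layer order must be conv -> recurrent -> dense"
            )

    for name, layers in spec.branch_sections.items():
        check_order(name, layers)
        if not layers and not spec.common_section:
            violations.append(f"branch section '{name}' is empty and there are no common layers")
        for l in layers:
            if l.kind == "conv" and l.kernel_size > spec.input_length:
                violations.append(
                    f"section '{name}': kernel_size {l.kernel_size} exceeds input length "
                    f"{spec.input_length}"
                )
    check_order("common", spec.common_section)
    if any(l.kind == "conv" for l in spec.common_section):
        violations.append("convolutional layers are not allowed in the common section")
    return violations


def _append_layer(layers: list, lspec: LayerSpec, shape: tuple, is_last_recurrent: bool,
                  init_rng: np.random.Generator, dropout_rng: np.random.Generator) -> tuple:
    """Translate one LayerSpec into primitive layers; returns the new shape."""
    if lspec.kind == "conv":
        L, C = shape
        layers.append(Conv1D(C, lspec.filters, lspec.kernel_size, init_rng))
        if lspec.batch_norm:
            layers.append(BatchNorm(lspec.filters))
        layers.append(ReLU())
        shape = (L, lspec.filters)
    elif lspec.kind == "recurrent":
        if len(shape) == 1:  # common section opening with a recurrent layer
            layers.append(Reshape3D())
            shape = (shape[0], 1)
        L, C = shape
        cell_cls = {"GRU": GRU, "LSTM": LSTM}[lspec.recurrent_cell]
        return_sequences = not is_last_recurrent
        if lspec.bidirectional:
            fwd = cell_cls(C, lspec.units, init_rng, return_sequences=return_sequences)
            bwd = cell_cls(C, lspec.units, init_rng, return_sequences=return_sequences)
            layers.append(Bidirectional(fwd, bwd))
            width = 2 * lspec.units
        else:
            layers.append(cell_cls(C, lspec.units, init_rng, return_sequences=return_sequences))
            width = lspec.units
        if lspec.batch_norm:
            layers.append(BatchNorm(width))
        shape = (L, width) if return_sequences else (width,)
    else:  # dense
        if len(shape) > 1:
            layers.append(Flatten())
            shape = (int(np.prod(shape)),)
        layers.append(Dense(shape[0], lspec.units, init_rng))
        if lspec.batch_norm:
            layers.append(BatchNorm(lspec.units))
        layers.append(ReLU())
        shape = (lspec.units,)
    if lspec.dropout_rate > 0:
        layers.append(Dropout(lspec.dropout_rate, dropout_rng))
    return shape


def _build_section(specs: list[LayerSpec], shape: tuple,
                   init_rng, dropout_rng) -> tuple[Sequential, tuple]:
    layers: list = []
    last_recurrent = max(
        (i for i, l in enumerate(specs) if l.kind == "recurrent"), default=None
    )
    for i, lspec in enumerate(specs):
        shape = _append_layer(layers, lspec, shape, i == last_recurrent,
                              init_rng, dropout_rng)
    if len(shape) > 1:
        layers.append(Flatten())
        shape = (int(np.prod(shape)),)
    return Sequential(layers), shape


def build_model(spec: ModelSpec, seed: int = 0) -> BranchNetwork:
    """Construct the differentiable classifier a valid spec describes.

    Two builds from the same (spec, seed) agree parameter-by-parameter.
    """
    violations = validate_model_spec(spec)
    if violations:
        raise ValueError("invalid model spec:\n  - " + "\n  - ".join(violations))
    init_rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    dropout_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))

    branches: dict[str, Sequential] = {}
    input_shapes: dict[str, tuple[int, int]] = {}
    widths = []
    for name in BRANCH_NAMES:  # fixed order, independent of dict order
        if name not in spec.branch_sections:
            continue
        shape0 = (spec.input_length, BRANCH_CHANNELS[name])
        input_shapes[name] = shape0
        section, shape = _build_section(spec.branch_sections[name], shape0,
                                        init_rng, dropout_rng)
        branches[name] = section
        widths.append(shape[0])

    common, common_shape = _build_section(spec.common_section, (sum(widths),),
                                          init_rng, dropout_rng)
    head = Dense(common_shape[0], spec.n_classes, init_rng)
    return BranchNetwork(branches, common, head, dropout_rng, spec.n_classes, input_shapes)


def summarize_model(spec: ModelSpec) -> str:
    """Plain-text architecture summary (exported alongside every model)."""
    lines = [f"input length: {spec.input_length} bp, classes: {spec.n_classes}"]
    for name in spec.branch_sections:
        lines.append(f"branch [{name}] ({spec.input_length} x {BRANCH_CHANNELS[name]}):")
        for l in spec.branch_sections[name]:
            lines.append("  " + _layer_line(l))
    lines.append("concatenate -> common section:")
    for l in spec.common_section:
        lines.append("  " + _layer_line(l))
    lines.append(f"output: dense({spec.n_classes}) + softmax")
    return "\n".join(lines)


def _layer_line(l: LayerSpec) -> str:
    if l.kind == "conv":
        base = f"conv(filters={l.filters}, kernel={l.kernel_size}, padding=same, relu)"
    elif l.kind == "recurrent":
        wrap = "bidirectional " if l.bidirectional else ""
        base = f"{wrap}{l.recurrent_cell}(units={l.units})"
    else:
        base = f"dense(units={l.units}, relu)"
    extras = []
    if l.batch_norm:
        extras.append("batch_norm")
    if l.dropout_rate > 0:
        extras.append(f"dropout={l.dropout_rate}")
    return base + (f" [{', '.join(extras)}]" if extras else "")


# ---------------------------------------------------------------------------
# Serialisation


def save_model(network: BranchNetwork, spec: ModelSpec, path, seed: int = 0) -> None:
    """Write weights (npz) plus a YAML sidecar of the producing ModelSpec."""
    path = Path(path)
    arrays = {f"arr_{i}": a for i, a in enumerate(network.state_arrays())}
    np.savez_compressed(path, **arrays)
    sidecar = {"model_spec": spec.model_dump(mode="json"), "seed": seed}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))


def load_model(path) -> tuple[BranchNetwork, ModelSpec]:
    path = Path(path)
    sidecar = yaml.safe_load(path.with_suffix(".yaml").read_text())
    spec = ModelSpec(**sidecar["model_spec"])
    network = build_model(spec, seed=int(sidecar.get("seed", 0)))
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        arrays = [data[f"arr_{i}"] for i in range(len(data.files))]
    network.set_state_arrays(arrays)
    return network, spec
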