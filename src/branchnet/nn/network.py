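"""Multi-branch network container: per-branch sections, a common section after
concatenation, and a linear output head whose softmax gives class probabilities.
"""

from __future__ import annotations

import numpy as np

from .layers import Dense, Sequential


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class BranchNetwork:
    """A differentiable classifier over named input branches.

    Parameters
    ----------
    branches : dict
        Ordered ``branch name -> Sequential`` mapping; every section must end
        with a 2-D activation (the builder guarantees this with ``Flatten``).
    common : Sequential
        Section applied to the concatenated branch outputs.
    head : Dense
        Linear output layer with one unit per class; ``predict_proba`` applies
        the softmax, while :meth:`logits` exposes the pre-softmax scores that
        attribution differentiates.
    rng : numpy.random.Generator
        Generator shared with the dropout layers.
    """

    def __init__(self, branches: dict[str, Sequential], common: Sequential, head: Dense,
                 rng: np.random.Generator, n_classes: int, input_shapes: dict[str, tuple[int, int]]):
        self.branches = branches
        self.common = common
        self.head = head
        self.rng = rng
        self.n_classes = n_classes
        self.input_shapes = input_shapes
        self._widths: list[int] = []

    # -- forward / backward -------------------------------------------------
    def _check_inputs(self, inputs: dict[str, np.ndarray]) -> None:
        # A dataset may carry more branches than the model consumes; the
        # extras are ignored. A branch the model needs must be present.
        missing = set(self.branches) - set(inputs)
        if missing:
            raise ValueError(
                f"missing input branch(es) {sorted(missing)}; model requires "
                f"{sorted(self.branches)}"
            )
        for name, (L, C) in self.input_shapes.items():
            if inputs[name].shape[1:] != (L, C):
                raise ValueError(
                    f"branch '{name}' expects shape (batch, {L}, {C}), got {inputs[name].shape}"
                )

    def forward(self, inputs: dict[str, np.ndarray], training: bool = False) -> np.ndarray:
        """Return logits of shape ``(batch, n_classes)``."""
        self._check_inputs(inputs)
        outs = []
        self._widths = []
        for name, section in self.branches.items():
            y = section.forward(np.asarray(inputs[name], dtype=float), training=training)
            self._widths.append(y.shape[1])
            outs.append(y)
        z = np.concatenate(outs, axis=1) if len(outs) > 1 else outs[0]
        z = self.common.forward(z, training=training)
        return self.head.forward(z, training=training)

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Backpropagate ``dlogits`` and return gradients w.r.t. each input branch."""
        dz = self.head.backward(dlogits)
        dz = self.common.backward(dz)
        dinputs = {}
        offset = 0
        for (name, section), width in zip(self.branches.items(), self._widths):
            dinputs[name] = section.backward(dz[:, offset : offset + width])
            offset += width
        return dinputs

    # -- inference ----------------------------------------------------------
    def logits(self, inputs, batch_size: int | None = None) -> np.ndarray:
        if batch_size is None:
            return self.forward(inputs, training=False)
        n = next(iter(inputs.values())).shape[0]
        parts = [
            self.forward({k: v[i : i + batch_size] for k, v in inputs.items()}, training=False)
            for i in range(0, n, batch_size)
        ]
        return np.concatenate(parts, axis=0)

    def predict_proba(self, inputs, batch_size: int | None = 256) -> np.ndarray:
        return softmax(self.logits(inputs, batch_size=batch_size))

    def input_gradients(self, inputs: dict[str, np.ndarray], target_class: int) -> dict[str, np.ndarray]:
        """Gradient of the target-class logit w.r.t. every input element.

        Rows of the batch are independent, so differentiating the *sum* of the
        target logit over the batch gives each row its own gradient.
        """
        logits = self.forward(inputs, training=False)
        if not np.all(np.isfinite(logits)):
            raise FloatingPointError("non-finite logits in attribution forward pass")
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        grads = self.backward(dlogits)
        for name, g in grads.items():
            if not np.all(np.isfinite(g)):
                raise FloatingPointError(f"non-finite gradient for branch '{name}'")
        return grads

    # -- loss ---------------------------------------------------------------
    def loss_and_grad(self, logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
        """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
        p = softmax(logits)
        n = logits.shape[0]
        loss = -np.sum(labels * np.log(np.clip(p, 1e-12, None))) / n
        return loss, (p - labels) / n

    # -- parameter plumbing --------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out = []
        for section in self.branches.values():
            out.extend(section.params)
        out.extend(self.common.params)
        out.extend(self.head.params)
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for section in self.branches.values():
            out.extend(section.grads)
        out.extend(self.common.grads)
        out.extend(self.head.grads)
        return out

    def zero_grad(self) -> None:
        for g in self.gradients():
            g[...] = 0.0

    def all_layers(self):
        for section in list(self.branches.values()) + [self.common]:
            yield from section.layers
        yield self.head

    def state_arrays(self) -> list[np.ndarray]:
        """Parameters plus batch-norm running statistics, for serialisation."""
        out = list(self.parameters())
        for layer in self.all_layers():
            if hasattr(layer, "running_mean"):
                out.extend([layer.running_mean, layer.running_var])
        return out

    def set_state_arrays(self, arrays: list[np.ndarray]) -> None:
        n = len(self.parameters())
        self.set_weights(arrays[:n])
        rest = list(arrays[n:])
        for layer in self.all_layers():
            if hasattr(layer, "running_mean"):
                layer.running_mean = rest.pop(0).copy()
                layer.running_var = rest.pop(0).copy()
        if rest:
            raise ValueError("state array list length mismatch")

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            p[...] = w
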