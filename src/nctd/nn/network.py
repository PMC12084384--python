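"""Sequential network container, softmax cross-entropy loss and Adam."""

from __future__ import annotations

import numpy as np

from .layers import DTYPE, Layer

__all__ = ["Sequential", "SoftmaxCrossEntropy", "Adam", "softmax"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities in evaluation mode (running batch-norm stats)."""
        chunks = []
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start : start + batch_size], train=False)
            chunks.append(softmax(logits))
        return np.concatenate(chunks, axis=0)

    def named_parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.parameters().items():
                out[f"layer{i}.{name}"] = arr
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        """All parameters and buffers, for checkpointing."""
        out = dict(self.named_parameters())
        for i, layer in enumerate(self.layers):
            for name, arr in layer.state().items():
                out[f"layer{i}.{name}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.parameters():
                layer.parameters()[name][...] = state[f"layer{i}.{name}"]
            for name in layer.state():
                layer.state()[name][...] = state[f"layer{i}.{name}"]

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_dict().items()}


class SoftmaxCrossEntropy:
    """Categorical cross-entropy on logits with the fused softmax gradient."""

    def forward(self, logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
        probs = softmax(logits.astype(np.float64))
        eps = 1e-12
        loss = float(-(onehot * np.log(probs + eps)).sum() / logits.shape[0])
        grad = ((probs - onehot) / logits.shape[0]).astype(DTYPE)
        return loss, grad


class Adam:
    """Adam optimizer with bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(
        self,
        network: Sequential,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.network = network
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        correction = np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for i, layer in enumerate(self.network.layers):
            params = layer.parameters()
            grads = layer.gradients()
            for name, param in params.items():
                key = f"layer{i}.{name}"
                g = grads[name]
                m = self._m.setdefault(key, np.zeros_like(param))
                v = self._v.setdefault(key, np.zeros_like(param))
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                param -= (self.lr * correction) * m / (np.sqrt(v) + self.eps)
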