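"""Sequential container, losses and the Adam optimizer."""

from __future__ import annotations

import numpy as np

from .layers import Layer


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers for name in layer.params]

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping for serialization."""
        return {
            f"layer{idx}.{name}": layer.params[name]
            for idx, layer in enumerate(self.layers)
            for name in layer.params
        }

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for idx, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{idx}.{name}"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy over the batch; returns (loss, dlogits, probs)."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n, probs


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean squared error over all elements; returns (loss, dpred)."""
    diff = pred - target
    loss = float(np.mean(diff ** 2))
    return loss, 2.0 * diff / diff.size


class Adam:
    def __init__(self, net: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()}
                   for l in net.layers if l.params}
        self._v = {id(l): {k: np.zeros_like(v) for k, v in l.params.items()}
                   for l in net.layers if l.params}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for layer in self.net.layers:
            if not layer.params:
                continue
            m, v = self._m[id(layer)], self._v[id(layer)]
            for name, p in layer.params.items():
                g = layer.grads[name]
                m[name] = b1 * m[name] + (1 - b1) * g
                v[name] = b2 * v[name] + (1 - b2) * g ** 2
                p -= self.lr * (m[name] / corr1) / (np.sqrt(v[name] / corr2) + self.eps)
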