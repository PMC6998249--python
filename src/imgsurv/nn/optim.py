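"""Adam optimizer over a Sequential's trainable layers."""

from __future__ import annotations

import numpy as np

from .network import Sequential


class Adam:
    def __init__(self, net: Sequential, lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8) -> None:
        self.net = net
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self) -> None:
        """Apply one update from the gradients currently stored in the
        network's trainable layers."""
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, layer, pname, arr in self.net.named_params(trainable_only=True):
            g = layer.grads.get(pname)
            if g is None:
                continue
            m = self._m.setdefault(key, np.zeros_like(arr))
            v = self._v.setdefault(key, np.zeros_like(arr))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            arr -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(arr.dtype)
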