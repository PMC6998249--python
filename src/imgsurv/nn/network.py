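"""A named sequential container with save/load and parameter hashing."""

from __future__ import annotations

import hashlib

import numpy as np

from .layers import Layer


class Sequential:
    def __init__(self, layers: list[tuple[str, Layer]]) -> None:
        names = [n for n, _ in layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        self.layers = layers

    def __getitem__(self, name: str) -> Layer:
        for n, layer in self.layers:
            if n == name:
                return layer
        raise KeyError(name)

    def forward(self, x: np.ndarray, train: bool = False,
                upto: str | None = None) -> np.ndarray:
        """Run the network; with ``upto`` set, stop after (and return the
        output of) the named layer."""
        for name, layer in self.layers:
            x = layer.forward(x, train)
            if name == upto:
                return x
        if upto is not None:
            raise KeyError(upto)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    # -- parameter bookkeeping ------------------------------------------------

    def named_params(self, trainable_only: bool = False):
        for name, layer in self.layers:
            if trainable_only and not layer.trainable:
                continue
            for pname, arr in layer.params.items():
                yield f"{name}.{pname}", layer, pname, arr

    def n_parameters(self, trainable_only: bool = False) -> int:
        return sum(arr.size for *_, arr in self.named_params(trainable_only))

    def set_trainable(self, names: set[str] | None) -> None:
        """Restrict trainable layers to ``names`` (None = everything with
        parameters trainable)."""
        for name, layer in self.layers:
            if not layer.params:
                continue
            layer.trainable = names is None or name in names

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, layer in self.layers:
            for pname, arr in layer.params.items():
                state[f"{name}.{pname}"] = arr.copy()
            for bname, arr in layer.buffers.items():
                state[f"{name}.buffer.{bname}"] = arr.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.layers:
            for pname in layer.params:
                layer.params[pname] = state[f"{name}.{pname}"].copy()
            for bname in layer.buffers:
                layer.buffers[bname] = state[f"{name}.buffer.{bname}"].copy()

    def param_hash(self, layer_names: set[str] | None = None) -> str:
        """SHA-256 over the raw bytes of parameters and buffers, optionally
        restricted to the given layers. Bit-exact change detection."""
        digest = hashlib.sha256()
        state = self.state_dict()
        for key in sorted(state):
            lname = key.split(".")[0]
            if layer_names is not None and lname not in layer_names:
                continue
            digest.update(key.encode())
            digest.update(np.ascontiguousarray(state[key]).tobytes())
        return digest.hexdigest()
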