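"""Parameterized layers built on the autodiff Tensor."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["Module", "Conv2d", "InstanceNorm2d", "Embedding", "same_pad"]


def same_pad(kernel: int) -> tuple:
    """(top, bottom, left, right) padding keeping H, W under stride 1.

    Even kernels pad asymmetrically (one less before than after).
    """
    lo = (kernel - 1) // 2
    hi = kernel - 1 - lo
    return (lo, hi, lo, hi)


class Module:
    """Tiny parameter-container base; subclasses register Tensor attributes."""

    def parameters(self) -> list:
        params = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def state_arrays(self) -> list:
        """All parameter arrays in a deterministic order (for checkpoints)."""
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint has {len(arrays)} arrays, model needs {len(params)}"
            )
        for p, a in zip(params, arrays):
            a = np.asarray(a, dtype=p.data.dtype)
            if a.shape != p.data.shape:
                raise ValueError(f"shape mismatch {a.shape} vs {p.data.shape}")
            p.data = a

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad=None, rng: np.random.Generator = None, bias: bool = True,
                 trainable: bool = True):
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stacks
        w = rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel))
        self.weight = Tensor(w.astype(np.float32), requires_grad=trainable)
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=trainable)
            if bias else None
        )
        self.stride = stride
        self.pad = same_pad(kernel) if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, pad=self.pad)

    def parameters(self):
        params = [self.weight] if self.weight.requires_grad else []
        if self.bias is not None and self.bias.requires_grad:
            params.append(self.bias)
        return params


class InstanceNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.instance_norm(self.gamma, self.beta, eps=self.eps)

    def parameters(self):
        return [self.gamma, self.beta]


class Embedding(Module):
    """Trainable lookup table: integer index -> vector."""

    def __init__(self, n_rows: int, dim: int, rng: np.random.Generator = None,
                 init: str = "ones"):
        rng = rng if rng is not None else np.random.default_rng(0)
        if init == "ones":
            # start at identity gating so conditioning perturbs a working net
            table = np.ones((n_rows, dim), dtype=np.float32)
            table += rng.normal(0.0, 0.01, size=table.shape).astype(np.float32)
        else:
            table = rng.normal(0.0, 1.0, size=(n_rows, dim)).astype(np.float32)
        self.table = Tensor(table, requires_grad=True)

    def __call__(self, idx) -> Tensor:
        return self.table.take_rows(idx)

    def parameters(self):
        return [self.table]
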