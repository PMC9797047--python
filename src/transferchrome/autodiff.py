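"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine provides exactly the primitives the network needs: dense (linear)
layers, 1D convolution with "same" padding, max pooling, ReLU/sigmoid,
softmax, batched matrix products for attention, dropout, concatenation along
the channel axis, a gradient reversal op, and a numerically stable binary
cross-entropy on logits.  All arithmetic is float64; gradients are accumulated
by a topological-order sweep over the tape.

Gradient correctness of every primitive is pinned by central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "add",
    "scale",
    "concat",
    "conv1d",
    "linear",
    "relu",
    "sigmoid",
    "max_pool1d",
    "dropout",
    "reshape",
    "transpose",
    "bmm",
    "softmax",
    "grad_reverse",
    "bce_with_logits",
    "SGD",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self._parents
        )

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Accumulate gradients into every reachable node with requires_grad."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a seed gradient requires a scalar")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep under many epochs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy()
    else:
        t.grad += g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    if out_data.shape != a.data.shape or out_data.shape != b.data.shape:
        raise ValueError("add requires identical shapes")

    def backward(g):
        _accumulate(a, g)
        _accumulate(b, g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(idx)])

    return Tensor(data, parents=tuple(tensors), backward=backward)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 1D convolution.

    x: (batch, in_channels, length); w: (out_channels, in_channels, k) with k
    odd; b: (out_channels,).  Output length equals input length.
    """
    B, C, L = x.data.shape
    O, C2, K = w.data.shape
    if C != C2:
        raise ValueError(f"conv1d channel mismatch: input {C}, kernel {C2}")
    if K % 2 != 1:
        raise ValueError("conv1d requires an odd kernel length for same padding")
    pad = K // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad)))
    # cols: (B, C, L, K) sliding windows
    cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)
    out = np.einsum("bclk,ock->bol", cols, w.data, optimize=True)
    out += b.data[None, :, None]

    def backward(g):
        if b.requires_grad:
            _accumulate(b, g.sum(axis=(0, 2)))
        if w.requires_grad:
            _accumulate(w, np.einsum("bclk,bol->ock", cols, g, optimize=True))
        if x.requires_grad:
            gcols = np.einsum("ock,bol->bclk", w.data, g, optimize=True)
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k : k + L] += gcols[:, :, :, k]
            _accumulate(x, gxp[:, :, pad : pad + L] if pad else gxp)

    return Tensor(out, parents=(x, w, b), backward=backward)


def linear(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """x: (batch, in_features) @ w: (in_features, out_features) + b."""
    out = x.data @ w.data + b.data

    def backward(g):
        if b.requires_grad:
            _accumulate(b, g.sum(axis=0))
        if w.requires_grad:
            _accumulate(w, x.data.T @ g)
        if x.requires_grad:
            _accumulate(x, g @ w.data.T)

    return Tensor(out, parents=(x, w, b), backward=backward)


def scale(x: Tensor, c: float) -> Tensor:
    def backward(g):
        _accumulate(x, g * c)

    return Tensor(x.data * c, parents=(x,), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        _accumulate(x, g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 0.5 * (np.tanh(0.5 * x.data) + 1.0)  # stable logistic

    def backward(g):
        _accumulate(x, g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=backward)


def max_pool1d(x: Tensor, length: int = 2) -> Tensor:
    """Non-overlapping max pooling along the last axis (stride = length)."""
    B, C, L = x.data.shape
    if L % length != 0:
        raise ValueError(f"pooling length {length} does not divide signal length {L}")
    win = x.data.reshape(B, C, L // length, length)
    arg = win.argmax(axis=3)
    out = np.take_along_axis(win, arg[..., None], axis=3)[..., 0]

    def backward(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, arg[..., None], g[..., None], axis=3)
        _accumulate(x, gwin.reshape(B, C, L))

    return Tensor(out, parents=(x,), backward=backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (evaluation mode)."""
    if rng is None or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)

    def backward(g):
        _accumulate(x, g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=backward)


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape

    def backward(g):
        _accumulate(x, g.reshape(orig))

    return Tensor(x.data.reshape(shape), parents=(x,), backward=backward)


def transpose(x: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def backward(g):
        _accumulate(x, g.transpose(inv))

    return Tensor(x.data.transpose(axes), parents=(x,), backward=backward)


def bmm(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product: (B,N,K) @ (B,K,M) -> (B,N,M)."""
    out = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            _accumulate(a, g @ b.data.transpose(0, 2, 1))
        if b.requires_grad:
            _accumulate(b, a.data.transpose(0, 2, 1) @ g)

    return Tensor(out, parents=(a, b), backward=backward)


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        _accumulate(x, s * (g - (g * s).sum(axis=-1, keepdims=True)))

    return Tensor(s, parents=(x,), backward=backward)


def grad_reverse(x: Tensor, lam: float) -> Tensor:
    """Identity in the forward pass; scales the backward gradient by -lam."""
    if lam < 0:
        raise ValueError("gradient reversal strength must be nonnegative")

    def backward(g):
        _accumulate(x, -lam * g)

    return Tensor(x.data.copy(), parents=(x,), backward=backward)


def bce_with_logits(
    logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None
) -> Tensor:
    """Mean binary cross-entropy computed from logits.

    Equals -[y log s + (1-y) log(1-s)] with s = sigmoid(logit), evaluated in
    the log-sum-exp form so extreme logits cannot produce log(0).  `weights`
    (same shape as targets) selects/weights samples; the mean is taken over
    the total weight.
    """
    z = logits.data
    y = np.asarray(targets, dtype=np.float64)
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=np.float64)
    total = w.sum()
    if total <= 0:
        raise ValueError("bce_with_logits requires positive total weight")
    # log(1 + exp(-|z|)) + max(z, 0) - z*y
    per = np.logaddexp(0.0, -np.abs(z)) + np.maximum(z, 0.0) - z * y
    out = (w * per).sum() / total

    def backward(g):
        s = 0.5 * (np.tanh(0.5 * z) + 1.0)
        _accumulate(logits, g * w * (s - y) / total)

    return Tensor(out, parents=(logits,), backward=backward)


class SGD:
    """Stochastic gradient descent with classical momentum and L2 weight decay.

    The decay term is added to the raw gradient before the momentum update,
    matching the common deep-learning convention.
    """

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 0.001,
        momentum: float = 0.85,
        weight_decay: float = 0.001,
        clip_norm: float | None = 5.0,
    ):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        # global-norm gradient clipping: the unscaled attention logits can
        # produce rare very large gradients once the softmax saturates
        if self.clip_norm is not None:
            sq = sum(
                float(np.sum(p.grad * p.grad))
                for p in self.params
                if p.grad is not None
            )
            norm = np.sqrt(sq)
            if norm > self.clip_norm:
                factor = self.clip_norm / norm
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= factor
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
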