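"""The network: dense-conv feature extractor, self-attention, and the
label / domain classification heads with gradient reversal.

Architecture (default configuration), for a 5-mark x 100-bin input:

    position encoding (append 1 relative-distance channel)   ->  6 x 100
    dense-conv block, 3 layers of 32/16/8 kernels (len 5),
      each layer sees the concatenation of all previous maps  -> 62 x 100
    conv 50 kernels (len 5) + ReLU + dropout 0.4              -> 50 x 100
    max pool (len 2)                                          -> 50 x 50
    self-attention x 2 (conv_q/conv_k half channels, conv_v
      full channels, kernel len 1, softmax(Q^T K) V)          -> 50 x 50
    flatten + linear                                          -> 128 features

    label head:  128 -> 100 -> 50 -> 1 (sigmoid)
    domain head: GRL(lambda) -> 128 -> 50 -> 1 (sigmoid)

The gradient reversal layer (GRL) is the identity forward and multiplies the
backward gradient by -lambda, so minimizing the domain loss trains the
domain head as a discriminator while training the extractor to produce
domain-invariant features.

Dense-block and position-encoding variants used in ablations are selectable
through :class:`ModelConfig` (aliases: alpha = sinusoidal encoding, beta = no
encoding, v1 = dense 50/50/50, v2 = a single 50-kernel conv, v3 = three
plain 50-kernel convs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor

DENSE_BLOCK_VARIANTS = (
    "dense_32_16_8",
    "dense_50_50_50",
    "single_conv_50",
    "plain_3x_conv_50",
)
POSITION_ENCODING_MODES = ("relative_distance", "sinusoidal", "none")

VARIANT_ALIASES = {
    "default": {},
    "alpha": {"position_encoding": "sinusoidal"},
    "beta": {"position_encoding": "none"},
    "v1": {"dense_block": "dense_50_50_50"},
    "v2": {"dense_block": "single_conv_50"},
    "v3": {"dense_block": "plain_3x_conv_50"},
}


@dataclass
class ModelConfig:
    """Architecture hyperparameters, including ablation-variant switches."""

    n_marks: int = 5
    n_bins: int = 100
    dense_block: str = "dense_32_16_8"
    conv_kernels: int = 50
    conv_length: int = 5
    pool_length: int = 2
    dropout_rate: float = 0.4
    n_attention_layers: int = 2
    position_encoding: str = "relative_distance"
    scaled_attention: bool = False
    feature_dim: int = 128
    label_head_dims: tuple[int, int] = (100, 50)
    domain_head_dim: int = 50
    lambda_grl: float = 1.0

    def __post_init__(self):
        if self.dense_block not in DENSE_BLOCK_VARIANTS:
            raise ValueError(f"unknown dense_block variant {self.dense_block!r}")
        if self.position_encoding not in POSITION_ENCODING_MODES:
            raise ValueError(f"unknown position_encoding {self.position_encoding!r}")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.lambda_grl < 0:
            raise ValueError("lambda_grl must be nonnegative")
        for name in ("n_marks", "n_bins", "conv_kernels", "conv_length",
                     "pool_length", "n_attention_layers", "feature_dim",
                     "domain_head_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.label_head_dims = tuple(self.label_head_dims)

    @property
    def pe_channels(self) -> int:
        return {"relative_distance": 1, "sinusoidal": 2, "none": 0}[
            self.position_encoding
        ]

    @property
    def dense_plan(self) -> tuple[tuple[int, ...], bool]:
        """(per-layer kernel counts, densely connected?)"""
        return {
            "dense_32_16_8": ((32, 16, 8), True),
            "dense_50_50_50": ((50, 50, 50), True),
            "single_conv_50": ((50,), False),
            "plain_3x_conv_50": ((50, 50, 50), False),
        }[self.dense_block]

    @property
    def block_out_channels(self) -> int:
        widths, dense = self.dense_plan
        c0 = self.n_marks + self.pe_channels
        return c0 + sum(widths) if dense else widths[-1]

    @classmethod
    def from_variant(cls, variant: str = "default", **overrides) -> "ModelConfig":
        if variant not in VARIANT_ALIASES:
            raise ValueError(
                f"unknown variant {variant!r}; choose from {sorted(VARIANT_ALIASES)}"
            )
        kwargs = dict(VARIANT_ALIASES[variant])
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def position_encode(signal: np.ndarray, mode: str, n_bins: int | None = None) -> np.ndarray:
    """Append position-encoding channels to a (marks x bins) signal matrix.

    ``relative_distance`` appends one channel with the normalized distance of
    each bin to the central (TSS) bin, d_j = |j - (m-1)/2| / (m/2) in [0, 1);
    ``sinusoidal`` appends sin/cos channels (base 10000 convention);
    ``none`` returns the input unchanged.  Accepts a single matrix or a
    batch (genes x marks x bins).
    """
    x = np.asarray(signal, dtype=np.float64)
    single = x.ndim == 2
    if single:
        x = x[None]
    m = x.shape[2] if n_bins is None else n_bins
    if mode == "none":
        out = x
    elif mode == "relative_distance":
        j = np.arange(m)
        d = np.abs(j - (m - 1) / 2.0) / (m / 2.0)
        pe = np.broadcast_to(d, (x.shape[0], 1, m))
        out = np.concatenate([x, pe], axis=1)
    elif mode == "sinusoidal":
        j = np.arange(m, dtype=np.float64)
        # two channels: the i=0 sine/cosine pair of the base-10000 encoding
        angle = j / 10000.0 ** (0.0 / 2.0)
        pe = np.stack([np.sin(angle), np.cos(angle)])
        pe = np.broadcast_to(pe, (x.shape[0], 2, m))
        out = np.concatenate([x, pe], axis=1)
    else:
        raise ValueError(f"unknown position encoding mode {mode!r}")
    return out[0] if single else out


def _he_conv(rng: np.random.Generator, out_c: int, in_c: int, k: int) -> Parameter:
    std = np.sqrt(2.0 / (in_c * k))
    return Parameter(rng.normal(0.0, std, size=(out_c, in_c, k)))


def _he_linear(rng: np.random.Generator, in_f: int, out_f: int) -> Parameter:
    std = np.sqrt(2.0 / in_f)
    return Parameter(rng.normal(0.0, std, size=(in_f, out_f)))


class _Conv1d:
    def __init__(self, rng, in_c, out_c, k):
        self.w = _he_conv(rng, out_c, in_c, k)
        self.b = Parameter(np.zeros(out_c))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv1d(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class _Linear:
    def __init__(self, rng, in_f, out_f):
        self.w = _he_linear(rng, in_f, out_f)
        self.b = Parameter(np.zeros(out_f))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.linear(x, self.w, self.b)

    def parameters(self):
        return [self.w, self.b]


class DenseBlock:
    """Densely connected 1D conv layers (or the plain ablation variants).

    In dense mode, layer l applies H = ReLU -> conv to the concatenation of
    the block input and all previous layer outputs, and the block emits the
    full concatenation [x0, x1, ..., xL].  In plain mode the layers are
    chained sequentially and the last layer's maps are emitted.  Dropout
    follows every convolution.
    """

    def __init__(self, rng, in_channels: int, config: ModelConfig):
        self.widths, self.dense = config.dense_plan
        self.dropout_rate = config.dropout_rate
        self.convs = []
        c = in_channels
        for w in self.widths:
            self.convs.append(_Conv1d(rng, c, w, config.conv_length))
            c = c + w if self.dense else w

    def __call__(self, x0: Tensor, rng) -> Tensor:
        feats = [x0]
        for conv in self.convs:
            inp = ad.concat(feats, axis=1) if (self.dense and len(feats) > 1) else feats[-1]
            h = conv(ad.relu(inp))
            h = ad.dropout(h, self.dropout_rate, rng)
            if self.dense:
                feats.append(h)
            else:
                feats = [h]
        return ad.concat(feats, axis=1) if self.dense else feats[-1]

    def parameters(self):
        return [p for c in self.convs for p in c.parameters()]


class SelfAttention:
    """Single-head self-attention over positions via 1x1 convolutions.

    Q and K have half the input channels, V the full channel count; the
    attention matrix is softmax(Q^T K) over positions (no 1/sqrt(d) scaling
    unless ``scaled`` is set) and the output is attention-weighted V, shaped
    like the input.
    """

    def __init__(self, rng, channels: int, scaled: bool = False):
        if channels % 2 != 0:
            raise ValueError("self-attention requires an even channel count")
        self.channels = channels
        self.scaled = scaled
        self.conv_q = _Conv1d(rng, channels, channels // 2, 1)
        self.conv_k = _Conv1d(rng, channels, channels // 2, 1)
        self.conv_v = _Conv1d(rng, channels, channels, 1)
        # The attention logits QᵀK are raw channel inner products (no 1/√d
        # factor), so He-scale Q/K weights would saturate the softmax to a
        # hard argmax at initialization and destabilize early training.
        # Small-gain init (std 1/C) keeps initial attention near uniform;
        # Xavier-scale V keeps the mixed output at the input's magnitude.
        for conv, std in ((self.conv_q, 1.0 / channels),
                          (self.conv_k, 1.0 / channels),
                          (self.conv_v, np.sqrt(1.0 / channels))):
            conv.w.data = rng.normal(0.0, std, size=conv.w.data.shape)

    def attention_matrix(self, x: Tensor) -> Tensor:
        q = self.conv_q(x)  # (B, C/2, L)
        k = self.conv_k(x)
        scores = ad.bmm(ad.transpose(q, (0, 2, 1)), k)  # (B, L, L)
        if self.scaled:
            scores = ad.scale(scores, 1.0 / np.sqrt(self.channels // 2))
        return ad.softmax(scores)

    def __call__(self, x: Tensor) -> Tensor:
        att = self.attention_matrix(x)  # rows sum to 1 over key positions
        v = self.conv_v(x)  # (B, C, L)
        out = ad.bmm(att, ad.transpose(v, (0, 2, 1)))  # (B, L, C)
        return ad.transpose(out, (0, 2, 1))

    def parameters(self):
        return (
            self.conv_q.parameters() + self.conv_k.parameters() + self.conv_v.parameters()
        )


class TransferChromeModel:
    """Feature extractor + label head + adversarial domain head."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c0 = config.n_marks + config.pe_channels
        self.dense_block = DenseBlock(rng, c0, config)
        self.conv = _Conv1d(rng, config.block_out_channels, config.conv_kernels,
                            config.conv_length)
        if config.n_bins % config.pool_length != 0:
            raise ValueError("pool_length must divide n_bins")
        pooled = config.n_bins // config.pool_length
        self.attention = [
            SelfAttention(rng, config.conv_kernels, config.scaled_attention)
            for _ in range(config.n_attention_layers)
        ]
        self.fc_feature = _Linear(rng, config.conv_kernels * pooled, config.feature_dim)
        h1, h2 = config.label_head_dims
        self.label_fc = [
            _Linear(rng, config.feature_dim, h1),
            _Linear(rng, h1, h2),
            _Linear(rng, h2, 1),
        ]
        self.domain_fc = [
            _Linear(rng, config.feature_dim, config.domain_head_dim),
            _Linear(rng, config.domain_head_dim, 1),
        ]

    # -- forward passes -----------------------------------------------------

    def extract_features(self, x: np.ndarray, rng=None) -> Tensor:
        """Run the feature extractor; ``rng`` enables dropout (training)."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.config.n_marks or x.shape[2] != self.config.n_bins:
            raise ValueError(
                f"expected input (batch, {self.config.n_marks}, {self.config.n_bins}), "
                f"got {x.shape}"
            )
        x = position_encode(x, self.config.position_encoding)
        t = Tensor(x)
        t = self.dense_block(t, rng)
        t = ad.dropout(ad.relu(self.conv(t)), self.config.dropout_rate, rng)
        t = ad.max_pool1d(t, self.config.pool_length)
        for att in self.attention:
            t = att(t)
        t = ad.reshape(t, (t.shape[0], -1))
        return self.fc_feature(t)

    def label_logit(self, features: Tensor) -> Tensor:
        t = features
        for fc in self.label_fc[:-1]:
            t = ad.relu(fc(t))
        return ad.reshape(self.label_fc[-1](t), (-1,))

    def domain_logit(self, features: Tensor, lam: float | None = None) -> Tensor:
        lam = self.config.lambda_grl if lam is None else lam
        t = ad.grad_reverse(features, lam)
        t = ad.relu(self.domain_fc[0](t))
        return ad.reshape(self.domain_fc[1](t), (-1,))

    def forward(self, x: np.ndarray, rng=None, lam: float | None = None):
        """Return (label_logit, domain_logit, features) tensors."""
        f = self.extract_features(x, rng)
        return self.label_logit(f), self.domain_logit(f, lam), f

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode P(label = 1) per gene (dropout disabled)."""
        logits = self.label_logit(self.extract_features(x, rng=None))
        return 0.5 * (np.tanh(0.5 * logits.data) + 1.0)

    def predict_domain_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.domain_logit(self.extract_features(x, rng=None))
        return 0.5 * (np.tanh(0.5 * logits.data) + 1.0)

    # -- parameters & persistence -------------------------------------------

    def parameters(self) -> list[Parameter]:
        params = self.dense_block.parameters() + self.conv.parameters()
        for att in self.attention:
            params += att.parameters()
        params += self.fc_feature.parameters()
        for fc in self.label_fc + self.domain_fc:
            params += fc.parameters()
        return params

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"parameter shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


def save_checkpoint(model: TransferChromeModel, path) -> None:
    """Single-archive checkpoint: config JSON + parameter tensors."""
    arrays = {f"param_{i:03d}": p.data for i, p in enumerate(model.parameters())}
    np.savez(path, config=np.array(json.dumps(model.config.to_dict())), **arrays)


def load_checkpoint(path) -> TransferChromeModel:
    with np.load(path, allow_pickle=False) as npz:
        config = ModelConfig.from_dict(json.loads(str(npz["config"])))
        model = TransferChromeModel(config, seed=0)
        keys = sorted(k for k in npz.files if k.startswith("param_"))
        model.load_state([npz[k] for k in keys])
    return model
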