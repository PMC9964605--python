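"""The SGC-SRM network.

Per frequency band, trial features (channels x windows) pass through a
two-step simplifying graph convolution over a learnable electrode adjacency:

    H = relu( S (S X Theta1) Theta2 ),   S = D^{-1/2} (A + I) D^{-1/2}

with no nonlinearity between the two propagation steps.  The 64-dimensional
node embeddings are folded row-major into an 8x8 grid (EEG channels become
convolution channels) and encoded by three 2x2 convolutions interleaved with
two style-recalibration (SRM) gates, which squeeze each feature map to its
(mean, std) "style", map it through a per-channel linear layer, batch norm
and sigmoid, and multiply the resulting gate back onto the map.  Band
feature vectors are fused on the simplex via softmax weights and classified
by a linear head.  The loss is cross entropy plus an L1 penalty on every
band adjacency, so backpropagation both fits the classifier and dynamically
rewires (and sparsifies) the electrode graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .graph import (
    AdjacencyMatrix,
    ElectrodeLayout,
    GLOBAL_CONNECTION_PAIRS,
    apply_global_connections,
    init_adjacency,
    pairwise_distances,
)

__all__ = [
    "ModelConfig",
    "ConvStackConfig",
    "LossValue",
    "SgcSrmModel",
    "conv_channels_for",
    "normalize_adjacency_t",
    "sgc_band_encode",
    "reshape_to_grid",
    "srm_style_pool",
    "srm_style_integrate",
    "srm_recalibrate",
    "fuse_bands",
    "classify",
    "composite_loss",
]

_STYLE_EPS = 1e-5  # inside the style-std square root


@dataclass(frozen=True)
class ConvStackConfig:
    """Channel counts of the three-convolution encoder (kernel 2, stride 1)."""

    out1: int
    out2: int
    out3: int


def conv_channels_for(n_channels: int) -> ConvStackConfig:
    """Preset convolution widths: 62-channel and 12-channel configurations
    follow the published table; other channel counts get a small default."""
    if n_channels == 62:
        return ConvStackConfig(128, 256, 8)
    if n_channels == 12:
        return ConvStackConfig(32, 64, 8)
    return ConvStackConfig(16, 32, 8)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and ablation switches.

    ``mode`` is "fusion" (one encoder per band, learnable softmax fusion) or
    "direct" (bands concatenated along the feature axis into one shared
    encoder — the no-fusion variant).
    """

    n_channels: int
    window_dim: int
    bands: tuple[str, ...]
    h1: int = 128
    l1_strength: float = 0.01
    use_srm: bool = True
    use_global: bool = True
    freeze_adjacency: bool = False
    mode: str = "fusion"
    seed: int = 0
    dtype: str = "float32"
    delta: float = 5.0
    global_value: float = -1.0
    conv: ConvStackConfig | None = None

    def __post_init__(self):
        if self.l1_strength < 0:
            raise ValueError("l1_strength must be >= 0")
        if not self.bands:
            raise ValueError("bands must be nonempty")
        if self.mode not in ("fusion", "direct"):
            raise ValueError("mode must be 'fusion' or 'direct'")


@dataclass(frozen=True)
class LossValue:
    """Composite loss: total = cross_entropy + l1_strength * l1."""

    total: float
    cross_entropy: float
    l1: float


# ---------------------------------------------------------------------------
# Differentiable building blocks (free functions; the model class wires them)
# ---------------------------------------------------------------------------


def normalize_adjacency_t(a: Tensor) -> Tensor:
    """Differentiable S = D^{-1/2} (A + I) D^{-1/2} with absolute degrees."""
    c = a.shape[0]
    a_tilde = a + Tensor(np.eye(c, dtype=a.data.dtype))
    degree = a_tilde.abs().sum(axis=1, keepdims=True)  # (C, 1)
    inv_sqrt = degree ** -0.5
    return a_tilde * inv_sqrt * inv_sqrt.transpose(1, 0)


def sgc_band_encode(x: Tensor, a: Tensor, theta1: Tensor, theta2: Tensor) -> Tensor:
    """Two-step simplifying graph convolution: relu(S (S X Th1) Th2).

    ``x``: (N, C, D) band features; ``a``: (C, C) learnable adjacency.
    """
    s = normalize_adjacency_t(a)
    h1 = (s @ x) @ theta1
    return ((s @ h1) @ theta2).relu()


def reshape_to_grid(embeddings: Tensor) -> Tensor:
    """Fold (N, C, 64) node embeddings row-major into (N, C, 8, 8)."""
    n, c, width = embeddings.shape
    if width != 64:
        raise ValueError(f"node-feature width must be 64, got {width}")
    return embeddings.reshape(n, c, 8, 8)


def srm_style_pool(feature_map: Tensor) -> Tensor:
    """Per (trial, conv channel) style descriptor (mean, std) over H x W."""
    n, ch = feature_map.shape[:2]
    mu = feature_map.mean(axis=(2, 3))
    centered = feature_map + (-1.0) * mu.reshape(n, ch, 1, 1)
    var = (centered * centered).mean(axis=(2, 3))
    std = (var + _STYLE_EPS) ** 0.5
    return ad.stack([mu, std], axis=2)


def srm_style_integrate(
    style: Tensor,
    weights: Tensor,
    bn_gamma: Tensor,
    bn_beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
) -> Tensor:
    """Channel-wise FC (no bias) over (mean, std), batch norm, sigmoid gate."""
    z = (style * weights).sum(axis=2)  # (N, Ch)
    z = ad.batch_norm(z, bn_gamma, bn_beta, running_mean, running_var, training)
    # affine squeeze keeps gates strictly inside (0, 1) even where the
    # sigmoid saturates to 0.0/1.0 in floating point
    return z.sigmoid() * (1.0 - 2e-12) + 1e-12


def srm_recalibrate(feature_map: Tensor, gates: Tensor) -> Tensor:
    """Multiply each (trial, conv channel) map by its gate."""
    n, ch = feature_map.shape[:2]
    if gates.shape != (n, ch):
        raise ValueError(f"gate shape {gates.shape} does not match map {(n, ch)}")
    return feature_map * gates.reshape(n, ch, 1, 1)


def fuse_bands(band_vectors: list[Tensor], fusion_logits: Tensor) -> Tensor:
    """Convex combination of band vectors with softmax fusion weights."""
    b = len(band_vectors)
    if fusion_logits.shape != (b,):
        raise ValueError(f"{b} band vectors but {fusion_logits.shape[0]} fusion logits")
    lengths = {v.shape for v in band_vectors}
    if len(lengths) != 1:
        raise ValueError(f"band vectors differ in shape: {lengths}")
    weights = ad.softmax(fusion_logits)
    stacked = ad.stack(band_vectors, axis=0)  # (B, N, F)
    return (weights.reshape(b, 1, 1) * stacked).sum(axis=0)


def classify(fused: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Linear head followed by softmax: 3-class probabilities."""
    return ad.softmax(fused @ weight + bias)


def composite_loss(
    probs: np.ndarray,
    labels: np.ndarray,
    adjacencies: list[np.ndarray],
    l1_strength: float,
) -> LossValue:
    """Reference (non-differentiable) composite loss from probabilities."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("label outside the class range")
    ce = float(-np.mean(np.log(probs[np.arange(len(labels)), labels])))
    l1 = float(sum(np.abs(a).sum() for a in adjacencies))
    return LossValue(total=ce + l1_strength * l1, cross_entropy=ce, l1=l1)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class _Conv2d:
    def __init__(self, cin, cout, rng, dtype, padding=((0, 0), (0, 0))):
        bound = 1.0 / np.sqrt(cin * 4)
        self.weight = Tensor(
            rng.uniform(-bound, bound, (cout, cin, 2, 2)).astype(dtype), requires_grad=True
        )
        self.bias = Tensor(rng.uniform(-bound, bound, cout).astype(dtype), requires_grad=True)
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias, self.padding)

    def parameters(self):
        return [self.weight, self.bias]


class _SRM:
    """Style recalibration: pool -> channel-wise FC -> BN -> sigmoid -> scale."""

    def __init__(self, channels, rng, dtype):
        bound = 1.0 / np.sqrt(2)
        self.weights = Tensor(
            rng.uniform(-bound, bound, (channels, 2)).astype(dtype), requires_grad=True
        )
        self.bn_gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.bn_beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        style = srm_style_pool(x)
        gates = srm_style_integrate(
            style, self.weights, self.bn_gamma, self.bn_beta,
            self.running_mean, self.running_var, training,
        )
        return srm_recalibrate(x, gates)

    def parameters(self):
        return [self.weights, self.bn_gamma, self.bn_beta]


class _BandEncoder:
    """SGC over the learnable band graph, grid reshape, SRM-gated conv stack."""

    def __init__(self, cfg: ModelConfig, a_init: np.ndarray, d_in: int, rng, dtype):
        c = cfg.n_channels
        conv_cfg = cfg.conv or conv_channels_for(c)
        self.adjacency = Tensor(
            a_init.astype(dtype), requires_grad=not cfg.freeze_adjacency, name="A_b"
        )
        b1 = 1.0 / np.sqrt(d_in)
        self.theta1 = Tensor(rng.uniform(-b1, b1, (d_in, cfg.h1)).astype(dtype), requires_grad=True)
        b2 = 1.0 / np.sqrt(cfg.h1)
        self.theta2 = Tensor(rng.uniform(-b2, b2, (cfg.h1, 64)).astype(dtype), requires_grad=True)
        self.conv1 = _Conv2d(c, conv_cfg.out1, rng, dtype)
        self.srm1 = _SRM(conv_cfg.out1, rng, dtype)
        self.conv2 = _Conv2d(conv_cfg.out1, conv_cfg.out2, rng, dtype)
        self.srm2 = _SRM(conv_cfg.out2, rng, dtype)
        self.conv3 = _Conv2d(conv_cfg.out2, conv_cfg.out3, rng, dtype, padding=((0, 1), (0, 1)))
        self.out_dim = conv_cfg.out3 * 9
        self.use_srm = cfg.use_srm

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = sgc_band_encode(x, self.adjacency, self.theta1, self.theta2)
        g = reshape_to_grid(h)
        g = self.conv1(g)
        if self.use_srm:
            g = self.srm1(g, training)
        g = self.conv2(g)
        if self.use_srm:
            g = self.srm2(g, training)
        g = self.conv3(g)
        g = ad.maxpool2d_2x2(g)
        n = g.shape[0]
        return g.reshape(n, self.out_dim)

    def parameters(self):
        params = [self.adjacency, self.theta1, self.theta2]
        for layer in (self.conv1, self.srm1, self.conv2, self.srm2, self.conv3):
            params.extend(layer.parameters())
        return params


class SgcSrmModel:
    """Parallel band encoders, simplex fusion, linear softmax head."""

    def __init__(self, config: ModelConfig, layout: ElectrodeLayout):
        if len(layout.names) != config.n_channels:
            raise ValueError(
                f"layout has {len(layout.names)} electrodes, config expects {config.n_channels}"
            )
        self.config = config
        self.layout = layout
        dtype = np.dtype(config.dtype).type
        rng = np.random.default_rng(config.seed)

        a0 = init_adjacency(pairwise_distances(layout), config.delta, layout.names)
        if config.use_global:
            a0, self.applied_global_pairs = apply_global_connections(
                a0, GLOBAL_CONNECTION_PAIRS, config.global_value
            )
        else:
            self.applied_global_pairs = []
        self._a_init = a0.values.copy()

        n_encoders = len(config.bands) if config.mode == "fusion" else 1
        d_in = (
            config.window_dim
            if config.mode == "fusion"
            else config.window_dim * len(config.bands)
        )
        self.encoders = [
            _BandEncoder(config, a0.values, d_in, rng, dtype) for _ in range(n_encoders)
        ]
        self.fusion_logits = Tensor(
            np.zeros(n_encoders, dtype=dtype), requires_grad=config.mode == "fusion"
        )
        f = self.encoders[0].out_dim
        bound = 1.0 / np.sqrt(f)
        self.head_weight = Tensor(rng.uniform(-bound, bound, (f, 3)).astype(dtype), requires_grad=True)
        self.head_bias = Tensor(rng.uniform(-bound, bound, 3).astype(dtype), requires_grad=True)

    # -- forward --------------------------------------------------------
    def _band_inputs(self, x: np.ndarray) -> list[np.ndarray]:
        dtype = np.dtype(self.config.dtype)
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, B, D) input, got shape {x.shape}")
        if x.shape[1] != self.config.n_channels or x.shape[2] != len(self.config.bands):
            raise ValueError(
                f"input shape {x.shape[1:3]} does not match config "
                f"({self.config.n_channels} channels, {len(self.config.bands)} bands)"
            )
        if self.config.mode == "fusion":
            return [np.ascontiguousarray(x[:, :, b, :], dtype=dtype) for b in range(x.shape[2])]
        n, c = x.shape[:2]
        return [np.ascontiguousarray(x.transpose(0, 1, 2, 3).reshape(n, c, -1), dtype=dtype)]

    def forward(self, x: np.ndarray, training: bool = False) -> Tensor:
        """Class logits for a (N, C, B, D) feature array."""
        vecs = [
            enc(Tensor(xb), training) for enc, xb in zip(self.encoders, self._band_inputs(x))
        ]
        if len(vecs) == 1:
            fused = vecs[0]
        else:
            fused = fuse_bands(vecs, self.fusion_logits)
        return fused @ self.head_weight + self.head_bias

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start : start + batch_size], training=False)
            out.append(ad.softmax(logits).data)
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def loss(self, x: np.ndarray, labels: np.ndarray, training: bool = True):
        """Differentiable composite loss; returns (Tensor total, LossValue)."""
        logits = self.forward(x, training=training)
        ce = ad.cross_entropy_with_logits(logits, labels)
        l1 = None
        for enc in self.encoders:
            term = enc.adjacency.abs().sum()
            l1 = term if l1 is None else l1 + term
        total = ce + self.config.l1_strength * l1
        value = LossValue(
            total=float(total.data), cross_entropy=float(ce.data), l1=float(l1.data)
        )
        return total, value

    # -- bookkeeping ----------------------------------------------------
    def fusion_weights(self) -> np.ndarray:
        e = np.exp(self.fusion_logits.data - self.fusion_logits.data.max())
        return e / e.sum()

    def adjacency_matrices(self) -> list[AdjacencyMatrix]:
        return [
            AdjacencyMatrix(enc.adjacency.data.copy(), self.layout.names, self.config.delta)
            for enc in self.encoders
        ]

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for enc in self.encoders:
            params.extend(enc.parameters())
        params.append(self.fusion_logits)
        params.extend([self.head_weight, self.head_bias])
        return params

    def parameter_count(self) -> int:
        """Number of trainable scalars (a pure function of the config)."""
        return int(sum(p.data.size for p in self.parameters() if p.requires_grad))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all weights and running statistics."""
        state: dict[str, np.ndarray] = {}
        for i, enc in enumerate(self.encoders):
            state[f"enc{i}.adjacency"] = enc.adjacency.data
            state[f"enc{i}.theta1"] = enc.theta1.data
            state[f"enc{i}.theta2"] = enc.theta2.data
            for j, conv in enumerate((enc.conv1, enc.conv2, enc.conv3), start=1):
                state[f"enc{i}.conv{j}.weight"] = conv.weight.data
                state[f"enc{i}.conv{j}.bias"] = conv.bias.data
            for j, srm in enumerate((enc.srm1, enc.srm2), start=1):
                state[f"enc{i}.srm{j}.weights"] = srm.weights.data
                state[f"enc{i}.srm{j}.bn_gamma"] = srm.bn_gamma.data
                state[f"enc{i}.srm{j}.bn_beta"] = srm.bn_beta.data
                state[f"enc{i}.srm{j}.running_mean"] = srm.running_mean
                state[f"enc{i}.srm{j}.running_var"] = srm.running_var
        state["fusion_logits"] = self.fusion_logits.data
        state["head_weight"] = self.head_weight.data
        state["head_bias"] = self.head_bias.data
        return state

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing arrays: {sorted(missing)}")
        for name, arr in own.items():
            arr[...] = state[name]
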