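"""3D encoder–decoder segmentation network with valid-style output cropping.

The architecture contract is geometric, not a fixed layer stack: a
64-voxel input window yields a 36-voxel single-channel axon-probability
map (one margin of 14 voxels cropped per side at the head), and the
network exposes a deterministic ordered list of its convolutional layers
so that layer-selective fine-tuning ("first two", "middle two",
"last two" or all) is well defined.

Internally it is a U-Net-style stack: per resolution level two 3x3x3
same-padded convolutions (+ optional batch norm, ReLU), 2x average
pooling down, nearest-neighbour upsampling and skip concatenation back
up, then a centre crop and a 1x1x1 sigmoid head.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import (
    AvgPool3d,
    BatchNorm3d,
    Conv3d,
    Layer,
    Parameter,
    ReLU,
    Sigmoid,
    Upsample3d,
)

LAYER_SELECTORS = ("full", "first2", "middle2", "last2")


@dataclass(frozen=True)
class UNetConfig:
    depth: int = 3
    base_filters: int = 8
    input_size: int = 64
    margin: int = 14
    use_batchnorm: bool = True
    update_bn_stats: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 1:
            raise ValueError("base_filters must be >= 1")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.output_size <= 0:
            raise ValueError("input_size - 2*margin must be positive")
        factor = 2 ** (self.depth - 1)
        if self.input_size % factor:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^(depth-1)={factor}"
            )
        if self.input_size // factor < 2:
            raise ValueError("bottleneck would collapse below 2 voxels")

    @property
    def output_size(self) -> int:
        return self.input_size - 2 * self.margin


def _conv_block(
    c_in: int, c_out: int, use_bn: bool, rng: np.random.Generator, name: str
) -> list[Layer]:
    layers: list[Layer] = []
    for j, (ci, co) in enumerate([(c_in, c_out), (c_out, c_out)]):
        layers.append(Conv3d(ci, co, 3, rng=rng, name=f"{name}.conv{j}"))
        if use_bn:
            layers.append(BatchNorm3d(co, name=f"{name}.bn{j}"))
        layers.append(ReLU())
    return layers


def _run_block(block: list[Layer], x: np.ndarray, training: bool) -> np.ndarray:
    for layer in block:
        x = layer.forward(x, training)
    return x


def _back_block(block: list[Layer], g: np.ndarray) -> np.ndarray:
    for layer in reversed(block):
        g = layer.backward(g)
    return g


class UNet3D:
    """See module docstring. Build with :func:`build_network`."""

    def __init__(self, config: UNetConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        bn = config.use_batchnorm
        f = [config.base_filters * 2**i for i in range(config.depth)]

        self.enc_blocks: list[list[Layer]] = []
        c_in = 1
        for i in range(config.depth):
            self.enc_blocks.append(_conv_block(c_in, f[i], bn, rng, f"enc{i}"))
            c_in = f[i]
        self.pools = [AvgPool3d() for _ in range(config.depth - 1)]
        self.ups = [Upsample3d() for _ in range(config.depth - 1)]
        # dec_blocks[j] operates at level depth-2-j
        self.dec_blocks: list[list[Layer]] = []
        for j in range(config.depth - 1):
            level = config.depth - 2 - j
            self.dec_blocks.append(
                _conv_block(f[level] + f[level + 1], f[level], bn, rng, f"dec{level}")
            )
        self.head = Conv3d(f[0], 1, 1, rng=rng, name="head")
        self.sigmoid = Sigmoid()
        if not config.update_bn_stats:
            for b in self._bn_layers():
                b.update_running_stats = False
        self._cache: dict | None = None

    # ---- introspection -------------------------------------------------
    @property
    def conv_layers(self) -> list[Conv3d]:
        """All convolutional layers in forward-execution order (head last)."""
        convs: list[Conv3d] = []
        for block in self.enc_blocks + self.dec_blocks:
            convs.extend(l for l in block if isinstance(l, Conv3d))
        convs.append(self.head)
        return convs

    def _bn_layers(self) -> list[BatchNorm3d]:
        bns: list[BatchNorm3d] = []
        for block in self.enc_blocks + self.dec_blocks:
            bns.extend(l for l in block if isinstance(l, BatchNorm3d))
        return bns

    def _all_layers(self) -> list[Layer]:
        layers: list[Layer] = []
        for block in self.enc_blocks + self.dec_blocks:
            layers.extend(block)
        layers.append(self.head)
        return layers

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for layer in self._all_layers():
            params.extend(layer.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # ---- forward / backward -------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(N, 1, s, s, s) float input -> (N, 1, o, o, o) probabilities."""
        cfg = self.config
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, D, H, W) input, got {x.shape}")
        if x.shape[2] != cfg.input_size:
            raise ValueError(
                f"spatial size {x.shape[2:]} != configured input_size {cfg.input_size}"
            )
        skips: list[np.ndarray] = []
        h = x
        for i, block in enumerate(self.enc_blocks):
            h = _run_block(block, h, training)
            if i < cfg.depth - 1:
                skips.append(h)
                h = self.pools[i].forward(h, training)
        skip_channels: list[int] = []
        for j, block in enumerate(self.dec_blocks):
            h = self.ups[j].forward(h, training)
            skip = skips.pop()
            skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            h = _run_block(block, h, training)
        m = cfg.margin
        o = cfg.output_size
        full_shape = h.shape
        h = np.ascontiguousarray(h[:, :, m : m + o, m : m + o, m : m + o])
        h = self.head.forward(h, training)
        prob = self.sigmoid.forward(h, training)
        if training:
            self._cache = {"full_shape": full_shape, "skip_channels": skip_channels}
        return prob

    def backward(self, grad_prob: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dProbability."""
        assert self._cache is not None, "backward before forward(training=True)"
        cfg = self.config
        g = self.sigmoid.backward(grad_prob)
        g = self.head.backward(g)
        m, o = cfg.margin, cfg.output_size
        g_full = np.zeros(self._cache["full_shape"], dtype=g.dtype)
        g_full[:, :, m : m + o, m : m + o, m : m + o] = g
        g = g_full
        skip_grads: dict[int, np.ndarray] = {}
        skip_channels = self._cache["skip_channels"]
        for j in range(cfg.depth - 2, -1, -1):
            level = cfg.depth - 2 - j
            g = _back_block(self.dec_blocks[j], g)
            sc = skip_channels[j]
            skip_grads[level] = g[:, :sc]
            g = self.ups[j].backward(np.ascontiguousarray(g[:, sc:]))
        g = _back_block(self.enc_blocks[-1], g)
        for i in range(cfg.depth - 2, -1, -1):
            g = self.pools[i].backward(g)
            g = g + skip_grads[i]
            g = _back_block(self.enc_blocks[i], g)
        self._cache = None

    def predict_window(self, window: np.ndarray) -> np.ndarray:
        """Normalised 3D input window -> 3D probability window (eval mode)."""
        out = self.forward(
            np.asarray(window, dtype=np.float64)[None, None], training=False
        )
        return out[0, 0]

    # ---- serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data for p in self.parameters()}
        for i, b in enumerate(self._bn_layers()):
            state[f"{b.name}.running_mean"] = b.running_mean
            state[f"{b.name}.running_var"] = b.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.data = np.asarray(state[p.name], dtype=p.data.dtype).copy()
        for b in self._bn_layers():
            b.running_mean = np.asarray(state[f"{b.name}.running_mean"]).copy()
            b.running_var = np.asarray(state[f"{b.name}.running_var"]).copy()


def build_network(config: UNetConfig) -> UNet3D:
    """Construct a network realizing ``input_size³ -> output_size³``.

    Two builds with the same config (same seed) have bit-identical
    initial parameters.
    """
    return UNet3D(config)


def apply_layer_selection(network: UNet3D, selector: str) -> UNet3D:
    """Mark trainable layers for fine-tuning; returns the network.

    ``selector`` is one of ``full``, ``first2``, ``middle2``, ``last2``.
    The two-layer selectors index the ordered convolutional-layer list
    ("middle two" = the pair straddling the list midpoint). Batch-norm
    parameters are always left trainable.
    """
    if selector not in LAYER_SELECTORS:
        raise ValueError(f"selector must be one of {LAYER_SELECTORS}, got {selector!r}")
    convs = network.conv_layers
    if selector == "full":
        chosen = set(range(len(convs)))
    else:
        if len(convs) < 2:
            raise ValueError("network has fewer than 2 convolutional layers")
        if selector == "first2":
            chosen = {0, 1}
        elif selector == "last2":
            chosen = {len(convs) - 2, len(convs) - 1}
        else:  # middle2
            i0 = (len(convs) - 1) // 2
            chosen = {i0, i0 + 1}
    for i, conv in enumerate(convs):
        for p in conv.parameters():
            p.trainable = i in chosen
    for b in network._bn_layers():
        for p in b.parameters():
            p.trainable = True
    return network
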