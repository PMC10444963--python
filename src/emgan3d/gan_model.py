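"""Generator / discriminator networks and the four training loss terms.

Generator: conv(3^3) + PReLU, a stack of residual blocks
(conv - InstanceNorm - PReLU - dropout - conv - InstanceNorm, skip-added),
a trailing conv(3^3), a 1^3 single-channel projection, then tanh mapped to
[0, 1] via (x + 1) / 2.  All convolutions are stride 1 with padding that
preserves the cube shape.

Discriminator: a stack of conv layers whose channel count doubles every
``channel_doubling_period`` layers, with group normalization, PReLU and
dropout; even-indexed layers use stride 2 to shrink the cube, followed by
global average pooling and a two-logit softmax head.  The first softmax
component is read as P(real / simulated).

The losses are implemented literally as printed (linear in the
probabilities): content = squared error between simulated and generated
cubes (mean by default, sum by option), adversarial = -D(G(exp)),
generator = content + lambda * adversarial, discriminator =
(1 - D(real)) + D(generated).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "Generator",
    "Discriminator",
    "GanParams",
    "generator_forward",
    "discriminator_forward",
    "content_loss",
    "adversarial_loss",
    "generator_loss",
    "discriminator_loss",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class GeneratorConfig:
    n_resnet_blocks: int = 15
    channels: int = 32
    kernel_size: int = 3
    dropout_p: float = 0.25
    # The tanh head saturates (and kills gradients) if the pre-activation
    # starts at O(1) scale, so the output projection is initialized small,
    # and its bias starts at the density prior: normalized maps are mostly
    # near-zero, so the head begins near the low end of [0, 1] instead of
    # having to dive into tanh saturation to get there.
    output_init_scale: float = 0.02
    output_bias_init: float = -1.5

    def __post_init__(self) -> None:
        if self.n_resnet_blocks < 0:
            raise ValueError("n_resnet_blocks must be >= 0")
        if self.output_init_scale <= 0:
            raise ValueError("output_init_scale must be positive")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")


@dataclass
class DiscriminatorConfig:
    n_conv_layers: int = 10
    base_channels: int = 32
    channel_doubling_period: int = 2
    group_norm_group_size: int = 16
    dropout_p: float = 0.25

    def __post_init__(self) -> None:
        if self.n_conv_layers < 1:
            raise ValueError("n_conv_layers must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.channel_doubling_period < 1:
            raise ValueError("channel_doubling_period must be >= 1")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")

    def channel_sequence(self) -> list[int]:
        return [
            self.base_channels * 2 ** (i // self.channel_doubling_period)
            for i in range(self.n_conv_layers)
        ]


class _ResBlock(nn.Module):
    def __init__(self, channels, kernel_size, dropout_p, rng, dtype):
        self.conv1 = nn.Conv3d(channels, channels, kernel_size, rng=rng, dtype=dtype)
        self.norm1 = nn.InstanceNorm3d(channels, dtype=dtype)
        self.act = nn.PReLU(dtype=dtype)
        self.drop = nn.Dropout(dropout_p, rng=rng)
        self.conv2 = nn.Conv3d(channels, channels, kernel_size, rng=rng, dtype=dtype)
        self.norm2 = nn.InstanceNorm3d(channels, dtype=dtype)

    def forward(self, x, training=False):
        h = self.conv1(x, training)
        h = self.norm1(h, training)
        h = self.act(h, training)
        h = self.drop(h, training)
        h = self.conv2(h, training)
        h = self.norm2(h, training)
        return x + h

    def backward(self, grad):
        g = self.norm2.backward(grad)
        g = self.conv2.backward(g)
        g = self.drop.backward(g)
        g = self.act.backward(g)
        g = self.norm1.backward(g)
        g = self.conv1.backward(g)
        return grad + g


class Generator(nn.Module):
    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator, dtype=np.float32):
        self.cfg = cfg
        self.head = nn.Conv3d(1, cfg.channels, cfg.kernel_size, rng=rng, dtype=dtype)
        self.head_act = nn.PReLU(dtype=dtype)
        self.blocks = [
            _ResBlock(cfg.channels, cfg.kernel_size, cfg.dropout_p, rng, dtype)
            for _ in range(cfg.n_resnet_blocks)
        ]
        self.tail = nn.Conv3d(cfg.channels, cfg.channels, cfg.kernel_size, rng=rng, dtype=dtype)
        self.collapse = nn.Conv3d(cfg.channels, 1, 1, rng=rng, dtype=dtype)
        self.collapse.W.value *= dtype(cfg.output_init_scale)
        self.collapse.b.value[...] = dtype(cfg.output_bias_init)
        self.tanh = nn.Tanh()

    def forward(self, x, training=False):
        h = self.head(x, training)
        h = self.head_act(h, training)
        for block in self.blocks:
            h = block(h, training)
        h = self.tail(h, training)
        h = self.collapse(h, training)
        h = self.tanh(h, training)
        return (h + 1.0) / 2.0

    def backward(self, grad):
        g = grad * 0.5
        g = self.tanh.backward(g)
        g = self.collapse.backward(g)
        g = self.tail.backward(g)
        for block in reversed(self.blocks):
            g = block.backward(g)
        g = self.head_act.backward(g)
        g = self.head.backward(g)
        return g


class Discriminator(nn.Module):
    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator, dtype=np.float32):
        self.cfg = cfg
        layers: list[nn.Module] = []
        in_ch = 1
        for i, out_ch in enumerate(cfg.channel_sequence()):
            stride = 2 if i % 2 == 0 else 1
            layers.append(nn.Conv3d(in_ch, out_ch, 3, stride=stride, rng=rng, dtype=dtype))
            layers.append(nn.GroupNorm(out_ch, cfg.group_norm_group_size, dtype=dtype))
            layers.append(nn.PReLU(dtype=dtype))
            layers.append(nn.Dropout(cfg.dropout_p, rng=rng))
            in_ch = out_ch
        self.body = nn.Sequential(*layers)
        self.pool = nn.GlobalAvgPool()
        self.headlin = nn.Linear(in_ch, 2, rng=rng, dtype=dtype)
        self.softmax = nn.Softmax()

    def forward(self, x, training=False):
        h = self.body(x, training)
        h = self.pool(h, training)
        h = self.headlin(h, training)
        return self.softmax(h, training)  # (N, 2); column 0 = P(real)

    def backward(self, grad):
        g = self.softmax.backward(grad)
        g = self.headlin.backward(g)
        g = self.pool.backward(g)
        return self.body.backward(g)


@dataclass
class GanParams:
    """Bundle of generator + discriminator with their configuration."""

    generator: Generator
    discriminator: Discriminator
    generator_config: GeneratorConfig
    discriminator_config: DiscriminatorConfig
    adversarial_weight: float = 1e-3
    seed: int | None = None
    epoch: int = 0

    def __post_init__(self) -> None:
        if self.adversarial_weight < 0:
            raise ValueError("adversarial_weight must be >= 0")

    @classmethod
    def initialize(
        cls,
        generator_config: GeneratorConfig | None = None,
        discriminator_config: DiscriminatorConfig | None = None,
        adversarial_weight: float = 1e-3,
        seed: int = 0,
        dtype=np.float32,
    ) -> "GanParams":
        gen_cfg = generator_config or GeneratorConfig()
        disc_cfg = discriminator_config or DiscriminatorConfig()
        ss = np.random.SeedSequence(seed)
        g_rng, d_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        return cls(
            generator=Generator(gen_cfg, g_rng, dtype=dtype),
            discriminator=Discriminator(disc_cfg, d_rng, dtype=dtype),
            generator_config=gen_cfg,
            discriminator_config=disc_cfg,
            adversarial_weight=adversarial_weight,
            seed=seed,
        )


def _as_batch(cube: np.ndarray) -> np.ndarray:
    cube = np.asarray(cube)
    if cube.ndim == 3:
        return cube[None, None]
    if cube.ndim == 5:
        return cube
    raise ValueError(f"expected a 3-D cube or (N,1,D,H,W) batch, got shape {cube.shape}")


def generator_forward(exp_cube: np.ndarray, params: GanParams, training: bool = False) -> np.ndarray:
    """Run the generator on one cube (3-D in, 3-D out) or a batch."""
    batch = _as_batch(exp_cube)
    out = params.generator(batch.astype(params.generator.head.W.value.dtype), training=training)
    return out[0, 0] if np.asarray(exp_cube).ndim == 3 else out


def discriminator_forward(cube: np.ndarray, params: GanParams, training: bool = False):
    """Probability that a cube is a real (simulated) high-resolution cube."""
    batch = _as_batch(cube)
    probs = params.discriminator(
        batch.astype(params.discriminator.headlin.W.value.dtype), training=training
    )
    p_real = probs[:, 0]
    return float(p_real[0]) if np.asarray(cube).ndim == 3 else p_real


def content_loss(sim_cube: np.ndarray, gen_cube: np.ndarray, reduction: str = "mean") -> float:
    sim_cube = np.asarray(sim_cube, dtype=np.float64)
    gen_cube = np.asarray(gen_cube, dtype=np.float64)
    if sim_cube.shape != gen_cube.shape:
        raise ValueError(f"shape mismatch: {sim_cube.shape} vs {gen_cube.shape}")
    sq = (sim_cube - gen_cube) ** 2
    if reduction == "mean":
        return float(sq.mean())
    if reduction == "sum":
        return float(sq.sum())
    raise ValueError(f"unknown reduction {reduction!r}")


def adversarial_loss(d_prob: float) -> float:
    if not 0.0 <= d_prob <= 1.0:
        raise ValueError(f"discriminator probability {d_prob} outside [0, 1]")
    return -float(d_prob)


def generator_loss(content: float, adversarial: float, adversarial_weight: float = 1e-3) -> float:
    if content < 0:
        raise ValueError(f"content loss must be >= 0, got {content}")
    return float(content + adversarial_weight * adversarial)


def discriminator_loss(d_real: float, d_fake: float) -> float:
    for name, v in (("d_real", d_real), ("d_fake", d_fake)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return float((1.0 - d_real) + d_fake)


def save_checkpoint(params: GanParams, path, extra_meta: dict | None = None) -> None:
    """Serialize parameters + configs to an .npz container."""
    meta = {
        "format": "emgan3d-checkpoint-v1",
        "generator_config": asdict(params.generator_config),
        "discriminator_config": asdict(params.discriminator_config),
        "adversarial_weight": params.adversarial_weight,
        "seed": params.seed,
        "epoch": params.epoch,
    }
    if extra_meta:
        meta.update(extra_meta)
    arrays = {"meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, a in enumerate(params.generator.state()):
        arrays[f"g{i}"] = a
    for i, a in enumerate(params.discriminator.state()):
        arrays[f"d{i}"] = a
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> GanParams:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        if meta.get("format") != "emgan3d-checkpoint-v1":
            raise ValueError(f"unrecognized checkpoint format in {path!r}")
        gen_cfg = GeneratorConfig(**meta["generator_config"])
        disc_cfg = DiscriminatorConfig(**meta["discriminator_config"])
        params = GanParams.initialize(
            gen_cfg,
            disc_cfg,
            adversarial_weight=meta["adversarial_weight"],
            seed=meta["seed"] if meta["seed"] is not None else 0,
        )
        params.epoch = meta.get("epoch", 0)
        g_arrays = [npz[f"g{i}"] for i in range(len(params.generator.parameters()))]
        d_arrays = [npz[f"d{i}"] for i in range(len(params.discriminator.parameters()))]
    params.generator.load_state(g_arrays)
    params.discriminator.load_state(d_arrays)
    return params
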