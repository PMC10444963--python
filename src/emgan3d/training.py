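"""Alternating generator/discriminator training over cube-pair datasets.

Per batch, one generator step (content + weighted adversarial loss against
the current discriminator) is followed by one discriminator step on the
same simulated and generated cubes.  All randomness — parameter
initialization, shuffling, dropout — flows from the single seed in
:class:`TrainingConfig`, so runs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .cube_pipeline import CubePair
from .evaluation import UndefinedCorrelationError, cross_correlation
from .gan_model import (
    DiscriminatorConfig,
    GanParams,
    GeneratorConfig,
    content_loss,
)

__all__ = ["TrainingConfig", "TrainingHistory", "split_by_map", "train", "validate"]

logger = logging.getLogger(__name__)

LEARNING_RATE_SEARCH_SPACE = (0.01, 0.001, 0.005, 0.0001)


@dataclass
class TrainingConfig:
    lr_generator: float = 0.001
    lr_discriminator: float = 0.001
    batch_size: int = 16
    epochs: int = 100
    adversarial_weight: float = 1e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0
    max_steps: int | None = None
    freeze_discriminator: bool = False
    content_reduction: str = "mean"
    checkpoint_every: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValueError("learning rates must be positive")
        if self.adversarial_weight < 0:
            raise ValueError("adversarial_weight must be >= 0")


@dataclass
class EpochRecord:
    epoch: int
    generator_loss: float
    content_loss: float
    adversarial_loss: float
    discriminator_loss: float
    validation_cc: float | None = None
    validation_content: float | None = None


@dataclass
class TrainingHistory:
    records: list[EpochRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_rows(self) -> list[dict]:
        return [vars(r) for r in self.records]


def split_by_map(
    pairs_by_map: dict[str, list[CubePair]], validation_maps: int, seed: int = 0
) -> tuple[dict[str, list[CubePair]], dict[str, list[CubePair]]]:
    """Partition cube pairs at the source-map level.

    No cube from a validation map ever appears in the training partition.
    """
    ids = sorted(pairs_by_map)
    if len(ids) < 2:
        raise ValueError("need at least two source maps to split")
    if validation_maps >= len(ids):
        raise ValueError(
            f"validation_maps={validation_maps} must be < number of maps ({len(ids)})"
        )
    if validation_maps < 1:
        raise ValueError("validation_maps must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    val_ids = {ids[i] for i in order[:validation_maps]}
    train = {m: pairs_by_map[m] for m in ids if m not in val_ids}
    val = {m: pairs_by_map[m] for m in ids if m in val_ids}
    return train, val


def _flatten(pairs) -> list[CubePair]:
    if isinstance(pairs, dict):
        out: list[CubePair] = []
        for key in sorted(pairs):
            out.extend(pairs[key])
        return out
    return list(pairs)


def _stack(pairs: list[CubePair], idx: np.ndarray, dtype) -> tuple[np.ndarray, np.ndarray]:
    exp = np.stack([pairs[i].exp_cube for i in idx]).astype(dtype)[:, None]
    sim = np.stack([pairs[i].sim_cube for i in idx]).astype(dtype)[:, None]
    return exp, sim


def train(
    pairs,
    cfg: TrainingConfig,
    gen_cfg: GeneratorConfig | None = None,
    disc_cfg: DiscriminatorConfig | None = None,
    val_pairs=None,
    params: GanParams | None = None,
) -> tuple[GanParams, TrainingHistory]:
    """Train the GAN on cube pairs; returns final parameters and history."""
    pairs = _flatten(pairs)
    if not pairs:
        raise ValueError("training set is empty")
    val_list = _flatten(val_pairs) if val_pairs is not None else None

    if params is None:
        params = GanParams.initialize(
            gen_cfg, disc_cfg, adversarial_weight=cfg.adversarial_weight, seed=cfg.seed
        )
    gen, disc = params.generator, params.discriminator
    dtype = gen.head.W.value.dtype
    opt_g = nn.Adam(gen.parameters(), lr=cfg.lr_generator, betas=cfg.adam_betas)
    opt_d = nn.Adam(disc.parameters(), lr=cfg.lr_discriminator, betas=cfg.adam_betas)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[2])

    lam = cfg.adversarial_weight
    history = TrainingHistory()
    n = len(pairs)
    step = 0
    done = False
    for epoch in range(1, cfg.epochs + 1):
        order = shuffle_rng.permutation(n)
        sums = np.zeros(4)
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            if cfg.max_steps is not None and step >= cfg.max_steps:
                done = True
                break
            idx = order[start : start + cfg.batch_size]
            exp_b, sim_b = _stack(pairs, idx, dtype)
            bs = len(idx)

            # --- generator step ---
            gen.zero_grad()
            fake = gen(exp_b, training=True)
            c_loss = float(((sim_b - fake) ** 2).mean())
            if cfg.content_reduction == "sum":
                voxels = float(np.prod(fake.shape[2:]))
                grad_fake = 2.0 * (fake - sim_b) / bs
                c_loss_rep = c_loss * voxels
            else:
                grad_fake = 2.0 * (fake - sim_b) / fake.size
                c_loss_rep = c_loss
            a_loss = 0.0
            if lam > 0:
                disc.zero_grad()
                probs = disc(fake, training=True)
                a_loss = float(-probs[:, 0].mean())
                gprob = np.zeros_like(probs)
                gprob[:, 0] = -lam / bs
                grad_fake = grad_fake + disc.backward(gprob).astype(grad_fake.dtype)
            gen.backward(grad_fake.astype(dtype))
            g_loss = c_loss_rep + lam * a_loss
            if not np.isfinite(g_loss):
                raise FloatingPointError(
                    f"non-finite generator loss at epoch {epoch}, step {step}"
                )
            opt_g.step()

            # --- discriminator step ---
            d_loss = 0.0
            if not cfg.freeze_discriminator:
                disc.zero_grad()
                p_real = disc(sim_b, training=True)
                greal = np.zeros_like(p_real)
                greal[:, 0] = -1.0 / bs
                disc.backward(greal)
                d_real = float(p_real[:, 0].mean())
                p_fake = disc(fake, training=True)  # fake is detached by construction
                gfake = np.zeros_like(p_fake)
                gfake[:, 0] = 1.0 / bs
                disc.backward(gfake)
                d_fake = float(p_fake[:, 0].mean())
                d_loss = (1.0 - d_real) + d_fake
                if not np.isfinite(d_loss):
                    raise FloatingPointError(
                        f"non-finite discriminator loss at epoch {epoch}, step {step}"
                    )
                opt_d.step()

            sums += (g_loss, c_loss_rep, a_loss, d_loss)
            n_batches += 1
            step += 1

        if n_batches:
            record = EpochRecord(
                epoch, *(sums / n_batches)
            )
            if val_list:
                record.validation_cc, record.validation_content = validate(params, val_list)
            history.records.append(record)
            logger.info(
                "epoch %d: gen=%.5f content=%.5f adv=%.5f disc=%.5f val_cc=%s",
                epoch, record.generator_loss, record.content_loss,
                record.adversarial_loss, record.discriminator_loss, record.validation_cc,
            )
        params.epoch = epoch
        if done:
            break
    return params, history


def search_learning_rate(
    pairs,
    val_pairs,
    cfg: TrainingConfig,
    gen_cfg: GeneratorConfig | None = None,
    disc_cfg: DiscriminatorConfig | None = None,
    rates: tuple[float, ...] = LEARNING_RATE_SEARCH_SPACE,
) -> tuple[float, dict[float, float]]:
    """Train once per candidate rate and pick the best validation CC.

    A desk-scale mirror of a grid search over generator/discriminator
    learning rates; not run by default anywhere.
    """
    scores: dict[float, float] = {}
    for lr in rates:
        trial = replace(cfg, lr_generator=lr, lr_discriminator=lr)
        params, _ = train(pairs, trial, gen_cfg, disc_cfg)
        scores[lr], _ = validate(params, val_pairs)
    best = max(scores, key=scores.__getitem__)
    return best, scores


def validate(params: GanParams, pairs) -> tuple[float, float]:
    """Mean CC(G(exp), sim) and mean content loss in inference mode."""
    pairs = _flatten(pairs)
    if not pairs:
        raise ValueError("validation set is empty")
    dtype = params.generator.head.W.value.dtype
    ccs: list[float] = []
    closses: list[float] = []
    for i in range(0, len(pairs), 16):
        chunk = pairs[i : i + 16]
        exp_b = np.stack([p.exp_cube for p in chunk]).astype(dtype)[:, None]
        sim_b = np.stack([p.sim_cube for p in chunk]).astype(dtype)[:, None]
        out = params.generator(exp_b, training=False)
        for j, p in enumerate(chunk):
            closses.append(content_loss(sim_b[j, 0], out[j, 0]))
            try:
                ccs.append(cross_correlation(out[j, 0], sim_b[j, 0]))
            except UndefinedCorrelationError:
                pass
    mean_cc = float(np.mean(ccs)) if ccs else float("nan")
    return mean_cc, float(np.mean(closses))
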