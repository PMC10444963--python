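"""Desk-scale demonstration configuration.

The published architecture (15 ResNet blocks / 32 channels, 10
discriminator layers) trained for 100 epochs is far beyond a single-CPU
NumPy budget, so demos, the acceptance battery and the CLI training command
use this reduced configuration: same code paths and cube geometry, smaller
channel counts and step counts.  Dropout is disabled here — with only 8
channels it removes too much capacity to learn anything in a few hundred
steps.
"""

from __future__ import annotations

from .gan_model import DiscriminatorConfig, GeneratorConfig
from .synthetic_fixtures import FixtureSpec
from .training import TrainingConfig

__all__ = ["tiny_fixture_spec", "tiny_generator_config", "tiny_discriminator_config",
           "tiny_training_config"]


def tiny_fixture_spec(seed: int = 42, n_structures: int = 20) -> FixtureSpec:
    """20 small toy structures with 5 A noisy inputs and 2 A targets."""
    return FixtureSpec(
        n_structures=n_structures, residues_min=12, residues_max=24, seed=seed
    )


def tiny_generator_config() -> GeneratorConfig:
    return GeneratorConfig(n_resnet_blocks=3, channels=8, dropout_p=0.0)


def tiny_discriminator_config() -> DiscriminatorConfig:
    return DiscriminatorConfig(
        n_conv_layers=4, base_channels=8, group_norm_group_size=8, dropout_p=0.0
    )


def tiny_training_config(seed: int = 42, max_steps: int = 300) -> TrainingConfig:
    return TrainingConfig(
        batch_size=8,
        epochs=max(1, (max_steps // 4) or 1),
        max_steps=max_steps,
        lr_generator=5e-3,
        lr_discriminator=5e-3,
        adversarial_weight=1e-3,
        seed=seed,
    )
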