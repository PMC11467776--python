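"""Configuration of the dose-regression network and its training recipe."""

from __future__ import annotations

from dataclasses import dataclass, field


def _default_groups(base_features: int) -> int:
    """Default group-norm group count: 6 when it divides the base width
    (so 6 for the clinical-scale base of 24), otherwise the largest divisor
    not exceeding 8 (8 for base 8). Every level width is base_features x 2^k,
    so any divisor of the base divides all level widths."""
    if base_features % 6 == 0:
        return 6
    for g in range(min(8, base_features), 0, -1):
        if base_features % g == 0:
            return g
    return 1


@dataclass(frozen=True)
class NetConfig:
    """Architecture of the 3D U-Net variant.

    ``input_dims`` is (nx, ny, nz) voxels; features double after each of the
    ``levels - 1`` downsampling steps starting from ``base_features``.
    """

    levels: int = 4
    base_features: int = 24
    kernel: int = 3
    groupnorm_groups: int | None = None  # None -> largest divisor <= 8
    dropblock_size: int = 5  # maximal block edge, voxels
    dropblock_rate: float = 0.1
    input_dims: tuple[int, int, int] = (256, 256, 16)

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 levels")
        if self.kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        if not 0 <= self.dropblock_rate < 1:
            raise ValueError("dropblock_rate must lie in [0, 1)")
        f = 2 ** (self.levels - 1)
        if any(d % f != 0 for d in self.input_dims):
            raise ValueError(
                f"input dims {self.input_dims} must be divisible by {f} "
                f"for {self.levels} levels"
            )
        g = self.groups
        if self.base_features % g != 0:
            raise ValueError("groupnorm_groups must divide base_features")

    @property
    def groups(self) -> int:
        return self.groupnorm_groups or _default_groups(self.base_features)

    @property
    def level_widths(self) -> list[int]:
        return [self.base_features * 2**k for k in range(self.levels)]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe: central-axial-slice MSE with AdamW."""

    lr: float = 5e-4
    batch: int = 4
    patience: int = 30  # epochs without validation-loss decrease
    seed: int = 0
    max_epochs: int = 10000
    weight_decay: float = 1e-2
    betas: tuple[float, float] = (0.9, 0.999)
    eps: float = 1e-8
    #: "none" keeps the initial rate throughout; "cosine" anneals to lr/10
    #: over max_epochs (useful for short runs where the stochastic
    #: augmentations set a noise floor at constant rate).
    lr_schedule: str = "none"

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.lr_schedule not in ("none", "cosine"):
            raise ValueError("lr_schedule must be 'none' or 'cosine'")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch < 1 or self.max_epochs < 1:
            raise ValueError("batch and max_epochs must be >= 1")


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentations.

    A random factor drawn uniformly from ``scale_range`` multiplies the
    painted fluence intensities and the dose target together, leaving RED
    untouched (forces the model to read the fluence, not just anatomy);
    optionally both volumes are then rotated by a random angle about the
    superior-inferior axis.
    """

    scale_range: tuple[float, float] = (0.0, 5.0)
    rotate: bool = True
    rotation_range: tuple[float, float] = (0.0, 360.0)

    def __post_init__(self) -> None:
        if self.scale_range[0] < 0 or self.scale_range[1] < self.scale_range[0]:
            raise ValueError("scale_range must be ordered with lower bound >= 0")
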