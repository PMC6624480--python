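"""Architecture and training configuration for the multi-stream network."""

from __future__ import annotations

import dataclasses

__all__ = ["NetConfig", "TrainConfig", "net_preset", "train_preset"]

FULL_SCALE_FILTERS = (64, 128, 256, 256, 512, 512, 512, 512)
DESK_FILTERS = (8, 16, 32, 32, 64, 64, 64, 64)


@dataclasses.dataclass(frozen=True)
class NetConfig:
    """One stream's architecture: 8 conv, 5 max-pool, 2 fc, softmax output.

    ``pool_kernels`` lists the five pooling kernels (kernel == stride);
    the temporal stream's first pool is (2, 2, 1) so the frame axis keeps
    full resolution through the early layers.  ``patch_wh`` is the
    in-plane patch size and ``slices_per_patch`` the through-plane extent.
    """

    conv_filters: tuple[int, ...] = DESK_FILTERS
    kernel: tuple[int, int, int] = (3, 3, 3)
    fc_units: int = 64
    pool_kernels: tuple[tuple[int, int, int], ...] = ((2, 2, 2),) * 5
    patch_wh: int = 8
    slices_per_patch: int = 4
    classes: int = 2

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 8:
            raise ValueError("the architecture has exactly 8 convolution layers")
        if len(self.pool_kernels) != 5:
            raise ValueError("the architecture has exactly 5 pooling layers")
        if self.patch_wh < 8:
            raise ValueError(
                "patch_wh must be >= 8: five halving pools need at least "
                "8 in-plane voxels to keep the early feature maps non-trivial"
            )


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Mini-batch SGD settings (batch 50, lr 1e-3, momentum 0.9 at full scale)."""

    batch: int = 50
    epochs: int = 50
    lr: float = 1e-3
    momentum: float = 0.9
    seed: int = 0


def net_preset(name: str, stream: str) -> NetConfig:
    """Named architecture presets.

    ``full``: filters (64,...,512), 4096 fc units, 32-voxel patches — the
    full-scale network.  ``desk``: the architecture-isomorphic reduction
    (filters (8,...,64), 64 fc units, 8-voxel patches) sized for CPU
    training on the synthetic phantoms.
    """
    if stream not in ("spatial", "temporal"):
        raise ValueError(f"unknown stream {stream!r}")
    first_pool = (2, 2, 1) if stream == "temporal" else (2, 2, 2)
    pools = (first_pool,) + ((2, 2, 2),) * 4
    if name == "full":
        return NetConfig(
            conv_filters=FULL_SCALE_FILTERS, fc_units=4096, pool_kernels=pools,
            patch_wh=32, slices_per_patch=8,
        )
    if name == "desk":
        return NetConfig(
            conv_filters=DESK_FILTERS, fc_units=64, pool_kernels=pools,
            patch_wh=8, slices_per_patch=4,
        )
    raise ValueError(f"unknown preset {name!r}")


def train_preset(name: str) -> TrainConfig:
    if name == "full":
        return TrainConfig(batch=50, epochs=50, lr=1e-3, momentum=0.9)
    if name == "desk":
        # same optimizer settings; only the epoch count is scaled down for
        # the small, cleanly separable phantom patch sets
        return TrainConfig(batch=50, epochs=12, lr=1e-3, momentum=0.9)
    raise ValueError(f"unknown preset {name!r}")
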