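"""Stream construction and training for the multi-stream 3D CNN."""

from __future__ import annotations

import numpy as np

from ..preprocess import DegenerateInputError
from .config import NetConfig, TrainConfig
from .labeling import LabeledPatchSet
from .nn import Conv3D, Dense, Flatten, MaxPool3D, ReLU, Sequential

__all__ = ["build_stream", "train_stream", "stream_input", "stream_forward"]

# conv layers after which a pooling layer follows (0-based conv index):
# conv1-pool, conv2-pool, conv3, conv4-pool, conv5, conv6-pool, conv7, conv8-pool
_POOL_AFTER = {0: 0, 1: 1, 3: 2, 5: 3, 7: 4}


def _net_volume_shape(cfg: NetConfig, stream: str, n_frames: int) -> tuple[int, tuple[int, int, int]]:
    """(channels, (d1, d2, d3)) of the network input for one stream.

    The leading axis of the stream layout acts as the channel axis; the 3D
    convolution runs over the remaining three, ordered (w, h, last) where
    ``last`` is slices for the spatial stream and frames for the temporal
    stream — so the temporal stream's (2, 2, 1) first pool halves only the
    in-plane axes and preserves frame resolution.
    """
    if stream == "spatial":
        return n_frames, (cfg.patch_wh, cfg.patch_wh, cfg.slices_per_patch)
    if stream == "temporal":
        return cfg.slices_per_patch, (cfg.patch_wh, cfg.patch_wh, n_frames)
    raise ValueError(f"unknown stream {stream!r}")


def build_stream(
    cfg: NetConfig, stream: str, n_frames: int, seed: int = 0
) -> Sequential:
    """Build one stream: 8 conv(3x3x3) + 5 ceil-mode max-pool + 2 fc + softmax head.

    Raises a config error when the patch geometry cannot feed the five
    pooling stages (minimum in-plane size 8).
    """
    channels, dims = _net_volume_shape(cfg, stream, n_frames)
    rng = np.random.default_rng(seed)
    layers: list = []
    in_ch = channels
    d = np.asarray(dims)
    for i, filters in enumerate(cfg.conv_filters):
        eff_taps = int(np.prod([min(k, dim) for k, dim in zip(cfg.kernel, d)]))
        layers.append(
            Conv3D(in_ch, filters, rng, kernel=cfg.kernel, fan_in=in_ch * eff_taps)
        )
        layers.append(ReLU())
        in_ch = filters
        if i in _POOL_AFTER:
            k = cfg.pool_kernels[_POOL_AFTER[i]]
            layers.append(MaxPool3D(k))
            d = -(-d // np.asarray(k))  # ceil division
    flat = int(in_ch * d.prod())
    layers.append(Flatten())
    layers.append(Dense(flat, cfg.fc_units, rng))
    layers.append(ReLU())
    layers.append(Dense(cfg.fc_units, cfg.fc_units, rng))
    layers.append(ReLU())
    layers.append(Dense(cfg.fc_units, cfg.classes, rng))  # softmax output head
    return Sequential(layers)


def stream_input(patches: np.ndarray, stream: str) -> np.ndarray:
    """Map stored patch layouts to network input (N, C, w, h, last).

    Stored layouts are (N, f, s_p, wh, wh) for the spatial stream and
    (N, s_p, f, wh, wh) for the temporal stream; in both the leading axis
    is the channel axis and the trailing volume axis is the one the first
    temporal pool preserves.
    """
    if stream not in ("spatial", "temporal"):
        raise ValueError(f"unknown stream {stream!r}")
    # (N, C, last, wh, wh) -> (N, C, wh, wh, last)
    return np.ascontiguousarray(np.transpose(patches, (0, 1, 3, 4, 2)))


def stream_forward(
    model: Sequential, patches: np.ndarray, stream: str, batch: int = 256
) -> np.ndarray:
    """Softmax scores for a stack of stored-layout patches, batched."""
    x = stream_input(patches, stream)
    out = [model.predict_proba(x[i:i + batch]) for i in range(0, len(x), batch)]
    return np.concatenate(out) if out else np.empty((0, 2))


def train_stream(
    model: Sequential,
    patches: LabeledPatchSet,
    stream: str,
    tcfg: TrainConfig,
) -> list[float]:
    """Mini-batch SGD with momentum on cross-entropy; returns per-epoch mean loss.

    The batch order is drawn from a generator seeded with ``tcfg.seed``,
    so (seed, data, config) fully determine the trained weights.
    """
    y = patches.labels
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("training data must contain both classes")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise DegenerateInputError("need at least 2 examples per class")
    x = stream_input(
        patches.spatial_patches if stream == "spatial" else patches.temporal_patches,
        stream,
    ).astype(np.float32)
    n = len(y)
    batch = min(tcfg.batch, n)
    rng = np.random.default_rng(tcfg.seed)
    from .nn import SGDMomentum

    opt = SGDMomentum(model, lr=tcfg.lr, momentum=tcfg.momentum)
    trace: list[float] = []
    for _ in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            sel = order[start:start + batch]
            loss = model.loss_and_backward(x[sel], y[sel])
            if tcfg.lr > 0:
                opt.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return trace
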