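"""Lightweight encoder-decoder lesion segmentation.

The encoder alternates downsampling blocks (a 3x3 stride-2 convolution
concatenated channel-wise with a 2x2 max pool) with split-shuffle residual
units: the channels are split in half, each half passes through factorized
3x1 / 1x3 convolutions (the second half dilated to widen the receptive
field), the halves are re-concatenated, channel-shuffled and added back to
the input.  The decoder is an attention pyramid: stride-2 convolutions of
kernel size 3, 5 and 7 are fused coarse-to-fine into a spatial attention map
that multiplies a 1x1-projected encoder map pixel-wise; a global-average-
pooling branch is added, and the result is bilinearly upsampled to the input
resolution to give per-pixel lesion logits.

Multispectral stacks enter the 2-D network after uniform band averaging
(Lambda wavelengths -> ``in_channels`` bands), which keeps CPU training
tractable; training is plain full-batch gradient descent on per-pixel binary
cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .synthetic_data import LabeledStack

__all__ = [
    "LedNetConfig",
    "SegmenterModel",
    "downsample_block",
    "ssnbt_block",
    "apn_decode",
    "segment",
    "train_segmenter",
    "forward_logits",
    "reduce_bands",
    "dice_coefficient",
    "save_segmenter",
    "load_segmenter",
]

APN_KERNELS = (3, 5, 7)
GRAD_CLIP = 5.0


@dataclass(frozen=True)
class LedNetConfig:
    in_channels: int = 8
    base_channels: int = 16
    n_ssnbt_per_stage: int = 2
    n_downsamples: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_downsamples < 1:
            raise ValueError("n_downsamples must be >= 1")
        if self.n_ssnbt_per_stage < 0:
            raise ValueError("n_ssnbt_per_stage must be >= 0")
        if self.base_channels <= self.in_channels:
            raise ValueError("base_channels must exceed in_channels (concat downsampling)")
        if self.base_channels % 2 != 0:
            raise ValueError("base_channels must be even (split-shuffle units)")

    def stage_channels(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.n_downsamples)]


@dataclass
class SegmenterModel:
    config: LedNetConfig
    params: dict[str, Tensor]
    loss_history: list[float] = field(default_factory=list)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


def _he(rng: np.random.Generator, shape: tuple[int, ...]) -> Tensor:
    fan_in = int(np.prod(shape[1:]))
    return Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape), requires_grad=True)


def init_segmenter(config: LedNetConfig) -> SegmenterModel:
    rng = np.random.default_rng(config.seed)
    params: dict[str, Tensor] = {}
    chans = config.stage_channels()
    c_in = config.in_channels
    for s, c_out in enumerate(chans):
        conv_out = c_out - c_in
        params[f"ds{s}.w"] = _he(rng, (conv_out, c_in, 3, 3))
        params[f"ds{s}.b"] = Tensor(np.zeros(conv_out), requires_grad=True)
        half = c_out // 2
        for u in range(config.n_ssnbt_per_stage):
            for br in (1, 2):
                params[f"s{s}u{u}.b{br}.w31"] = _he(rng, (half, half, 3, 1))
                params[f"s{s}u{u}.b{br}.b31"] = Tensor(np.zeros(half), requires_grad=True)
                params[f"s{s}u{u}.b{br}.w13"] = _he(rng, (half, half, 1, 3))
                params[f"s{s}u{u}.b{br}.b13"] = Tensor(np.zeros(half), requires_grad=True)
        c_in = c_out
    c_enc = chans[-1]
    for i, k in enumerate(APN_KERNELS):
        cin_p = c_enc if i == 0 else 1
        params[f"apn.p{i}.w"] = _he(rng, (1, cin_p, k, k))
        params[f"apn.p{i}.b"] = Tensor(np.zeros(1), requires_grad=True)
    params["apn.proj.w"] = _he(rng, (1, c_enc, 1, 1))
    params["apn.proj.b"] = Tensor(np.zeros(1), requires_grad=True)
    params["apn.gap.w"] = _he(rng, (1, c_enc, 1, 1))
    params["apn.gap.b"] = Tensor(np.zeros(1), requires_grad=True)
    return SegmenterModel(config=config, params=params)


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

def downsample_block(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Concat of (3x3 conv, stride 2) and (2x2 max pool) branches; halves H, W."""
    if x.data.shape[2] < 2 or x.data.shape[3] < 2:
        raise ValueError("spatial dims must be >= 2 to downsample")
    conv_branch = nn.conv2d(x, w, b, stride=2, padding=1)
    pool_branch = nn.maxpool2x2(x)
    return nn.relu(nn.concat_channels([conv_branch, pool_branch]))


def ssnbt_block(x: Tensor, weights: dict[str, Tensor], dilation: int = 1) -> Tensor:
    """Split-shuffle residual unit; shape-preserving.

    Each half runs 3x1 -> ReLU -> 1x3 factorized convolutions (second half
    dilated); the shuffled concat is added to the input, so zero weights give
    the identity.
    """
    if x.data.shape[1] % 2 != 0:
        raise ValueError("channel count must be even")

    def branch(h: Tensor, tag: str, dil: int) -> Tensor:
        h = nn.conv2d(h, weights[f"{tag}.w31"], weights[f"{tag}.b31"],
                      dilation=dil, padding=(dil, 0))
        h = nn.relu(h)
        h = nn.conv2d(h, weights[f"{tag}.w13"], weights[f"{tag}.b13"],
                      dilation=dil, padding=(0, dil))
        return h

    h1, h2 = nn.split_channels(x)
    b1 = branch(h1, "b1", 1)
    b2 = branch(h2, "b2", dilation)
    mixed = nn.channel_shuffle(nn.concat_channels([b1, b2]), groups=2)
    return nn.relu(nn.add(x, mixed))


def apn_decode(
    enc: Tensor, weights: dict[str, Tensor], out_hw: tuple[int, int]
) -> Tensor:
    """Attention-pyramid decoder producing 1-channel logits at ``out_hw``.

    Pyramid levels: linear stride-2 convs with kernels 3/5/7 fused
    coarse-to-fine, passed through tanh to give a bounded spatial attention
    map (zero weights -> zero attention, so the output then reduces to the
    pooling-branch term); the 1x1-projected encoder map is multiplied by it
    pixel-wise, the global-average-pooling branch is added, and the sum is
    upsampled bilinearly.
    """
    h, w = enc.data.shape[2], enc.data.shape[3]
    if h < 2 ** len(APN_KERNELS) or w < 2 ** len(APN_KERNELS):
        raise ValueError(
            f"encoder map {h}x{w} smaller than the deepest pyramid level "
            f"(needs >= {2 ** len(APN_KERNELS)})"
        )
    levels: list[Tensor] = []
    cur = enc
    for i, k in enumerate(APN_KERNELS):
        cur = nn.conv2d(cur, weights[f"p{i}.w"], weights[f"p{i}.b"],
                        stride=2, padding=(k - 1) // 2)
        levels.append(cur)
    fused = levels[-1]
    for lvl in reversed(levels[:-1]):
        fused = nn.add(nn.upsample_bilinear(fused, lvl.data.shape[2:]), lvl)
    attention = nn.tanh(nn.upsample_bilinear(fused, (h, w)))

    proj = nn.conv2d(enc, weights["proj.w"], weights["proj.b"])
    gated = nn.mul(proj, attention)
    gap = nn.conv2d(nn.global_avg_pool(enc), weights["gap.w"], weights["gap.b"])
    out = nn.add(gated, gap)
    return nn.upsample_bilinear(out, out_hw)


def _sub_weights(params: dict[str, Tensor], prefix: str) -> dict[str, Tensor]:
    plen = len(prefix) + 1
    return {k[plen:]: v for k, v in params.items() if k.startswith(prefix + ".")}


def forward_logits(model: SegmenterModel, batch: np.ndarray) -> Tensor:
    """Per-pixel lesion logits (N, 1, H, W) for a band-reduced (N, C, H, W) batch."""
    cfg = model.config
    if batch.ndim != 4 or batch.shape[1] != cfg.in_channels:
        raise ValueError(
            f"batch must be N x {cfg.in_channels} x H x W, got {batch.shape}"
        )
    x = Tensor(batch)
    dilations = [1 + u for u in range(cfg.n_ssnbt_per_stage)]
    for s in range(cfg.n_downsamples):
        x = downsample_block(x, model.params[f"ds{s}.w"], model.params[f"ds{s}.b"])
        for u in range(cfg.n_ssnbt_per_stage):
            x = ssnbt_block(x, _sub_weights(model.params, f"s{s}u{u}"), dilation=dilations[u])
    return apn_decode(x, _sub_weights(model.params, "apn"), batch.shape[2:])


def reduce_bands(stack: np.ndarray, n_bands: int) -> np.ndarray:
    """Uniform averaging of the Lambda axis into ``n_bands`` contiguous bands."""
    stack = np.asarray(stack, dtype=float)
    if stack.shape[2] < n_bands:
        raise ValueError("cannot average into more bands than wavelengths")
    groups = np.array_split(np.arange(stack.shape[2]), n_bands)
    return np.stack([stack[:, :, g].mean(axis=2) for g in groups], axis=2)


def _as_batch(stacks: list[np.ndarray], in_channels: int) -> np.ndarray:
    """Band-reduce, z-score each band per specimen, and stack to NCHW.

    Per-band standardisation conditions plain gradient descent; a constant
    band maps to zeros.
    """
    reduced = []
    for s in stacks:
        s = np.asarray(s, dtype=float)
        if s.shape[2] != in_channels:
            s = reduce_bands(s, in_channels)
        chw = s.transpose(2, 0, 1)
        mu = chw.mean(axis=(1, 2), keepdims=True)
        sd = chw.std(axis=(1, 2), keepdims=True) + 1e-8
        reduced.append((chw - mu) / sd)
    return np.stack(reduced)


def segment(stack_or_features: np.ndarray | LabeledStack, model: SegmenterModel) -> np.ndarray:
    """Per-pixel lesion probability map in [0, 1] for one H x W x Lambda stack.

    Stacks with more wavelengths than the model's ``in_channels`` are reduced
    by uniform band averaging first; a stack with fewer raises.
    """
    stack = stack_or_features.stack if isinstance(stack_or_features, LabeledStack) else stack_or_features
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected an H x W x Lambda stack")
    if stack.shape[2] < model.config.in_channels:
        raise ValueError(
            f"stack has {stack.shape[2]} wavelengths but the model expects "
            f">= {model.config.in_channels}"
        )
    batch = _as_batch([stack], model.config.in_channels)
    logits = forward_logits(model, batch)
    return nn.sigmoid_array(logits.data[0, 0])


def train_segmenter(
    dataset: list[LabeledStack],
    config: LedNetConfig,
    n_steps: int = 500,
    lr: float = 0.5,
) -> SegmenterModel:
    """Full-batch gradient descent on per-pixel binary cross-entropy.

    The step is scaled down whenever the global gradient norm exceeds
    ``GRAD_CLIP`` (the multiplicative attention path can spike early on).
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    model = init_segmenter(config)
    batch = _as_batch([d.stack for d in dataset], config.in_channels)
    targets = np.stack([d.mask.astype(float) for d in dataset])[:, None]
    for _ in range(n_steps):
        model.zero_grad()
        logits = forward_logits(model, batch)
        loss = nn.bce_with_logits(logits, targets)
        loss.backward()
        gnorm = np.sqrt(
            sum(float((p.grad**2).sum()) for p in model.parameters() if p.grad is not None)
        )
        scale = min(1.0, GRAD_CLIP / max(gnorm, 1e-12))
        for p in model.parameters():
            if p.grad is not None:
                p.data -= lr * scale * p.grad
        model.loss_history.append(float(loss.data))
    return model


def save_segmenter(model: SegmenterModel, path) -> None:
    """Serialise config, weights and loss history to one JSON container."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    payload = {
        "config": asdict(model.config),
        "params": {k: {"shape": list(v.data.shape), "data": v.data.ravel().tolist()}
                   for k, v in model.params.items()},
        "loss_history": model.loss_history,
    }
    Path(path).write_text(json.dumps(payload))


def load_segmenter(path) -> SegmenterModel:
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    config = LedNetConfig(**payload["config"])
    model = init_segmenter(config)
    for k, spec in payload["params"].items():
        model.params[k].data = np.asarray(spec["data"]).reshape(spec["shape"])
    model.loss_history = list(payload["loss_history"])
    return model


def dice_coefficient(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """2|A&B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(pred_mask, dtype=bool)
    b = np.asarray(true_mask, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)
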