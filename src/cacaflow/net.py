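"""Double-head residual encoder with classifier head and U-Net decoder.

Two independent-weight heads ingest the synchronized patch pair: the
non-contrast patch (where CACs live, as subtle texture/brightness cues)
and the phase-matched contrast-enhanced patch (anatomical context).
Each head is Block1 (7x7 conv, batch norm, ReLU, stride 2) followed by
Block2 (a residual double-conv unit).  The heads' features are
concatenated, reduced back to the standard first-stage width by a 1x1
convolution, and passed through four residual tail stages (Block3-6,
standard 18-layer-residual-network stages of two basic blocks each,
stride 2), ending in global average pooling and a fully connected layer
whose sigmoid is the patch-level CAC probability.

A U-Net-style decoder mirrors the encoder: bilinear 2x upsampling,
concatenation of the corresponding encoder stage's features (Blocks 3-5,
plus the sum of the two heads' Block2 outputs at the shallowest skip),
and a double conv/norm/ReLU per stage, ending in a 1-channel sigmoid ROI
score map at patch resolution.  At inference the classifier gates the
map: patches the classifier calls CAC-free contribute an empty mask.

Training is from scratch — angiography is single-channel grayscale and no
pretrained weights are assumed.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np

from . import _nn
from ._nn import (
    BasicBlock,
    BatchNorm2d,
    Conv2d,
    ConvBnRelu,
    Linear,
    Module,
    Tensor,
    add,
    concat_channels,
    global_avg_pool,
    relu,
    sigmoid,
    upsample_bilinear2x,
)

__all__ = [
    "NetConfig",
    "NetOutputs",
    "DoubleHeadResUNet",
    "forward",
    "gate",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclasses.dataclass
class NetConfig:
    """Architecture hyperparameters.

    Defaults are the standard 18-layer residual widths; tests and desk-
    scale runs shrink them.  patch_size must be divisible by 32 (five
    stride-2 stages).  blocks_per_stage=2 gives the standard stage depth;
    1 halves the tail for cheap overfit studies.
    """

    in_channels_per_head: int = 1
    head_channels: int = 64
    tail_block_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    decoder_final_channels: int = 32
    patch_size: int = 256
    classifier_threshold: float = 0.5
    roi_threshold: float = 0.5
    blocks_per_stage: int = 2
    seed: int = 0

    def __post_init__(self):
        self.tail_block_channels = tuple(self.tail_block_channels)
        if self.patch_size % 32 != 0:
            raise ValueError("patch_size must be divisible by 32 (five stride-2 stages)")
        if len(self.tail_block_channels) != 4:
            raise ValueError("exactly four tail stage widths required")
        if self.blocks_per_stage < 1:
            raise ValueError("blocks_per_stage must be >= 1")


@dataclasses.dataclass
class NetOutputs:
    """Per-patch-pair network outputs (plus tensors for training/Grad-CAM)."""

    cac_probability: float
    roi_map: np.ndarray                    # (patch, patch) scores in [0, 1]
    skip_features: dict                    # stage name -> feature array
    gradcam_source: Tensor                 # Block6 activations (grad retained)
    probability_tensor: Tensor
    roi_map_tensor: Tensor


class _Head(Module):
    def __init__(self, cin, width, *, rng):
        self.block1 = ConvBnRelu(cin, width, 7, stride=2, pad=3, rng=rng)
        self.block2 = BasicBlock(width, width, stride=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.block2(self.block1(x))


class _Stage(Module):
    """One tail stage: blocks_per_stage residual units, first at stride 2."""

    def __init__(self, cin, cout, n_blocks, *, rng):
        self.blocks = [BasicBlock(cin if i == 0 else cout, cout,
                                  stride=2 if i == 0 else 1, rng=rng)
                       for i in range(n_blocks)]

    def __call__(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class _DecoderStage(Module):
    """Bilinear 2x upsample, concatenate skip, double conv/norm/ReLU."""

    def __init__(self, cin, skip_c, cout, *, rng):
        self.conv1 = ConvBnRelu(cin + skip_c, cout, 3, pad=1, rng=rng)
        self.conv2 = ConvBnRelu(cout, cout, 3, pad=1, rng=rng)

    def __call__(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = upsample_bilinear2x(x)
        if skip is not None:
            x = concat_channels(x, skip)
        return self.conv2(self.conv1(x))


class DoubleHeadResUNet(Module):
    def __init__(self, cfg: NetConfig | None = None):
        cfg = cfg or NetConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        hc = cfg.head_channels
        t = cfg.tail_block_channels
        self.head_nc = _Head(cfg.in_channels_per_head, hc, rng=rng)
        self.head_ce = _Head(cfg.in_channels_per_head, hc, rng=rng)
        self.reduce = ConvBnRelu(2 * hc, t[0], 1, rng=rng)   # absorb the doubled width
        self.stage3 = _Stage(t[0], t[0], cfg.blocks_per_stage, rng=rng)
        self.stage4 = _Stage(t[0], t[1], cfg.blocks_per_stage, rng=rng)
        self.stage5 = _Stage(t[1], t[2], cfg.blocks_per_stage, rng=rng)
        self.stage6 = _Stage(t[2], t[3], cfg.blocks_per_stage, rng=rng)
        self.classifier_fc = Linear(t[3], 1, rng=rng)
        self.dec5 = _DecoderStage(t[3], t[2], t[2], rng=rng)
        self.dec4 = _DecoderStage(t[2], t[1], t[1], rng=rng)
        self.dec3 = _DecoderStage(t[1], t[0], t[0], rng=rng)
        self.dec2 = _DecoderStage(t[0], hc, hc, rng=rng)
        self.dec1 = _DecoderStage(hc, 0, cfg.decoder_final_channels, rng=rng)
        self.final_conv = Conv2d(cfg.decoder_final_channels, 1, 1, rng=rng)

    # -- parameter groups -------------------------------------------------
    def encoder_modules(self) -> list[Module]:
        return [self.head_nc, self.head_ce, self.reduce,
                self.stage3, self.stage4, self.stage5, self.stage6,
                self.classifier_fc]

    def decoder_modules(self) -> list[Module]:
        return [self.dec5, self.dec4, self.dec3, self.dec2, self.dec1, self.final_conv]

    def encoder_parameters(self) -> list[Tensor]:
        return [p for m in self.encoder_modules() for p in m.parameters()]

    def decoder_parameters(self) -> list[Tensor]:
        return [p for m in self.decoder_modules() for p in m.parameters()]

    def encoder_parameter_count(self) -> int:
        return sum(p.data.size for p in self.encoder_parameters())

    # -- forward ----------------------------------------------------------
    def forward_batch(self, nc: Tensor, ce: Tensor, decode: bool = True):
        """Batched forward pass.

        Returns (classifier logit tensor (N,1), ROI-map logit tensor
        (N,1,H,W) or None when decode=False, block6 activations, skip
        tensors dict).  Stage-1 training sets decode=False: the decoder
        does not influence the classifier and skipping it saves most of
        the compute.
        """
        s2a = self.head_nc(nc)
        s2b = self.head_ce(ce)
        skip2 = add(s2a, s2b)            # one skip per head resolution, summed
        x = self.reduce(concat_channels(s2a, s2b))
        b3 = self.stage3(x)
        b4 = self.stage4(b3)
        b5 = self.stage5(b4)
        b6 = self.stage6(b5)
        logit = self.classifier_fc(global_avg_pool(b6))
        skips = {"head_nc_block2": s2a, "head_ce_block2": s2b,
                 "block3": b3, "block4": b4, "block5": b5}
        if not decode:
            return logit, None, b6, skips
        d = self.dec5(b6, b5)
        d = self.dec4(d, b4)
        d = self.dec3(d, b3)
        d = self.dec2(d, skip2)
        d = self.dec1(d, None)
        map_logit = self.final_conv(d)
        return logit, map_logit, b6, skips


def _validate_patch(patch: np.ndarray, size: int, name: str) -> np.ndarray:
    p = np.asarray(patch, dtype=np.float32)
    if p.shape != (size, size):
        raise ValueError(f"{name} patch must be {size}x{size}, got {p.shape}")
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{name} patch contains non-finite values")
    return p


def forward(model: DoubleHeadResUNet, nc_patch: np.ndarray, ce_patch: np.ndarray) -> NetOutputs:
    """Run one synchronized patch pair through the network (eval mode)."""
    size = model.cfg.patch_size
    nc = _validate_patch(nc_patch, size, "non-contrast")
    ce = _validate_patch(ce_patch, size, "contrast")
    model.eval()
    logit, map_logit, b6, skips = model.forward_batch(
        Tensor(nc[None, None]), Tensor(ce[None, None])
    )
    prob = sigmoid(logit)
    roi = sigmoid(map_logit)
    return NetOutputs(
        cac_probability=float(prob.data.ravel()[0]),
        roi_map=roi.data[0, 0].astype(np.float64),
        skip_features={k: v.data[0] for k, v in skips.items()},
        gradcam_source=b6,
        probability_tensor=prob,
        roi_map_tensor=roi,
    )


def gate(outputs: NetOutputs, cfg: NetConfig) -> np.ndarray:
    """Classifier-gated binarization of the ROI map.

    A probability below the classifier threshold vetoes the whole patch
    (all-zero mask); at or above it (ties count as positive) the ROI map
    is thresholded.  Raising the classifier threshold can therefore never
    add foreground pixels.
    """
    if outputs.cac_probability < cfg.classifier_threshold:
        return np.zeros_like(outputs.roi_map, dtype=np.uint8)
    return (outputs.roi_map >= cfg.roi_threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = "cacaflow-net-1"


def save_checkpoint(model: DoubleHeadResUNet, path) -> pathlib.Path:
    """Serialize weights, running statistics and the NetConfig."""
    path = pathlib.Path(path)
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    cfg = dataclasses.asdict(model.cfg)
    cfg["tail_block_channels"] = list(cfg["tail_block_channels"])
    np.savez(path, __config__=json.dumps({"version": CHECKPOINT_VERSION, "cfg": cfg}),
             **arrays)
    return path


def load_checkpoint(path) -> DoubleHeadResUNet:
    with np.load(pathlib.Path(path).with_suffix(".npz")
                 if not str(path).endswith(".npz") else path, allow_pickle=False) as z:
        meta = json.loads(str(z["__config__"]))
        if meta["version"] != CHECKPOINT_VERSION:
            raise ValueError(f"unknown checkpoint version {meta['version']}")
        cfg = meta["cfg"]
        cfg["tail_block_channels"] = tuple(cfg["tail_block_channels"])
        model = DoubleHeadResUNet(NetConfig(**cfg))
        for slot, key in zip(model.state_arrays(), (f"arr_{i}" for i in range(len(z) - 1))):
            slot[...] = z[key]
    return model
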