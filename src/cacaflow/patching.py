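"""Five-window patching of frames and reassembly of patch predictions.

Each frame (512x512 in the clinical protocol) is partitioned into five
overlapping 256x256 windows — the four corners plus the center, the only
symmetric five-window cover of a 512 grid by 256 windows.  Patching keeps
the small CACs at a workable scale while retaining global context, and
the overlap acts as a mild augmentation.  At inference the per-patch ROI
predictions are fused back to the frame grid with a pixel-wise OR
(recall-favoring, appropriate for assistive region proposal).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import MaskImage

__all__ = ["PatchSet", "patch_offsets", "partition", "reassemble", "PATCH_SIZE"]

PATCH_SIZE = 256


@dataclasses.dataclass
class PatchSet:
    """The five patches of one synchronized frame pair."""

    offsets: list[tuple[int, int]]                    # (row, col) top-left corners
    size: int
    image_patches: list[tuple[np.ndarray, np.ndarray]]  # (non-contrast, contrast)
    labels: list[int] | None = None                   # CAC-presence flags
    roi_gt_patches: list[np.ndarray] | None = None    # decoder targets
    cac_patches: list[np.ndarray] | None = None       # raw CAC mask crops


def patch_offsets(frame_shape: tuple[int, int], size: int = PATCH_SIZE) -> list[tuple[int, int]]:
    """Four corner windows plus the center window."""
    h, w = frame_shape
    if h < size or w < size:
        raise ValueError(f"frame {frame_shape} smaller than patch size {size}")
    return [
        (0, 0),
        (0, w - size),
        (h - size, 0),
        (h - size, w - size),
        ((h - size) // 2, (w - size) // 2),
    ]


def _crop(img: np.ndarray, offset: tuple[int, int], size: int) -> np.ndarray:
    r, c = offset
    return img[r:r + size, c:c + size]


def partition(
    frame_pair: tuple[np.ndarray, np.ndarray],
    cac_mask: MaskImage | None = None,
    roi_gt: MaskImage | None = None,
    size: int = PATCH_SIZE,
) -> PatchSet:
    """Split a synchronized (non-contrast, contrast) frame pair into the
    five windows; when a fused CAC mask is given, label each patch 1 iff
    its CAC crop contains at least one foreground pixel, and crop the ROI
    ground truth alongside when provided."""
    nc, ce = frame_pair
    if nc.shape != ce.shape:
        raise ValueError("the two frames of a pair must share one shape")
    offsets = patch_offsets(nc.shape, size)
    image_patches = [(_crop(nc, o, size), _crop(ce, o, size)) for o in offsets]
    labels = cac_patches = roi_patches = None
    if cac_mask is not None:
        if cac_mask.pixels.shape != nc.shape:
            raise ValueError("CAC mask shape must match the frame shape")
        cac_patches = [_crop(cac_mask.pixels, o, size) for o in offsets]
        labels = [int(p.any()) for p in cac_patches]
    if roi_gt is not None:
        if roi_gt.pixels.shape != nc.shape:
            raise ValueError("ROI ground-truth shape must match the frame shape")
        roi_patches = [_crop(roi_gt.pixels, o, size) for o in offsets]
    return PatchSet(
        offsets=offsets,
        size=size,
        image_patches=image_patches,
        labels=labels,
        roi_gt_patches=roi_patches,
        cac_patches=cac_patches,
    )


def reassemble(
    patch_masks: list[np.ndarray],
    offsets: list[tuple[int, int]],
    frame_shape: tuple[int, int],
    frame_index: int = 0,
) -> MaskImage:
    """Fuse per-patch binary masks to the frame grid with a pixel-wise OR."""
    if len(patch_masks) != len(offsets):
        raise ValueError("one offset per patch mask required")
    out = np.zeros(frame_shape, dtype=np.uint8)
    for m, (r, c) in zip(patch_masks, offsets):
        m = np.asarray(m)
        if r < 0 or c < 0 or r + m.shape[0] > frame_shape[0] or c + m.shape[1] > frame_shape[1]:
            raise ValueError(f"patch at offset {(r, c)} does not fit in frame {frame_shape}")
        out[r:r + m.shape[0], c:c + m.shape[1]] |= (m > 0).astype(np.uint8)
    return MaskImage(pixels=out, frame_index=frame_index)
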