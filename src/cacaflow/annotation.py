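"""Annotation fusion and ROI ground truth.

Multiple cardiologists annotate CACs independently; the reference
segmentation is their pixel-wise majority vote, which damps individual
annotation bias.  The decoder is not trained on the (tiny) CAC pixels
directly but on a region of interest obtained by iteratively dilating the
fused CAC mask with an elliptical structuring element — by default four
iterations of a 5-pixel disk (a circle being the isotropic ellipse; the
eccentricity is configurable since only the 5-pixel step is prescribed).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import binary_dilation

from .io import MaskImage

__all__ = ["RoiGtConfig", "majority_vote", "make_roi_gt"]


@dataclasses.dataclass
class RoiGtConfig:
    """ROI-ground-truth dilation settings.

    iterations: number of successive dilations (4 balances coverage against
    ROI size; 0 disables dilation).  step_px: semi-axes of the elliptical
    structuring element per iteration, in pixels.  aspect: ratio of the
    column semi-axis to step_px (1.0 = disk).
    """

    iterations: int = 4
    step_px: int = 5
    aspect: float = 1.0

    def __post_init__(self):
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.step_px < 1:
            raise ValueError("step_px must be >= 1")
        if self.aspect <= 0:
            raise ValueError("aspect must be positive")

    def element(self) -> np.ndarray:
        """Elliptical structuring element with semi-axes (step_px, aspect*step_px).

        Exact ellipse-equation footprint: pixel (dr, dc) belongs iff
        (dr/a)^2 + (dc/b)^2 <= 1, so no pixel lies farther than the
        semi-axis length from the center (for a disk, exactly skimage's
        disk(step_px)).
        """
        a = self.step_px
        b = max(1, int(round(self.aspect * self.step_px)))
        rr, cc = np.mgrid[-a:a + 1, -b:b + 1]
        return (rr / a) ** 2 + (cc / b) ** 2 <= 1.0


def majority_vote(masks: list[MaskImage]) -> MaskImage:
    """Pixel-wise strict majority of >= 2 aligned masks.

    A pixel is foreground iff more than half of the annotators marked it;
    with an even number of voters a tie resolves to background
    (conservative ground truth).  Permutation-invariant by construction.
    """
    if len(masks) < 2:
        raise ValueError("majority vote needs at least two masks")
    shape = masks[0].pixels.shape
    frame_index = masks[0].frame_index
    for m in masks[1:]:
        if m.pixels.shape != shape:
            raise ValueError(f"mask shape mismatch: {m.pixels.shape} vs {shape}")
        if m.frame_index != frame_index:
            raise ValueError("masks must refer to the same frame")
    votes = np.sum([m.pixels for m in masks], axis=0)
    fused = (votes * 2 > len(masks)).astype(np.uint8)
    return MaskImage(pixels=fused, frame_index=frame_index)


def make_roi_gt(cac: MaskImage, cfg: RoiGtConfig | None = None) -> MaskImage:
    """Dilate a fused CAC mask into the decoder's ROI training target.

    Applies cfg.iterations successive dilations of the whole mask with the
    elliptical element (disconnected CAC components dilate jointly and may
    merge).  The output always contains the input, so IoM(cac, roi) = 1.
    """
    cfg = cfg or RoiGtConfig()
    roi = cac.pixels.astype(bool)
    if cfg.iterations and roi.any():
        footprint = cfg.element()
        for _ in range(cfg.iterations):
            roi = binary_dilation(roi, structure=footprint)
    return MaskImage(pixels=roi.astype(np.uint8), frame_index=cac.frame_index)
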