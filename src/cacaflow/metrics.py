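"""Evaluation metrics and Grad-CAM.

Classification of patches is scored with precision, recall and F1.  ROI
identification is scored with intersection-over-minimum (IoM),
|A ∩ B| / min(|A|, |B|) — which is 1 whenever one mask contains the
other, the right notion for judging whether a proposed region covers a
small target — and the symmetric Hausdorff distance between the two
masks' boundary pixel sets, reported in millimeters via the pixel
spacing.  Per-fold values are aggregated as median and quartiles
(linear-interpolation quantile rule).

Grad-CAM maps localize the image evidence behind the classifier's
decision: gradients of the CAC probability with respect to the last
encoder block's activations are spatially averaged into channel weights,
the weighted activation sum is rectified, upsampled to the patch grid and
min-max normalized.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy.ndimage import binary_erosion, zoom
from scipy.spatial.distance import directed_hausdorff

from .io import MaskImage

__all__ = [
    "EvalReport",
    "classification_metrics",
    "iom",
    "hausdorff_mm",
    "gradcam",
    "aggregate",
]


def classification_metrics(predicted, true) -> tuple[float, float, float]:
    """Precision, recall and F1 of binary label sequences.

    A zero denominator (no predicted positives / no true positives / both)
    yields 0 for the affected metric, with a warning as the flag.
    """
    p = np.asarray(predicted).astype(bool).ravel()
    t = np.asarray(true).astype(bool).ravel()
    if p.size != t.size:
        raise ValueError("label sequences must have equal length")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    if tp + fp == 0:
        warnings.warn("no predicted positives: precision defined as 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        warnings.warn("no true positives: recall defined as 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def iom(a: MaskImage, b: MaskImage) -> float:
    """Intersection over minimum: |a ∩ b| / min(|a|, |b|); 0 if either
    mask is empty (flagged) — an empty gated prediction is a legitimate
    outcome that must still enter aggregation."""
    pa, pb = a.pixels.astype(bool), b.pixels.astype(bool)
    if pa.shape != pb.shape:
        raise ValueError("masks must share one shape")
    area_a, area_b = int(pa.sum()), int(pb.sum())
    if area_a == 0 or area_b == 0:
        warnings.warn("empty mask in IoM: defined as 0")
        return 0.0
    return float(np.sum(pa & pb)) / min(area_a, area_b)


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """Coordinates of foreground pixels with a background 4-neighbor."""
    m = mask.astype(bool)
    interior = binary_erosion(m, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
                              border_value=0)
    return np.argwhere(m & ~interior).astype(np.float64)


def hausdorff_mm(a: MaskImage, b: MaskImage, spacing: float) -> float:
    """Symmetric Hausdorff distance between mask boundaries, in mm."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError("masks must share one shape")
    if spacing <= 0:
        raise ValueError("spacing must be positive (mm/pixel)")
    pa, pb = _boundary_points(a.pixels), _boundary_points(b.pixels)
    if pa.size == 0 or pb.size == 0:
        raise ValueError("HD undefined for empty set")
    d_ab = directed_hausdorff(pa, pb)[0]
    d_ba = directed_hausdorff(pb, pa)[0]
    return max(d_ab, d_ba) * spacing


def gradcam(model, nc_patch: np.ndarray, ce_patch: np.ndarray) -> np.ndarray:
    """Grad-CAM heat map (patch-sized, values in [0, 1]) for the
    classifier's CAC probability, taken at the last encoder block."""
    from .net import forward  # local import: metrics must not require the net stack

    model.eval()
    out = forward(model, nc_patch, ce_patch)
    out.probability_tensor.backward()
    acts = out.gradcam_source.data[0]                  # (C, h, w)
    grads = out.gradcam_source.grad
    if grads is None or not np.any(grads):
        warnings.warn("all-zero Grad-CAM gradients: returning a zero map")
        return np.zeros(nc_patch.shape, dtype=np.float64)
    weights = grads[0].mean(axis=(1, 2))               # GAP of the gradients
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    scale = (nc_patch.shape[0] / cam.shape[0], nc_patch.shape[1] / cam.shape[1])
    cam = zoom(cam.astype(np.float64), scale, order=1)
    lo, hi = cam.min(), cam.max()
    if hi - lo <= 0:
        warnings.warn("flat Grad-CAM map: returning zeros")
        return np.zeros_like(cam)
    return (cam - lo) / (hi - lo)


def aggregate(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with the linear-interpolation quantile rule."""
    v = np.asarray(list(values), dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot aggregate an empty collection")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


@dataclasses.dataclass
class EvalReport:
    """Per-fold classification and identification summaries."""

    precision: list[float]
    recall: list[float]
    f1: list[float]
    iom_values: list[float]
    hd_mm_values: list[float]
    hd_missing: int = 0            # frames where HD was undefined (empty mask)

    def summary(self) -> dict:
        out: dict = {"hd_missing": self.hd_missing}
        for name, vals in [
            ("precision", self.precision),
            ("recall", self.recall),
            ("f1", self.f1),
            ("iom", self.iom_values),
            ("hd_mm", self.hd_mm_values),
        ]:
            if vals:
                med, q1, q3 = aggregate(vals)
                out[name] = {"median": med, "q1": q1, "q3": q3}
            else:
                out[name] = None
        return out
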