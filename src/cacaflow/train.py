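"""Two-stage training and leave-one-acquisition-out cross-validation.

Stage 1 trains the double-head encoder and its classifier head with
binary cross-entropy on patch-level CAC presence labels (Adam, learning
rate 1e-4, batch size 32, 100 epochs in the reference configuration).
Stage 2 freezes every encoder/classifier weight — their values are
bit-identical before and after — and trains only the decoder with the
boundary loss (Adam, learning rate 1e-3): the mean over pixels of the
predicted score times the signed Euclidean distance to the ROI-ground-
truth boundary (negative inside the target, positive outside, zero on
its inner boundary ring), so probability mass is rewarded inside the
target and penalized outside, linearly in the score.

Cross-validation is leave-one-acquisition-out: each video sequence is
the test set of exactly one fold, with the identical split reused for
both stages.  Splitting is at acquisition level because frames within an
acquisition are near-duplicates.
"""

from __future__ import annotations

import csv
import dataclasses
import pathlib
import warnings

import numpy as np
from scipy.ndimage import distance_transform_edt

from ._nn import Adam, Tensor, bce_with_logits, mean, mul_const, sigmoid
from .io import MaskImage
from .metrics import classification_metrics, iom
from .net import DoubleHeadResUNet

__all__ = [
    "TrainConfig",
    "FoldPlan",
    "build_folds",
    "signed_distance_map",
    "boundary_loss",
    "PatchDataset",
    "train_classifier",
    "train_decoder",
]


@dataclasses.dataclass
class TrainConfig:
    """Optimization hyperparameters (reference values; desk-scale runs
    shrink epochs and batch size)."""

    classifier_lr: float = 1e-4
    decoder_lr: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    seed: int = 0
    val_fraction: float = 0.2       # share of training acquisitions held out

    def __post_init__(self):
        if self.classifier_lr <= 0 or self.decoder_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclasses.dataclass
class FoldPlan:
    folds: list[tuple[list[str], str]]   # (train ids, test id)


def build_folds(acquisition_ids: list[str]) -> FoldPlan:
    """Leave-one-acquisition-out folds: one fold per acquisition, each
    acquisition the test set exactly once."""
    ids = list(acquisition_ids)
    if len(ids) < 2:
        raise ValueError("need at least two acquisitions for cross-validation")
    if len(set(ids)) != len(ids):
        raise ValueError("acquisition ids must be unique")
    return FoldPlan(folds=[([t for t in ids if t != test], test) for test in ids])


# ---------------------------------------------------------------------------
# Boundary loss
# ---------------------------------------------------------------------------

def signed_distance_map(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance to the target boundary, in pixels.

    Positive outside the target, negative inside, zero on the inner
    boundary ring.  For an empty target the map is a uniform positive
    constant (the image diagonal), so the loss stays defined and is
    minimized by the empty prediction.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return np.full(m.shape, float(np.hypot(*m.shape)), dtype=np.float64)
    dist_out = distance_transform_edt(~m)            # 0 inside, >0 outside
    dist_in = distance_transform_edt(m)              # >0 inside, 0 outside
    return dist_out - (dist_in - 1.0) * m            # inner boundary ring -> 0


def boundary_loss(roi_map: np.ndarray, roi_gt: MaskImage | np.ndarray) -> float:
    """Mean over pixels of predicted score x signed distance."""
    gt = roi_gt.pixels if isinstance(roi_gt, MaskImage) else roi_gt
    scores = np.asarray(roi_map, dtype=np.float64)
    if scores.shape != gt.shape:
        raise ValueError("score map and ROI ground truth must share one shape")
    if scores.min() < 0 or scores.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    return float((scores * signed_distance_map(gt)).mean())


# ---------------------------------------------------------------------------
# Patch dataset
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PatchDataset:
    """Training patches: synchronized pairs, CAC labels, ROI targets."""

    pairs: np.ndarray                     # (N, 2, size, size) float32
    labels: np.ndarray                    # (N,) uint8
    roi_gt: np.ndarray | None = None      # (N, size, size) uint8

    def __len__(self) -> int:
        return self.pairs.shape[0]

    @property
    def positive_fraction(self) -> float:
        return float(self.labels.mean()) if len(self) else 0.0


def _write_log(path, history):
    if path is None or not history:
        return
    path = pathlib.Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(history[0].keys()))
        writer.writeheader()
        writer.writerows(history)


def _batches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


# ---------------------------------------------------------------------------
# Stage 1: classifier
# ---------------------------------------------------------------------------

def train_classifier(
    ds: PatchDataset,
    model: DoubleHeadResUNet,
    cfg: TrainConfig,
    val_ds: PatchDataset | None = None,
    log_path=None,
    stop_at_f1: float | None = None,
) -> list[dict]:
    """Stage 1: binary cross-entropy on patch labels; per-epoch F1 log.

    stop_at_f1 optionally ends training once the monitored F1 reaches the
    given value (useful for overfit studies); otherwise all cfg.epochs run.
    """
    if len(ds) == 0:
        raise ValueError("empty training set")
    if ds.labels.max() == 0:
        warnings.warn("fold has no positive patches; classifier trained anyway")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.encoder_parameters(), lr=cfg.classifier_lr)
    monitor = val_ds if val_ds is not None else ds
    history = []
    for epoch in range(cfg.epochs):
        model.train()
        epoch_loss = 0.0
        for idx in _batches(len(ds), cfg.batch_size, rng):
            nc = Tensor(ds.pairs[idx, 0:1])
            ce = Tensor(ds.pairs[idx, 1:2])
            logit, _, _, _ = model.forward_batch(nc, ce, decode=False)
            loss = bce_with_logits(logit, ds.labels[idx].reshape(-1, 1))
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        preds = predict_labels(model, monitor)
        _, _, f1 = classification_metrics(preds, monitor.labels)
        history.append({"epoch": epoch, "loss": epoch_loss / len(ds), "f1": f1})
        if stop_at_f1 is not None and f1 >= stop_at_f1:
            break
    _write_log(log_path, history)
    return history


def predict_labels(model: DoubleHeadResUNet, ds: PatchDataset, batch_size: int = 16) -> np.ndarray:
    """Thresholded classifier predictions for a dataset (eval mode)."""
    model.eval()
    out = np.empty(len(ds), dtype=np.uint8)
    for start in range(0, len(ds), batch_size):
        sl = slice(start, min(start + batch_size, len(ds)))
        logit, _, _, _ = model.forward_batch(
            Tensor(ds.pairs[sl, 0:1]), Tensor(ds.pairs[sl, 1:2]), decode=False
        )
        out[sl] = (logit.data.ravel() >= 0).astype(np.uint8)  # sigmoid(0) = threshold 0.5
    return out


# ---------------------------------------------------------------------------
# Stage 2: decoder
# ---------------------------------------------------------------------------

def train_decoder(
    ds: PatchDataset,
    model: DoubleHeadResUNet,
    cfg: TrainConfig,
    log_path=None,
    stop_at_iom: float | None = None,
) -> list[dict]:
    """Stage 2: boundary loss on the ROI map, encoder/classifier frozen.

    The freeze is enforced two ways: only decoder parameters enter the
    optimizer, and the encoder (including batch-norm running statistics)
    runs in eval mode; an assertion checks every encoder array is
    bit-identical afterwards.
    """
    if len(ds) == 0:
        raise ValueError("empty training set")
    if ds.roi_gt is None:
        raise ValueError("decoder training needs ROI ground-truth patches")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.decoder_parameters(), lr=cfg.decoder_lr)

    # distance maps are static in the scores, so precompute them
    dists = np.stack([signed_distance_map(g) for g in ds.roi_gt]).astype(np.float32)

    encoder_before = [a.copy() for m in model.encoder_modules() for a in m.state_arrays()]
    history = []
    for epoch in range(cfg.epochs):
        model.train()
        for m in model.encoder_modules():
            for sub in m.modules():
                sub.training = False     # frozen encoder: eval-mode statistics
        epoch_loss = 0.0
        for idx in _batches(len(ds), cfg.batch_size, rng):
            nc = Tensor(ds.pairs[idx, 0:1])
            ce = Tensor(ds.pairs[idx, 1:2])
            _, map_logit, _, _ = model.forward_batch(nc, ce)
            scores = sigmoid(map_logit)
            loss = mean(mul_const(scores, dists[idx][:, None]))
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(idx)
        train_iom = dataset_iom(model, ds)
        history.append({"epoch": epoch, "loss": epoch_loss / len(ds), "iom": train_iom})
        if stop_at_iom is not None and train_iom >= stop_at_iom:
            break

    encoder_after = [a for m in model.encoder_modules() for a in m.state_arrays()]
    for before, after in zip(encoder_before, encoder_after):
        if not np.array_equal(before, after):
            raise AssertionError("encoder weights changed during decoder training")
    _write_log(log_path, history)
    return history


def dataset_iom(model: DoubleHeadResUNet, ds: PatchDataset, batch_size: int = 8) -> float:
    """Mean IoM of thresholded (ungated) ROI maps against ROI ground truth,
    over patches with a nonempty target."""
    model.eval()
    values = []
    for start in range(0, len(ds), batch_size):
        sl = slice(start, min(start + batch_size, len(ds)))
        _, map_logit, _, _ = model.forward_batch(
            Tensor(ds.pairs[sl, 0:1]), Tensor(ds.pairs[sl, 1:2])
        )
        pred = (map_logit.data[:, 0] >= 0).astype(np.uint8)
        for p, g in zip(pred, ds.roi_gt[sl]):
            if g.any():
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    values.append(iom(MaskImage(p), MaskImage(g)))
    return float(np.mean(values)) if values else 0.0
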