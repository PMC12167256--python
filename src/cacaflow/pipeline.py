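"""End-to-end orchestration: dataset assembly, prediction, evaluation.

Glues the stages together in the order the method runs: synchronize the
acquisition, fuse annotations and build ROI ground truth, partition the
synchronized pairs into patch datasets, run the gated network over every
patch, reassemble and refine frame-level ROI masks, and score them.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .annotation import RoiGtConfig, majority_vote, make_roi_gt
from .framesync import SyncResult, synchronize
from .io import FrameSequence, MaskImage
from .metrics import EvalReport, classification_metrics, hausdorff_mm, iom
from .net import DoubleHeadResUNet, forward, gate
from .patching import partition, reassemble
from .postprocess import PostprocessConfig, refine
from .train import PatchDataset

__all__ = [
    "AnnotatedAcquisition",
    "build_patch_dataset",
    "predict_frame",
    "evaluate_acquisition",
    "end_to_end_report",
]


@dataclasses.dataclass
class AnnotatedAcquisition:
    """An acquisition plus fused CAC masks for its annotated frames."""

    sequence: FrameSequence
    cac_masks: dict[int, MaskImage]          # frame index -> fused CAC mask
    sync: SyncResult | None = None

    @classmethod
    def from_annotations(cls, sequence, annotations: dict[int, list[MaskImage]]):
        """Fuse per-annotator masks by majority vote, one frame at a time."""
        fused = {k: majority_vote(v) for k, v in annotations.items()}
        return cls(sequence=sequence, cac_masks=fused)

    def synchronized(self) -> "AnnotatedAcquisition":
        if self.sync is None:
            self.sync = synchronize(self.sequence, annotated=sorted(self.cac_masks))
        return self


def build_patch_dataset(
    acq: AnnotatedAcquisition,
    roi_cfg: RoiGtConfig | None = None,
    patch_size: int = 256,
) -> PatchDataset:
    """Patch every synchronized annotated frame pair of an acquisition."""
    acq = acq.synchronized()
    roi_cfg = roi_cfg or RoiGtConfig()
    pairs, labels, rois = [], [], []
    for k, partner in acq.sync.pairs:
        cac = acq.cac_masks[k]
        roi_gt = make_roi_gt(cac, roi_cfg)
        ps = partition(
            (acq.sequence.frames[k], acq.sequence.frames[partner]),
            cac_mask=cac, roi_gt=roi_gt, size=patch_size,
        )
        for (nc, ce), label, roi in zip(ps.image_patches, ps.labels, ps.roi_gt_patches):
            pairs.append(np.stack([nc, ce]))
            labels.append(label)
            rois.append(roi)
    return PatchDataset(
        pairs=np.asarray(pairs, dtype=np.float32),
        labels=np.asarray(labels, dtype=np.uint8),
        roi_gt=np.asarray(rois, dtype=np.uint8),
    )


def predict_frame(
    model: DoubleHeadResUNet,
    nc_frame: np.ndarray,
    ce_frame: np.ndarray,
    post_cfg: PostprocessConfig | None = None,
    frame_index: int = 0,
) -> tuple[MaskImage, list[int]]:
    """Gated, reassembled, refined ROI for one synchronized frame pair.

    Returns the frame-level ROI mask and the five per-patch classifier
    decisions.
    """
    ps = partition((nc_frame, ce_frame), size=model.cfg.patch_size)
    patch_masks, decisions = [], []
    for nc, ce in ps.image_patches:
        out = forward(model, nc, ce)
        patch_masks.append(gate(out, model.cfg))
        decisions.append(int(out.cac_probability >= model.cfg.classifier_threshold))
    mask = reassemble(patch_masks, ps.offsets, nc_frame.shape, frame_index=frame_index)
    mask = refine(mask, post_cfg or PostprocessConfig())
    return mask, decisions


def evaluate_acquisition(
    model: DoubleHeadResUNet,
    acq: AnnotatedAcquisition,
    post_cfg: PostprocessConfig | None = None,
) -> EvalReport:
    """Score the model on every annotated frame of one acquisition.

    Classification metrics compare per-patch decisions against CAC
    presence labels; identification metrics (IoM, Hausdorff in mm)
    compare the refined frame-level ROI against the fused CAC mask.
    """
    import warnings

    acq = acq.synchronized()
    all_pred, all_true = [], []
    ioms, hds, hd_missing = [], [], 0
    for k, partner in acq.sync.pairs:
        cac = acq.cac_masks[k]
        ps = partition(
            (acq.sequence.frames[k], acq.sequence.frames[partner]),
            cac_mask=cac, size=model.cfg.patch_size,
        )
        roi, decisions = predict_frame(
            model, acq.sequence.frames[k], acq.sequence.frames[partner],
            post_cfg=post_cfg, frame_index=k,
        )
        all_pred.extend(decisions)
        all_true.extend(ps.labels)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ioms.append(iom(roi, cac))
        if roi.area and cac.area:
            hds.append(hausdorff_mm(roi, cac, acq.sequence.pixel_spacing))
        else:
            hd_missing += 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1 = classification_metrics(all_pred, all_true)
    return EvalReport(
        precision=[precision], recall=[recall], f1=[f1],
        iom_values=ioms, hd_mm_values=hds, hd_missing=hd_missing,
    )


def end_to_end_report(
    seed: int,
    n_annotated: int = 2,
    phantom_kwargs: dict | None = None,
    net_kwargs: dict | None = None,
    stage1_epochs: int = 100,
    stage2_epochs: int = 100,
    post_cfg: PostprocessConfig | None = None,
) -> dict:
    """Run the whole workflow on a phantom and return a JSON-ready report.

    simulate -> synchronize -> annotation fusion + ROI ground truth ->
    two-stage training (overfit-scale) -> gated prediction -> evaluation.
    Deterministic in the seed: identical seeds yield identical reports.
    The default problem size (256-px frames, 128-px patches, narrow
    widths) keeps a full run within a few CPU-minutes.
    """
    from .phantom import PhantomSpec, generate_acquisition, simulate_annotators
    from .train import TrainConfig, train_classifier, train_decoder

    pk = {"n_frames": 60, "period": 10, "frame_size": 256, "n_cacs": 2,
          "cac_radius_px": 5.0, "motion_amplitude_px": 4.0, "noise_sd": 0.01}
    pk.update(phantom_kwargs or {})
    spec = PhantomSpec(seed=seed, **pk)
    phantom = generate_acquisition(spec)

    # three simulated annotators per annotated frame, fused by majority vote
    annotations = {
        t: simulate_annotators(phantom.cac_masks[t], n=3, jitter_px=2, seed=seed + 13 * t)
        for t in range(n_annotated)
    }
    acq = AnnotatedAcquisition.from_annotations(phantom.sequence, annotations)
    acq = acq.synchronized()

    nk = {"head_channels": 8, "tail_block_channels": (8, 16, 32, 64),
          "patch_size": 128, "blocks_per_stage": 1, "decoder_final_channels": 8,
          "seed": seed}
    nk.update(net_kwargs or {})
    from .net import NetConfig

    model = DoubleHeadResUNet(NetConfig(**nk))
    ds = build_patch_dataset(acq, RoiGtConfig(), patch_size=model.cfg.patch_size)

    tcfg1 = TrainConfig(batch_size=8, epochs=stage1_epochs, seed=seed)
    h1 = train_classifier(ds, model, tcfg1, stop_at_f1=1.0)
    tcfg2 = TrainConfig(batch_size=8, epochs=stage2_epochs, seed=seed)
    h2 = train_decoder(ds, model, tcfg2, stop_at_iom=0.9)

    report = evaluate_acquisition(model, acq, post_cfg or PostprocessConfig())
    return {
        "seed": seed,
        "estimated_period_frames": acq.sync.period,
        "true_period_frames": spec.period,
        "n_patches": len(ds),
        "positive_fraction": ds.positive_fraction,
        "stage1_epochs_run": len(h1),
        "classifier_train_f1": h1[-1]["f1"],
        "stage2_epochs_run": len(h2),
        "decoder_train_iom": h2[-1]["iom"],
        "evaluation": report.summary(),
    }
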