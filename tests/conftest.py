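"""Shared fixtures: small phantom acquisitions and a once-trained overfit model.

Everything is generated programmatically at collection time; problem sizes
are kept small (60-200 frames, 128-256 px) so the whole suite runs on one
CPU in a few minutes.
"""

import numpy as np
import pytest

import cacaflow as cf
from cacaflow.pipeline import AnnotatedAcquisition, build_patch_dataset
from cacaflow.train import PatchDataset, TrainConfig, train_classifier, train_decoder


@pytest.fixture(scope="session")
def phantom_small():
    """A 60-frame, 256-px phantom with two CACs (period 10 at 15 fps)."""
    spec = cf.PhantomSpec(
        n_frames=60, period=10, frame_size=256, n_cacs=2,
        cac_radius_px=5.0, motion_amplitude_px=4.0, seed=3,
    )
    return spec, cf.generate_acquisition(spec)


@pytest.fixture(scope="session")
def tiny_net_cfg():
    return cf.NetConfig(
        head_channels=8, tail_block_channels=(8, 16, 32, 64),
        patch_size=128, blocks_per_stage=1, decoder_final_channels=8, seed=0,
    )


@pytest.fixture(scope="session")
def overfit_patches(phantom_small):
    """Eight phantom patch pairs (4 CAC-positive, 4 negative) with ROI targets."""
    _, acq = phantom_small
    ann = AnnotatedAcquisition(
        sequence=acq.sequence,
        cac_masks={t: acq.cac_masks[t] for t in range(4)},
    )
    ds = build_patch_dataset(ann, cf.RoiGtConfig(), patch_size=128)
    pos = np.flatnonzero(ds.labels == 1)[:4]
    neg = np.flatnonzero(ds.labels == 0)[:4]
    idx = np.concatenate([pos, neg])
    return PatchDataset(pairs=ds.pairs[idx], labels=ds.labels[idx], roi_gt=ds.roi_gt[idx])


@pytest.fixture(scope="session")
def overfit_run(overfit_patches, tiny_net_cfg):
    """Both training stages run once on the 8-pair fixture; reused by the
    training, Grad-CAM and acceptance tests."""
    model = cf.DoubleHeadResUNet(tiny_net_cfg)
    cfg = TrainConfig(batch_size=8, epochs=200, seed=0)
    h1 = train_classifier(overfit_patches, model, cfg, stop_at_f1=1.0)
    h2 = train_decoder(overfit_patches, model, cfg, stop_at_iom=0.9)
    return {"model": model, "ds": overfit_patches, "stage1": h1, "stage2": h2}


@pytest.fixture(scope="session")
def roi_like_mask():
    """Factory for random ROI-proposal-like masks: a few compact blobs
    (above the island threshold), some sub-threshold islets, and speckle —
    the mask population the refinement stage actually sees."""

    def make(rng, size=96):
        m = np.zeros((size, size), np.uint8)
        yy, xx = np.mgrid[0:size, 0:size]
        for _ in range(int(rng.integers(1, 4))):
            r = int(rng.integers(8, 20))
            cy, cx = rng.integers(r, size - r, 2)
            m[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = 1
        for _ in range(int(rng.integers(0, 4))):
            r = int(rng.integers(1, 4))
            cy, cx = rng.integers(r, size - r, 2)
            m[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = 1
        m |= (rng.random((size, size)) < 0.01).astype(np.uint8)
        return m

    return make
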