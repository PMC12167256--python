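"""Architecture contracts: shapes, gating, head independence, serialization."""

import numpy as np
import pytest

import cacaflow as cf
from cacaflow.net import DoubleHeadResUNet, forward, gate


@pytest.fixture(scope="module")
def tiny_model(tiny_net_cfg):
    return DoubleHeadResUNet(tiny_net_cfg)


@pytest.fixture(scope="module")
def patch_pair(tiny_net_cfg):
    rng = np.random.default_rng(0)
    s = tiny_net_cfg.patch_size
    return rng.random((s, s)).astype(np.float32), rng.random((s, s)).astype(np.float32)


def test_output_shapes_and_bounds(tiny_model, patch_pair):
    out = forward(tiny_model, *patch_pair)
    assert 0.0 <= out.cac_probability <= 1.0
    assert out.roi_map.shape == patch_pair[0].shape
    assert out.roi_map.min() >= 0.0 and out.roi_map.max() <= 1.0


def test_forward_at_full_patch_resolution():
    cfg = cf.NetConfig(head_channels=4, tail_block_channels=(4, 8, 16, 32),
                       patch_size=256, blocks_per_stage=1, decoder_final_channels=4)
    model = DoubleHeadResUNet(cfg)
    rng = np.random.default_rng(1)
    out = forward(model, rng.random((256, 256)).astype(np.float32),
                  rng.random((256, 256)).astype(np.float32))
    assert out.roi_map.shape == (256, 256)
    assert np.isscalar(out.cac_probability)


def test_zeroed_final_layers_give_half_probability_and_half_map(tiny_net_cfg, patch_pair):
    model = DoubleHeadResUNet(tiny_net_cfg)
    model.classifier_fc.weight.data[...] = 0.0
    model.classifier_fc.bias.data[...] = 0.0
    model.final_conv.weight.data[...] = 0.0
    model.final_conv.bias.data[...] = 0.0
    out = forward(model, *patch_pair)
    assert out.cac_probability == pytest.approx(0.5, abs=1e-6)
    assert np.allclose(out.roi_map, 0.5, atol=1e-6)


def test_forward_deterministic_in_eval_mode(tiny_model, patch_pair):
    a = forward(tiny_model, *patch_pair)
    b = forward(tiny_model, *patch_pair)
    assert a.cac_probability == b.cac_probability
    assert np.array_equal(a.roi_map, b.roi_map)


def test_heads_do_not_share_weights(tiny_model, patch_pair):
    """Perturbing only the contrast input changes head-2 features while
    head-1 features stay bit-identical (independent weights, no leakage)."""
    nc, ce = patch_pair
    base = forward(tiny_model, nc, ce)
    pert = forward(tiny_model, nc, np.clip(ce + 0.05, 0, 1))
    assert np.array_equal(base.skip_features["head_nc_block2"],
                          pert.skip_features["head_nc_block2"])
    assert not np.array_equal(base.skip_features["head_ce_block2"],
                              pert.skip_features["head_ce_block2"])


def test_skip_features_exposed_per_stage(tiny_model, patch_pair, tiny_net_cfg):
    out = forward(tiny_model, *patch_pair)
    s = tiny_net_cfg.patch_size
    t = tiny_net_cfg.tail_block_channels
    assert out.skip_features["block3"].shape == (t[0], s // 4, s // 4)
    assert out.skip_features["block5"].shape == (t[2], s // 16, s // 16)
    assert out.gradcam_source.data.shape[1] == t[3]


def test_encoder_parameter_count_near_standard_18_layer():
    """Sanity bound against gross misconstruction: the default encoder is
    within a factor two of an 18-layer residual classifier (~11.2M)."""
    model = DoubleHeadResUNet(cf.NetConfig())
    n = model.encoder_parameter_count()
    reference = 11_176_512
    assert reference / 2 <= n <= reference * 2


class TestGate:
    def _outputs(self, prob, roi):
        from cacaflow.net import NetOutputs
        from cacaflow._nn import Tensor
        return NetOutputs(cac_probability=prob, roi_map=roi, skip_features={},
                          gradcam_source=Tensor(np.zeros(1)),
                          probability_tensor=Tensor(np.zeros(1)),
                          roi_map_tensor=Tensor(np.zeros(1)))

    def test_below_threshold_vetoes_everything(self):
        cfg = cf.NetConfig(classifier_threshold=0.5, patch_size=64,
                           tail_block_channels=(4, 8, 16, 32), head_channels=4)
        out = self._outputs(0.2, np.full((64, 64), 0.9))
        assert gate(out, cfg).sum() == 0

    def test_above_threshold_thresholds_the_map(self):
        cfg = cf.NetConfig(classifier_threshold=0.5, patch_size=64,
                           tail_block_channels=(4, 8, 16, 32), head_channels=4)
        out = self._outputs(0.9, np.full((64, 64), 0.8))
        assert gate(out, cfg).all()

    def test_probability_exactly_at_threshold_counts_as_positive(self):
        cfg = cf.NetConfig(classifier_threshold=0.5, patch_size=64,
                           tail_block_channels=(4, 8, 16, 32), head_channels=4)
        out = self._outputs(0.5, np.full((64, 64), 0.8))
        assert gate(out, cfg).all()

    def test_raising_threshold_never_adds_pixels(self):
        rng = np.random.default_rng(0)
        roi = rng.random((64, 64))
        prev = None
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            cfg = cf.NetConfig(classifier_threshold=thr, patch_size=64,
                               tail_block_channels=(4, 8, 16, 32), head_channels=4)
            cur = gate(self._outputs(0.6, roi), cfg)
            if prev is not None:
                assert np.all(cur <= prev)
            prev = cur


def test_wrong_patch_size_and_nonfinite_inputs_rejected(tiny_model):
    s = tiny_model.cfg.patch_size
    with pytest.raises(ValueError, match="patch"):
        forward(tiny_model, np.zeros((s - 1, s), np.float32), np.zeros((s - 1, s), np.float32))
    bad = np.zeros((s, s), np.float32)
    bad[0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        forward(tiny_model, bad, np.zeros((s, s), np.float32))


def test_patch_size_must_be_divisible_by_32():
    with pytest.raises(ValueError, match="32"):
        cf.NetConfig(patch_size=200)


def test_checkpoint_round_trip(tmp_path, tiny_model, patch_pair):
    before = forward(tiny_model, *patch_pair)
    path = cf.save_checkpoint(tiny_model, tmp_path / "model.npz")
    loaded = cf.load_checkpoint(path)
    after = forward(loaded, *patch_pair)
    assert before.cac_probability == after.cac_probability
    assert np.array_equal(before.roi_map, after.roi_map)
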