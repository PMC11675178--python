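import numpy as np
import pytest

from eggct import nn
from eggct.nets import FCN3D, NetConfig, UNet3D, attach_head, build_fcn3d, build_unet3d


def conv_params(cin, cout, k=3):
    return cout * (cin * k**3 + 1)


def expected_unet_params(b, ns, n_classes=5, in_ch=1):
    """Layer-by-layer parameter count from the architecture definition."""
    total = 0
    cin = in_ch
    for s in range(ns):  # encoder: two convs per stage
        c = b * 2**s
        total += conv_params(cin, c) + conv_params(c, c)
        cin = c
    cbot = b * 2**ns
    total += conv_params(cin, cbot) + conv_params(cbot, cbot)
    for s in reversed(range(ns)):  # decoder: up-conv + two convs
        c = b * 2**s
        total += (2 * c) * (c * 2**3) + c          # transposed conv k=2 + bias
        total += conv_params(2 * c, c) + conv_params(c, c)
    total += conv_params(b, n_classes, k=1)
    return total


def expected_fcn_params(b, n_classes=5, in_ch=1):
    chans = [b, 2 * b, 4 * b, 8 * b, 8 * b]
    convs = [2, 2, 3, 3, 3]
    total = 0
    cin = in_ch
    for c, n in zip(chans, convs):
        total += conv_params(cin, c)
        total += (n - 1) * conv_params(c, c)
        cin = c
    total += conv_params(cin, 8 * b) + conv_params(8 * b, 8 * b)  # blocks 6-7
    total += conv_params(8 * b, n_classes, k=1)   # score on block 7
    total += conv_params(chans[3], n_classes, k=1)  # score on pool4 skip
    total += n_classes * (n_classes * 2**3) + n_classes   # transposed conv x2
    total += n_classes * (n_classes * 16**3) + n_classes  # transposed conv x16
    return total


class TestShapes:
    def test_unet_study_shape(self):
        model = build_unet3d(NetConfig(base_channels=2), seed=0)
        x = np.zeros((1, 1, 40, 140, 90), dtype=np.float32)
        assert model.forward(x, train=False).shape == (1, 5, 40, 140, 90)

    def test_fcn_study_shape(self):
        model = build_fcn3d(NetConfig(base_channels=2), seed=0)
        x = np.zeros((1, 1, 40, 140, 90), dtype=np.float32)
        assert model.forward(x, train=False).shape == (1, 5, 40, 140, 90)

    @pytest.mark.parametrize("shape", [(16, 20, 12), (24, 36, 28), (10, 30, 18)])
    def test_fcn_output_matches_input_shape(self, shape):
        model = build_fcn3d(NetConfig(base_channels=2), seed=1)
        x = np.zeros((1, 1, *shape), dtype=np.float32)
        assert model.forward(x, train=False).shape[2:] == shape

    def test_unet_rejects_too_small_input(self):
        model = build_unet3d(NetConfig(base_channels=2, n_stages=4), seed=0)
        with pytest.raises(ValueError, match="smaller than"):
            model.forward(np.zeros((1, 1, 8, 40, 40), dtype=np.float32))


class TestParameterCounts:
    def test_unet_count_matches_closed_form(self):
        b, ns = 8, 2
        model = build_unet3d(NetConfig(base_channels=b, n_stages=ns), seed=0)
        total = sum(p.value.size for p in model.backbone_params())
        assert total == expected_unet_params(b, ns)

    def test_fcn_count_matches_closed_form(self):
        model = build_fcn3d(NetConfig(base_channels=4), seed=0)
        total = sum(p.value.size for p in model.backbone_params())
        assert total == expected_fcn_params(4)


class TestOutputs:
    def test_class_probabilities_sum_to_one(self):
        model = build_unet3d(NetConfig(base_channels=4, n_stages=2), seed=2)
        x = np.random.default_rng(0).normal(size=(1, 1, 8, 12, 8)).astype(np.float32)
        p = nn.softmax(model.forward(x, train=False), axis=1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_zeroed_final_layer_gives_uniform_probabilities(self):
        model = build_fcn3d(NetConfig(base_channels=2), seed=0)
        model.up16.W.value[...] = 0
        model.up16.b.value[...] = 0
        x = np.random.default_rng(1).normal(size=(1, 1, 10, 12, 10)).astype(np.float32)
        p = nn.softmax(model.forward(x, train=False), axis=1)
        np.testing.assert_allclose(p, 0.2, atol=1e-6)

    def test_constant_input_gives_constant_interior_scores(self):
        # translation consistency: away from borders a constant input must
        # produce spatially constant class scores (exact for the
        # nearest-neighbor decoder; a learned up-convolution is only
        # consistent modulo its stride-2 phase, checked separately below)
        model = build_unet3d(NetConfig(base_channels=4, n_stages=1,
                                       dropout_rate=0.0, upsample="nearest"), seed=3)
        x = np.full((1, 1, 20, 20, 20), 0.5, dtype=np.float32)
        s = model.forward(x, train=False)
        core = s[0, :, 8:12, 8:12, 8:12]
        ref = core[:, :1, :1, :1]
        np.testing.assert_allclose(core, np.broadcast_to(ref, core.shape), atol=1e-4)

    def test_transposed_decoder_constant_modulo_upsampling_phase(self):
        model = build_unet3d(NetConfig(base_channels=4, n_stages=1,
                                       dropout_rate=0.0), seed=3)
        x = np.full((1, 1, 20, 20, 20), 0.5, dtype=np.float32)
        s = model.forward(x, train=False)
        core = s[0, :, 8:12, 8:12, 8:12]
        for a in range(2):
            for b in range(2):
                for c in range(2):
                    phase = core[:, a::2, b::2, c::2]
                    ref = phase[:, :1, :1, :1]
                    np.testing.assert_allclose(
                        phase, np.broadcast_to(ref, phase.shape), atol=1e-4)


def test_fcn_block_dropout_flag_active_only_in_training():
    cfg = NetConfig(base_channels=2, fcn_dropout=True, dropout_rate=0.5)
    model = build_fcn3d(cfg, seed=9)
    x = np.random.default_rng(6).normal(size=(1, 1, 10, 12, 10)).astype(np.float32)
    eval_a = model.forward(x, train=False)
    eval_b = model.forward(x, train=False)
    np.testing.assert_array_equal(eval_a, eval_b)  # eval mode is deterministic
    train_out = model.forward(x, train=True)
    assert not np.array_equal(train_out, eval_a)  # dropout perturbs training


class TestHead:
    def _model(self):
        return build_unet3d(NetConfig(base_channels=4, n_stages=2), seed=4)

    def test_forward_returns_scores_and_three_vector(self):
        model = attach_head(self._model())
        x = np.random.default_rng(2).normal(size=(2, 1, 8, 12, 8)).astype(np.float32)
        scores, meas = model.forward_with_head(x, train=False)
        assert scores.shape == (2, 5, 8, 12, 8)
        assert meas.shape == (2, 3)

    def test_zeroed_head_outputs_zero(self):
        model = attach_head(self._model())
        for p in model.head_params():
            p.value[...] = 0
        x = np.random.default_rng(3).normal(size=(1, 1, 8, 12, 8)).astype(np.float32)
        _, meas = model.forward_with_head(x, train=False)
        np.testing.assert_array_equal(meas, np.zeros((1, 3)))

    def test_attach_twice_is_error(self):
        model = attach_head(self._model())
        with pytest.raises(ValueError, match="already attached"):
            model.attach_head()

    def test_segmentation_unchanged_by_head(self):
        x = np.random.default_rng(4).normal(size=(1, 1, 8, 12, 8)).astype(np.float32)
        model = self._model()
        before = model.forward(x, train=False).copy()
        attach_head(model)
        after, _ = model.forward_with_head(x, train=False)
        np.testing.assert_array_equal(before, after)

    def test_backbone_and_head_params_partition(self):
        model = attach_head(self._model())
        backbone = {id(p) for p in model.backbone_params()}
        head = {id(p) for p in model.head_params()}
        allp = {id(p) for p in model.params()}
        assert backbone & head == set()
        assert backbone | head == allp


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model = attach_head(build_unet3d(NetConfig(base_channels=4, n_stages=2), seed=5))
        x = np.random.default_rng(5).normal(size=(1, 1, 8, 12, 8)).astype(np.float32)
        s1, m1 = model.forward_with_head(x, train=False)
        model.save(tmp_path / "ckpt.npz")
        loaded = UNet3D.load(tmp_path / "ckpt.npz")
        assert loaded.config == model.config
        s2, m2 = loaded.forward_with_head(x, train=False)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(m1, m2)
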