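"""Network blocks and assemblies: shapes, receptive fields, parameter counts."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from fissureseg._nn import count_params
from fissureseg._nn.autodiff import Tensor
from fissureseg.net import (
    BRBlock,
    GCNBlock,
    InceptionBlock,
    ModelConfig,
    ResidualBlock,
    SEBlock,
    build_encoder,
    build_improved_unet,
    full_conv_param_count,
    gcn_param_count,
    predict,
    spec_of,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestModelConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"encoder": "resnet50"},
            {"gcn_kernel_size": 4},
            {"gcn_variant": "grouped"},
            {"num_classes": 1},
            {"base_channels": 12},
            {"upsample": "pixelshuffle"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)


class TestInceptionBlock:
    def test_shape_contract(self):
        block = InceptionBlock(32, (8, 16, 4, 4), _rng())
        block.eval()
        out = block(Tensor(_rng(1).normal(size=(2, 32, 16, 16)).astype(np.float32)))
        assert out.data.shape == (2, 32, 16, 16)

    def test_param_count_matches_spec(self):
        block = InceptionBlock(32, (8, 16, 4, 4), _rng())
        assert spec_of(block).param_count == count_params(block)

    def test_zero_weights_give_zero_output(self):
        block = InceptionBlock(8, (4, 8, 2, 2), _rng())
        for p in block.parameters():
            p.data[:] = 0.0
        block.eval()
        out = block(Tensor(_rng(2).normal(size=(1, 8, 8, 8)).astype(np.float32)))
        np.testing.assert_array_equal(out.data, 0.0)


class TestResidualAndSE:
    def test_residual_zero_f_is_identity(self):
        block = ResidualBlock(8, 8, _rng())
        # zero the residual path; shortcut is the identity
        block.conv2.weight.data[:] = 0.0
        block.conv2.bias.data[:] = 0.0
        block.bn2.gamma.data[:] = 0.0
        block.eval()
        x = np.abs(_rng(3).normal(size=(1, 8, 6, 6))).astype(np.float32)  # relu-safe
        out = block(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-6)

    def test_se_gate_extremes(self):
        se = SEBlock(4, _rng())
        x = _rng(4).normal(size=(2, 4, 5, 5)).astype(np.float32)
        # force gate to ~1: huge positive bias on the second fc
        se.fc2.bias.data[:] = 50.0
        np.testing.assert_allclose(se(Tensor(x)).data, x, rtol=1e-4)
        # force gate to ~0
        se.fc2.bias.data[:] = -50.0
        se.fc2.weight.data[:] = 0.0
        np.testing.assert_allclose(se(Tensor(x)).data, 0.0, atol=1e-6)


def _gcn_dense_equivalent_kernel(block):
    """Compose the branch convolutions into one dense (cout, cin, k, k) kernel."""
    k = block.k
    if block.variant == "dense":
        w_a1 = block.a1.weight.data  # (cout, cin, k, 1)
        w_a2 = block.a2.weight.data  # (cout, cout, 1, k)
        w_b1 = block.b1.weight.data  # (cout, cin, 1, k)
        w_b2 = block.b2.weight.data  # (cout, cout, k, 1)
        ka = np.einsum("omj,mci->ocij", w_a2[:, :, 0, :], w_a1[:, :, :, 0])
        kb = np.einsum("omi,mcj->ocij", w_b2[:, :, :, 0], w_b1[:, :, 0, :])
        return ka + kb
    # separable: depthwise (c, kh, kw) then pointwise (cout, cin, 1, 1) per conv
    def sep(conv, horizontal):
        dw = conv.depthwise.weight.data
        pw = conv.pointwise.weight.data[:, :, 0, 0]
        taps = dw[:, 0, :] if horizontal else dw[:, :, 0]  # (c, k)
        return pw, taps

    pa1, ta1 = sep(block.a1, horizontal=False)  # k x 1 on cin
    pa2, ta2 = sep(block.a2, horizontal=True)  # 1 x k on cout
    pb1, tb1 = sep(block.b1, horizontal=True)
    pb2, tb2 = sep(block.b2, horizontal=False)
    # first conv: E1[m, c, i] = pa1[m, c] * ta1[c, i]; second: E2[o, m, j] = pa2[o, m] * ta2[m, j]
    ka = np.einsum("om,mj,mc,ci->ocij", pa2, ta2, pa1, ta1)
    kb = np.einsum("om,mi,mc,cj->ocij", pb2, tb2, pb1, tb1)
    return ka + kb


class TestGCNBlock:
    @pytest.mark.parametrize("variant", ["dense", "separable"])
    @pytest.mark.parametrize("k", [3, 7, 11])
    def test_impulse_support_and_dense_oracle(self, k, variant):
        """Impulse response stays inside the k x k window and equals the
        composed dense kernel applied by an independent convolution."""
        cin, cout = 3, 2
        block = GCNBlock(cin, cout, k, _rng(k), variant=variant)
        size = 4 * k + 1
        x = np.zeros((1, cin, size, size), dtype=np.float64)
        center = size // 2
        x[0, :, center, center] = _rng(100 + k).normal(size=cin)
        out = block(Tensor(x)).data[0]
        half = (k - 1) // 2
        support = np.argwhere(np.abs(out).sum(axis=0) > 1e-9)
        assert support.size > 0
        assert support[:, 0].min() >= center - half and support[:, 0].max() <= center + half
        assert support[:, 1].min() >= center - half and support[:, 1].max() <= center + half
        dense = _gcn_dense_equivalent_kernel(block)
        for o in range(cout):
            ref = sum(
                correlate2d(x[0, c], dense[o, c], mode="same") for c in range(cin)
            )
            np.testing.assert_allclose(out[o], ref, atol=1e-4)

    @pytest.mark.parametrize("variant", ["dense", "separable"])
    def test_oracle_on_random_input_interior(self, variant):
        """Away from borders the block equals dense convolution with the
        composed kernel on arbitrary inputs, not just impulses."""
        k, cin, cout = 7, 3, 2
        block = GCNBlock(cin, cout, k, _rng(5), variant=variant)
        x = _rng(6).normal(size=(1, cin, 24, 24))
        out = block(Tensor(x)).data[0]
        dense = _gcn_dense_equivalent_kernel(block)
        half = k - 1
        for o in range(cout):
            ref = sum(correlate2d(x[0, c], dense[o, c], mode="same") for c in range(cin))
            np.testing.assert_allclose(
                out[o, half:-half, half:-half], ref[half:-half, half:-half], atol=1e-4
            )

    def test_dense_param_economy(self):
        """2(k c_in c_out + k c_out^2) from formula, blocks, and LayerSpec."""
        block = GCNBlock(64, 2, 7, _rng(), variant="dense")
        assert gcn_param_count(7, 64, 2, "dense") == 1848
        assert count_params(block) == 1848
        assert spec_of(block).param_count == 1848
        assert full_conv_param_count(7, 64, 2) == 6272

    def test_separable_param_count(self):
        block = GCNBlock(64, 2, 7, _rng(), variant="separable")
        assert count_params(block) == gcn_param_count(7, 64, 2, "separable")
        assert spec_of(block).param_count == count_params(block)

    @pytest.mark.parametrize("k", [3, 5, 7, 11, 15])
    def test_linear_growth_beats_full_conv(self, k):
        if k > 4:
            assert gcn_param_count(k, 64, 2, "dense") < full_conv_param_count(k, 64, 2)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            GCNBlock(8, 2, 4, _rng())

    def test_k1_degenerate_equals_sum_of_pointwise_paths(self):
        """With branch-2 weights zeroed, k=1 dense reduces to one 1x1 conv."""
        block = GCNBlock.__new__(GCNBlock)  # bypass the k >= 3 model-config gate
        GCNBlock.__init__(block, 4, 2, 1, _rng(9), variant="dense")
        block.b1.weight.data[:] = 0.0
        x = _rng(10).normal(size=(1, 4, 6, 6))
        out = block(Tensor(x)).data
        w = np.einsum("om,mc->oc", block.a2.weight.data[:, :, 0, 0], block.a1.weight.data[:, :, 0, 0])
        ref = np.einsum("oc,nchw->nohw", w, x)
        np.testing.assert_allclose(out, ref, atol=1e-5)


class TestBRBlock:
    def test_identity_at_initialization(self):
        """Zero-initialized second conv makes the block the exact identity."""
        block = BRBlock(2, _rng())
        x = _rng(11).normal(size=(3, 2, 9, 13)).astype(np.float32)
        out = block(Tensor(x)).data
        assert np.array_equal(out, x)  # bit-exact: x + 0

    def test_shape_preserved_arbitrary_sizes(self):
        block = BRBlock(4, _rng())
        for shape in [(1, 4, 5, 5), (2, 4, 17, 3)]:
            x = _rng(12).normal(size=shape).astype(np.float32)
            assert block(Tensor(x)).data.shape == shape

    def test_residual_support_bounded_by_5x5_dilation(self):
        """Two stacked 3x3 convs: the correction spreads at most 2 px."""
        block = BRBlock(1, _rng(13))
        block.conv2.weight.data[:] = _rng(14).normal(size=block.conv2.weight.data.shape)
        x = np.zeros((1, 1, 15, 15), dtype=np.float64)
        x[0, 0, 7, 7] = 1.0
        residual = block(Tensor(x)).data[0, 0] - x[0, 0]
        support = np.argwhere(np.abs(residual) > 1e-9)
        assert np.abs(support - 7).max() <= 2


class TestEncoders:
    @pytest.mark.parametrize("name,strides", [
        ("googlenet", (4, 8, 16, 32)),
        ("vgg", (4, 8, 16, 32)),
        ("seresnet", (4, 8, 16, 32)),
        ("plain_unet", (2, 4, 8, 16)),
    ])
    def test_stage_strides_and_channels(self, name, strides):
        enc = build_encoder(name, 8, _rng())
        enc.eval()
        assert enc.stage_strides == strides
        x = Tensor(_rng(15).normal(size=(1, 3, 64, 64)).astype(np.float32))
        _, feats = enc(x)
        for f, stride, ch in zip(feats, strides, enc.stage_channels):
            assert f.data.shape == (1, ch, 64 // stride, 64 // stride)

    @pytest.mark.parametrize("name", ["googlenet", "vgg", "seresnet", "plain_unet"])
    def test_stage_spec_counts_match_instantiated(self, name):
        enc = build_encoder(name, 8, _rng())
        for stage in enc.stages:
            assert spec_of(stage).param_count == count_params(stage)

    def test_same_seed_identical_weights(self):
        a = build_encoder("googlenet", 8, 7)
        b = build_encoder("googlenet", 8, 7)
        for (ka, pa), (kb, pb) in zip(a.named_parameters(), b.named_parameters()):
            assert ka == kb
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            build_encoder("mobilenet", 8, _rng())


def _classic_unet_param_oracle(base, in_channels, num_classes):
    """Independent enumeration of classic U-Net weights at `base` channels:
    double 3x3 conv(+BN) blocks, 2x2 deconvs, concat skips, 1x1 head."""
    def conv(cin, cout, k):
        return k * k * cin * cout + cout

    def bn(c):
        return 2 * c

    def double(cin, cout):
        return conv(cin, cout, 3) + bn(cout) + conv(cout, cout, 3) + bn(cout)

    b = base
    total = double(in_channels, b)  # stem
    enc_chans = [b, 2 * b, 4 * b, 8 * b, 16 * b]
    for cin, cout in zip(enc_chans[:-1], enc_chans[1:]):
        total += double(cin, cout)  # four pooled stages
    for deep, shallow in zip(enc_chans[:0:-1], enc_chans[-2::-1]):
        total += 2 * 2 * deep * shallow + shallow  # deconv
        total += double(2 * shallow, shallow)
    total += conv(b, num_classes, 1)  # head
    return total


class TestAssemblies:
    def test_improved_unet_shape_contract(self):
        config = ModelConfig(encoder="googlenet", base_channels=8, input_size=(64, 64))
        model = build_improved_unet(config, seed=0).eval()
        x = _rng(16).normal(size=(1, 3, 64, 64)).astype(np.float32)
        assert model(Tensor(x)).data.shape == (1, 2, 64, 64)

    def test_plain_unet_matches_independent_param_count(self):
        config = ModelConfig(
            encoder="plain_unet", use_gcn=False, use_br=False,
            base_channels=8, in_channels=1, input_size=(64, 64),
        )
        model = build_improved_unet(config, seed=0).eval()
        x = _rng(17).normal(size=(1, 1, 64, 64)).astype(np.float32)
        assert model(Tensor(x)).data.shape == (1, 2, 64, 64)
        expected = _classic_unet_param_oracle(8, in_channels=1, num_classes=2)
        assert count_params(model) == expected
        assert spec_of(model).param_count == expected

    @pytest.mark.parametrize("encoder", ["vgg", "seresnet"])
    def test_classic_decoder_on_other_encoders(self, encoder):
        config = ModelConfig(encoder=encoder, use_gcn=False, use_br=False, base_channels=8)
        model = build_improved_unet(config, seed=0).eval()
        x = _rng(18).normal(size=(1, 3, 64, 64)).astype(np.float32)
        assert model(Tensor(x)).data.shape == (1, 2, 64, 64)

    def test_concat_fusion_variant(self):
        config = ModelConfig(base_channels=8, fusion="concat", input_size=(64, 64))
        model = build_improved_unet(config, seed=0).eval()
        x = _rng(19).normal(size=(1, 3, 64, 64)).astype(np.float32)
        assert model(Tensor(x)).data.shape == (1, 2, 64, 64)

    def test_bilinear_upsampling_variant(self):
        config = ModelConfig(base_channels=8, upsample="bilinear", input_size=(64, 64))
        model = build_improved_unet(config, seed=0).eval()
        x = _rng(20).normal(size=(1, 3, 64, 64)).astype(np.float32)
        assert model(Tensor(x)).data.shape == (1, 2, 64, 64)

    def test_indivisible_input_rejected_at_forward(self):
        model = build_improved_unet(ModelConfig(base_channels=8), seed=0).eval()
        with pytest.raises(ValueError):
            model(Tensor(np.zeros((1, 3, 50, 50), dtype=np.float32)))

    def test_forward_deterministic_in_eval(self):
        model = build_improved_unet(ModelConfig(base_channels=8), seed=3).eval()
        x = _rng(21).normal(size=(1, 3, 64, 64)).astype(np.float32)
        a = model(Tensor(x)).data
        b = model(Tensor(x)).data
        assert np.array_equal(a, b)

    def test_rot180_equivariance_with_symmetric_kernels(self):
        """With every kernel symmetrized under 180-degree rotation the
        fully-convolutional assembly commutes with rot180."""
        model = build_improved_unet(
            ModelConfig(base_channels=8, input_size=(64, 64)), seed=4
        ).eval()
        for _, p in model.named_parameters():
            if p.data.ndim == 4:  # conv / deconv kernels: average with rot180
                p.data = 0.5 * (p.data + p.data[:, :, ::-1, ::-1])
        x = _rng(22).normal(size=(1, 3, 64, 64)).astype(np.float32)
        pred = predict(model, x)
        pred_rot = predict(model, np.ascontiguousarray(x[:, :, ::-1, ::-1]))
        np.testing.assert_array_equal(pred_rot[:, ::-1, ::-1], pred)


class TestPredict:
    def test_argmax_oracle_and_tie_rule(self):
        class Frozen:
            training = False

            def eval(self):
                return self

            def train(self, mode=True):
                return self

            def __call__(self, t):
                return t

        rng = _rng(23)
        scores = rng.normal(size=(4, 2, 8, 8))
        preds = predict(Frozen(), scores)
        brute = np.zeros((4, 8, 8), dtype=np.uint8)
        for n in range(4):
            for r in range(8):
                for c in range(8):
                    brute[n, r, c] = 1 if scores[n, 1, r, c] > scores[n, 0, r, c] else 0
        np.testing.assert_array_equal(preds, brute)
        # exact ties go to the background class
        tied = np.zeros((1, 2, 4, 4))
        assert predict(Frozen(), tied).sum() == 0
        # class 1 everywhere larger -> all ones
        up = np.stack([np.zeros((4, 4)), np.ones((4, 4))])[None]
        assert predict(Frozen(), up).all()
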