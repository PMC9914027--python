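"""Architecture blocks: shuffle permutation, parameter accounting, SE, unit."""

import numpy as np
import pytest
from scipy.special import erf

import lightdermo as ld
from lightdermo import nn
from lightdermo._tensor import Tensor
from lightdermo.blocks import shuffle_permutation


def brute_force_perm(c, g):
    """Independent oracle: reshape the index list to (G, N), transpose, flatten."""
    return list(np.arange(c).reshape(g, c // g).T.flatten())


class TestChannelShuffle:
    def test_identity_for_single_group(self, rng):
        x = rng.random((2, 6, 4, 4))
        np.testing.assert_array_equal(ld.channel_shuffle(x, 1), x)

    def test_c4_g2_interleaves(self, rng):
        x = rng.random((1, 4, 2, 2))
        out = ld.channel_shuffle(x, 2)
        np.testing.assert_array_equal(out, x[:, [0, 2, 1, 3]])

    def test_matches_reshape_transpose_oracle_all_divisors(self):
        for c in range(1, 65):
            for g in range(1, c + 1):
                if c % g:
                    continue
                assert list(shuffle_permutation(c, g)) == brute_force_perm(c, g)

    def test_double_shuffle_is_identity(self, rng):
        for g, n in [(2, 3), (4, 4), (3, 5)]:
            x = rng.random((2, g * n, 3, 3))
            back = ld.channel_shuffle(ld.channel_shuffle(x, g), n)
            np.testing.assert_array_equal(back, x)

    def test_is_permutation_conserving_channel_sum(self, rng):
        x = rng.random((2, 12, 3, 3))
        out = ld.channel_shuffle(x, 3)
        np.testing.assert_allclose(out.sum(axis=1), x.sum(axis=1), atol=1e-12)
        assert sorted(map(tuple, out[0, :, 0, :1])) == sorted(map(tuple, x[0, :, 0, :1]))

    def test_indivisible_raises_naming_c_and_g(self, rng):
        with pytest.raises(ValueError, match="C=10.*G=4"):
            ld.channel_shuffle(rng.random((1, 10, 2, 2)), 4)


def enumerate_conv_weights(spec: ld.ConvSpec) -> int:
    """Counting oracle: instantiate the weight arrays and count entries."""
    w = np.zeros((spec.out_channels, spec.in_channels // spec.groups, spec.kernel_h, spec.kernel_w))
    b = np.zeros(spec.out_channels) if spec.has_bias else np.zeros(0)
    return w.size + b.size


class TestConvParamCount:
    @pytest.mark.parametrize(
        "spec,expected",
        [
            (ld.ConvSpec(1, 1, 1, 1), 1),
            (ld.ConvSpec(3, 3, 64, 128), 73_728),
            (ld.ConvSpec(3, 3, 64, 64, groups=64), 576),  # depthwise: k*k*C
        ],
    )
    def test_reference_examples(self, spec, expected):
        assert ld.conv_param_count(spec) == expected

    def test_matches_weight_enumeration_on_random_specs(self, rng):
        for _ in range(200):
            groups = int(rng.integers(1, 5))
            cin = groups * int(rng.integers(1, 17))
            cout = groups * int(rng.integers(1, 17))
            spec = ld.ConvSpec(
                kernel_w=int(rng.integers(1, 8)),
                kernel_h=int(rng.integers(1, 8)),
                in_channels=cin,
                out_channels=cout,
                groups=groups,
                has_bias=bool(rng.integers(0, 2)),
            )
            assert ld.conv_param_count(spec) == enumerate_conv_weights(spec)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ld.ConvSpec(3, 3, 5, 4, groups=2)
        with pytest.raises(ValueError):
            ld.ConvSpec(0, 3, 4, 4)


class TestDepthwiseSeparable:
    @pytest.mark.parametrize(
        "cin,cout,k,expected",
        [(1, 1, 1, 2), (64, 128, 3, 8_768), (8, 8, 3, 8 * 9 + 64)],
    )
    def test_parameter_count_is_kkC_plus_pointwise(self, cin, cout, k, expected):
        block = ld.DepthwiseSeparableConv(cin, cout, k)
        assert block.parameter_count() == expected

    def test_identity_construction_reproduces_input(self, rng):
        block = ld.DepthwiseSeparableConv(1, 1, kernel_size=1, padding=0)
        block.depthwise.weight.data[...] = 1.0
        block.pointwise.weight.data[...] = 1.0
        x = rng.random((1, 1, 5, 5)).astype(np.float32)
        np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-7)

    def test_output_channels(self, rng):
        block = ld.DepthwiseSeparableConv(4, 10, 3)
        assert block(Tensor(rng.random((2, 4, 8, 8)))).shape == (2, 10, 8, 8)


class TestSEBlock:
    def test_zero_weights_gate_half(self, rng):
        se = ld.SEBlock(6, reduction=2)
        for p in se.parameters():
            p.data[...] = 0.0
        x = rng.random((2, 6, 4, 4)).astype(np.float32)
        np.testing.assert_allclose(se(Tensor(x)).data, 0.5 * x, atol=1e-7)

    def test_gate_attenuates_everywhere(self, rng):
        se = ld.SEBlock(8, reduction=4, rng=rng)
        x = rng.normal(size=(2, 8, 5, 5)).astype(np.float32)
        out = se(Tensor(x)).data
        assert np.all(np.abs(out) <= np.abs(x) + 1e-7)

    def test_hand_computed_two_channel_gate(self):
        # C=2, r=1; constant planes (1, 3) -> squeeze = [1, 3]
        se = ld.SEBlock(2, reduction=1)
        w1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        w2 = np.array([[0.5, -0.5], [0.0, 0.25]])
        se.fc1.weight.data = w1.astype(np.float32)
        se.fc1.bias.data[...] = 0.0
        se.fc2.weight.data = w2.astype(np.float32)
        se.fc2.bias.data[...] = 0.0
        x = np.ones((1, 2, 3, 3), dtype=np.float32)
        x[0, 1] = 3.0
        # hand arithmetic: s=[1,3]; gelu(s)=[s*Phi(s)] = [0.84134, 2.99596]
        g1 = 1.0 * 0.5 * (1 + erf(1 / np.sqrt(2)))
        g3 = 3.0 * 0.5 * (1 + erf(3 / np.sqrt(2)))
        z = np.array([g1 * 0.5, g1 * -0.5 + g3 * 0.25])
        gate = 1 / (1 + np.exp(-z))
        out = se(Tensor(x)).data
        np.testing.assert_allclose(out[0, 0], gate[0], rtol=1e-5)
        np.testing.assert_allclose(out[0, 1], 3.0 * gate[1], rtol=1e-5)

    def test_saturated_gate_passes_input_through(self, rng):
        se = ld.SEBlock(4, reduction=2)
        for p in se.parameters():
            p.data[...] = 0.0
        se.fc2.bias.data[...] = 50.0  # huge positive logits -> gate -> 1
        x = rng.random((1, 4, 3, 3)).astype(np.float32)
        np.testing.assert_allclose(se(Tensor(x)).data, x, rtol=1e-6)

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="channels"):
            ld.SEBlock(4)(Tensor(rng.random((1, 6, 2, 2))))


class TestShuffleUnit:
    def test_odd_width_rejected(self):
        with pytest.raises(ValueError, match="even"):
            ld.ShuffleUnit(7)

    def test_preserves_shape(self, rng):
        unit = ld.ShuffleUnit(8, rng=rng)
        x = rng.random((3, 8, 6, 6)).astype(np.float32)
        assert unit(Tensor(x)).shape == (3, 8, 6, 6)

    def test_shuffle_toggle_is_fixed_permutation(self, rng):
        on = ld.ShuffleUnit(8, use_shuffle=True, rng=np.random.default_rng(3))
        off = ld.ShuffleUnit(8, use_shuffle=False, rng=np.random.default_rng(3))
        off.load_state_dict(on.state_dict())
        on.eval(), off.eval()
        x = rng.random((2, 8, 6, 6)).astype(np.float32)
        perm = shuffle_permutation(8, 2)
        np.testing.assert_allclose(on(Tensor(x)).data, off(Tensor(x)).data[:, perm], atol=1e-7)

    def test_identity_half_passes_through_with_zeroed_branch(self, rng):
        unit = ld.ShuffleUnit(8, use_shuffle=False, rng=rng)
        unit.eval()
        unit.pw2.weight.data[...] = 0.0
        unit.bn3.gamma.data[...] = 0.0
        x = rng.random((2, 8, 6, 6)).astype(np.float32)
        out = unit(Tensor(x)).data
        np.testing.assert_allclose(out[:, :4], x[:, :4], atol=1e-7)

    def test_parameter_count_matches_closed_form(self):
        width = 64
        half = width // 2
        unit = ld.ShuffleUnit(width)
        expected = 2 * half**2 + 9 * half + 3 * 2 * half  # convs + three BNs
        assert unit.parameter_count() == expected


def test_batchnorm_normalizes_in_train_mode(rng):
    bn = nn.BatchNorm2d(3)
    x = Tensor(rng.normal(2.0, 3.0, size=(8, 3, 10, 10)).astype(np.float32))
    out = bn(x).data
    assert np.allclose(out.mean(axis=(0, 2, 3)), 0.0, atol=1e-4)
    assert np.allclose(out.std(axis=(0, 2, 3)), 1.0, atol=1e-3)
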