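"""Dynamic upsampling: offset prediction, fusion, group-wise sampling."""

import numpy as np
import pytest

from orchardet.dadu import DADU, DADUConfig, fuse_offsets, make_base_grid
from orchardet.nn import Tensor
from orchardet.nn import functional as F


class TestPixelShuffle:
    def test_shape_rule(self, rng):
        out = F.pixel_shuffle(Tensor(rng.normal(size=(1, 4, 2, 2))), 2)
        assert out.shape == (1, 1, 4, 4)

    def test_roundtrip_exact(self, rng):
        x = Tensor(rng.normal(size=(2, 8, 3, 5)))
        back = F.pixel_unshuffle(F.pixel_shuffle(x, 2), 2)
        np.testing.assert_array_equal(back.data, x.data)

    def test_constant_input_stays_constant(self):
        out = F.pixel_shuffle(Tensor(np.full((1, 4, 3, 3), 2.5)), 2)
        np.testing.assert_allclose(out.data, 2.5)

    def test_indivisible_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            F.pixel_shuffle(Tensor(rng.normal(size=(1, 6, 2, 2))), 2)


class TestOffsetBranches:
    def _block(self, rng):
        return DADU(DADUConfig(channels=8, scale=2, groups=4), rng=rng)

    def test_zero_init_gives_zero_offsets(self, rng):
        block = self._block(rng)
        x = Tensor(rng.normal(size=(1, 8, 5, 5)))
        assert not block.predict_offsets(x, "pointwise").data.any()
        assert not block.predict_offsets(x, "spatial").data.any()

    def test_pointwise_branch_is_local_to_the_impulse_cell(self, rng):
        block = self._block(rng)
        block.branch1.conv.weight.data = rng.normal(size=block.branch1.conv.weight.shape)
        x = np.zeros((1, 8, 5, 5))
        x[0, :, 2, 3] = 1.0
        off = block.predict_offsets(Tensor(x), "pointwise").data
        nz = np.abs(off).sum(axis=(0, 1))
        assert nz[2, 3] > 0
        nz[2, 3] = 0
        assert not nz.any()

    def test_spatial_branch_confined_to_3x3_neighborhood(self, rng):
        block = self._block(rng)
        block.branch2.conv.weight.data = rng.normal(size=block.branch2.conv.weight.shape)
        x = np.zeros((1, 8, 7, 7))
        x[0, :, 3, 3] = 1.0
        off = block.predict_offsets(Tensor(x), "spatial").data
        nz = np.abs(off).sum(axis=(0, 1)) > 0
        outside = nz.copy()
        outside[2:5, 2:5] = False
        assert not outside.any()


class TestFusion:
    def test_equal_branches_fuse_to_themselves(self, rng):
        d = Tensor(rng.normal(size=(1, 8, 3, 3)))
        for p in (-3.0, 0.0, 7.0):
            np.testing.assert_allclose(fuse_offsets(d, d, p).data, d.data, atol=1e-12)

    def test_sigmoid_half_fixture(self):
        d1 = Tensor(np.ones((1, 4, 2, 2)))
        d2 = Tensor(np.zeros((1, 4, 2, 2)))
        out = fuse_offsets(d1, d2, 0.5).data
        np.testing.assert_allclose(out, 1 / (1 + np.exp(-0.5)), atol=1e-12)
        assert out.flat[0] == pytest.approx(0.6225, abs=1e-4)

    def test_saturation_limits_select_one_branch(self, rng):
        d1 = Tensor(rng.normal(size=(1, 2, 2, 2)))
        d2 = Tensor(rng.normal(size=(1, 2, 2, 2)))
        np.testing.assert_allclose(fuse_offsets(d1, d2, 20.0).data, d1.data, atol=1e-8)
        np.testing.assert_allclose(fuse_offsets(d1, d2, -20.0).data, d2.data, atol=1e-8)

    def test_output_bounded_between_branches(self, rng):
        d1 = Tensor(rng.normal(size=(1, 4, 3, 3)))
        d2 = Tensor(rng.normal(size=(1, 4, 3, 3)))
        out = fuse_offsets(d1, d2, rng.normal()).data
        lo = np.minimum(d1.data, d2.data)
        hi = np.maximum(d1.data, d2.data)
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            fuse_offsets(Tensor(np.zeros((1, 4, 2, 2))), Tensor(np.zeros((1, 4, 3, 2))), 0.0)


class TestScope:
    def test_scoped_offsets_never_larger(self, rng):
        block = DADU(DADUConfig(channels=8, scale=2, groups=4, dynamic_scope=True), rng=rng)
        block.scope_conv.weight.data = rng.normal(size=block.scope_conv.weight.shape)
        x = Tensor(rng.normal(size=(1, 8, 4, 4)))
        off = Tensor(rng.normal(size=(1, 2 * 4 * 4, 4, 4)))
        scoped = block.apply_scope(off, x).data
        assert np.all(np.abs(scoped) <= np.abs(off.data) + 1e-12)

    def test_zero_scope_conv_halves_offsets(self, rng):
        block = DADU(DADUConfig(channels=8, scale=2, groups=4, dynamic_scope=True), rng=rng)
        x = Tensor(rng.normal(size=(1, 8, 4, 4)))
        off = Tensor(rng.normal(size=(1, 32, 4, 4)))
        np.testing.assert_allclose(block.apply_scope(off, x).data, 0.5 * off.data, atol=1e-12)

    def test_hand_set_scope_matches_direct_evaluation(self, rng):
        block = DADU(DADUConfig(channels=4, scale=2, groups=2, dynamic_scope=True), rng=rng)
        w = rng.normal(size=block.scope_conv.weight.shape)
        block.scope_conv.weight.data = w
        block.scope_conv.bias.data[...] = 0.3
        x = rng.normal(size=(1, 4, 3, 3))
        off = rng.normal(size=(1, 16, 3, 3))
        scoped = block.apply_scope(Tensor(off), Tensor(x)).data
        pre = np.einsum("oc,bchw->bohw", w[:, :, 0, 0], x) + 0.3
        expected = off / (1 + np.exp(-pre))
        np.testing.assert_allclose(scoped, expected, atol=1e-10)


class TestForward:
    def test_output_shape_doubles_space(self, rng):
        block = DADU(DADUConfig(channels=4, scale=2, groups=2), rng=rng)
        y = block(Tensor(rng.normal(size=(1, 4, 8, 8))))
        assert y.shape == (1, 4, 16, 16)

    def test_zero_offsets_reduce_to_base_grid_resampling(self, rng):
        block = DADU(DADUConfig(channels=4, scale=2, groups=2), rng=rng)
        x = Tensor(rng.normal(size=(1, 4, 5, 7)))
        y = block(x).data
        gx, gy = make_base_grid(5, 7, 2)
        px = Tensor(((gx + 0.5) * (2 / 7) - 1)[None])
        py = Tensor(((gy + 0.5) * (2 / 5) - 1)[None])
        expected = F.grid_sample(x, px, py).data
        np.testing.assert_allclose(y, expected, atol=1e-12)

    def test_zero_offset_output_independent_of_fusion_weight(self, rng):
        x = Tensor(rng.normal(size=(1, 4, 4, 4)))
        outs = []
        for init in (-5.0, 0.5, 9.0):
            block = DADU(DADUConfig(channels=4, scale=2, groups=2, fusion_param_init=init), rng=rng)
            outs.append(block(x).data)
        np.testing.assert_array_equal(outs[0], outs[1])
        np.testing.assert_array_equal(outs[1], outs[2])

    def test_constant_input_stays_constant_under_any_offsets(self, rng):
        block = DADU(DADUConfig(channels=4, scale=2, groups=2), rng=rng)
        block.branch1.conv.weight.data = rng.normal(size=block.branch1.conv.weight.shape) * 0.5
        block.branch2.conv.weight.data = rng.normal(size=block.branch2.conv.weight.shape) * 0.5
        y = block(Tensor(np.full((1, 4, 4, 4), 3.25))).data
        np.testing.assert_allclose(y, 3.25, atol=1e-12)

    def test_full_pipeline_matches_stage_composition(self, rng):
        block = DADU(DADUConfig(channels=4, scale=2, groups=2, dynamic_scope=True), rng=rng)
        for conv in (block.branch1.conv, block.branch2.conv, block.scope_conv):
            conv.weight.data = rng.normal(size=conv.weight.shape) * 0.3
            conv.bias.data = rng.normal(size=conv.bias.shape) * 0.1
        x = Tensor(rng.normal(size=(1, 4, 4, 6)))
        y = block(x).data
        d1 = block.branch1(x)
        d2 = block.branch2(x)
        fused = fuse_offsets(d1, d2, block.fusion_param)
        fused = block.apply_scope(fused, x)
        expected = block._sample(x, fused, 2).data
        assert np.abs(y - expected).max() <= 1e-6

    def test_pl_mode_shape_and_channel_check(self, rng):
        block = DADU(DADUConfig(channels=8, scale=2, groups=2, mode="PL"), rng=rng)
        y = block(Tensor(rng.normal(size=(1, 8, 4, 4))))
        assert y.shape == (1, 2, 8, 8)
        with pytest.raises(ValueError, match="divisible"):
            DADUConfig(channels=6, scale=2, groups=1, mode="PL")

    def test_group_permutation_consistency(self, rng):
        """Permuting channel groups with their offsets permutes the output."""
        cfg = DADUConfig(channels=4, scale=2, groups=2)
        block = DADU(cfg, rng=rng)
        x = rng.normal(size=(1, 4, 4, 4))
        off = rng.normal(size=(1, 2 * 2 * 4, 4, 4)) * 0.5  # (2 axes * G * s^2)
        y = block._sample(Tensor(x), Tensor(off), 2).data
        # swap the two groups in channels and in offsets
        x_p = x[:, [2, 3, 0, 1]]
        off_r = off.reshape(1, 2, 2, 4, 4, 4)[:, :, ::-1]
        y_p = block._sample(Tensor(x_p), Tensor(off_r.reshape(1, 16, 4, 4)), 2).data
        np.testing.assert_allclose(y_p, y[:, [2, 3, 0, 1]], atol=1e-12)

    def test_offset_gradient_matches_finite_difference(self, rng):
        block = DADU(DADUConfig(channels=2, scale=1, groups=1), rng=rng)
        x = rng.normal(size=(1, 2, 4, 4))
        off = rng.normal(size=(1, 2, 4, 4)) * 0.3
        off_t = Tensor(off, requires_grad=True)
        y = block._sample(Tensor(x), off_t, 1)
        (y * y).sum().backward()
        idx = (0, 0, 1, 2)
        eps = 1e-5
        hi = off.copy()
        hi[idx] += eps
        lo = off.copy()
        lo[idx] -= eps
        f = lambda o: float((block._sample(Tensor(x), Tensor(o), 1).data ** 2).sum())
        num = (f(hi) - f(lo)) / (2 * eps)
        assert off_t.grad[idx] == pytest.approx(num, abs=1e-3, rel=1e-3)

    def test_fusion_weight_squashed_not_clipped(self, rng):
        block = DADU(DADUConfig(channels=4, scale=2, groups=2), rng=rng)
        d1 = Tensor(np.full((1, 4, 2, 2), 1.0))
        d2 = Tensor(np.full((1, 4, 2, 2), -1.0))
        for raw in (-30.0, 0.0, 30.0):
            block.fusion_param.data = np.array(raw)
            w = 1 / (1 + np.exp(-block.fusion_param.data))
            assert 0.0 < w < 1.0
            out = fuse_offsets(d1, d2, block.fusion_param).data
            assert np.all(out > -1.0) and np.all(out < 1.0)
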