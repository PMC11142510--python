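"""Architecture contracts: reference convolutions, layers, both branches,
fusion, head, and checkpoint round-trips."""

import h5py
import json
import numpy as np
import pytest

from hybridcs.autograd import Tensor
from hybridcs.layers import (BatchNorm, CBM, Conv2d, Conv3d, SandglassBlock,
                             smish)
from hybridcs.model import HybridCSModel, ModelConfig
from hybridcs.reference import conv2d_ref, conv3d_ref


class TestReferenceConvs:
    def test_one_by_one_identity_kernel(self, rng):
        v = rng.normal(size=(4, 4, 1))
        out = conv2d_ref(v, np.ones((1, 1, 1, 1)), np.zeros(1))
        np.testing.assert_allclose(out, v)

    def test_zero_kernel_bias_three(self, rng):
        v = rng.normal(size=(5, 5, 2))
        out = conv2d_ref(v, np.zeros((1, 3, 3, 2)), np.array([3.0]))
        np.testing.assert_allclose(out, 3.0)

    def test_delta_kernel_is_identity_3d(self, rng):
        v = rng.normal(size=(4, 4, 5, 1))
        w = np.zeros((1, 1, 1, 1, 1))
        w[0, 0, 0, 0, 0] = 1.0
        out = conv3d_ref(v, w, np.zeros(1), spectral_stride=1)
        np.testing.assert_allclose(out[..., 0], v[..., 0])

    def test_strided_spectral_depth_matches_formula(self, rng):
        """A (1,1,7) kernel with spectral stride 2 on 100 bands gives 47."""
        v = rng.normal(size=(7, 7, 100, 1))
        w = rng.normal(size=(2, 1, 1, 7, 1))
        out = conv3d_ref(v, w, np.zeros(2), spectral_stride=2)
        assert out.shape == (7, 7, 47, 2)


class TestFastPathAgainstOracle:
    def test_conv2d_random_instance(self, rng):
        layer = Conv2d("c", 2, 3, (3, 3), rng, padding="valid")
        x = rng.normal(size=(1, 6, 6, 2)).astype(np.float32)
        out = layer.forward(Tensor(x)).data[0]
        w = layer.w.data.reshape(3, 3, 2, 3).transpose(3, 0, 1, 2)
        np.testing.assert_allclose(out, conv2d_ref(x[0], w, layer.b.data),
                                   atol=1e-5)

    def test_conv3d_random_instance(self, rng):
        layer = Conv3d("c", 1, 4, (3, 3, 3), rng, spectral_stride=1,
                       spatial_padding="valid")
        x = rng.normal(size=(1, 5, 5, 9, 1)).astype(np.float32)
        out = layer.forward(Tensor(x)).data[0]
        w = layer.w.data.reshape(3, 3, 3, 1, 4).transpose(4, 0, 1, 2, 3)
        np.testing.assert_allclose(
            out, conv3d_ref(x[0], w, layer.b.data), atol=1e-5)


class TestSmish:
    def test_fixed_points_and_limits(self):
        assert smish(0.0) == 0.0
        assert abs(smish(-30.0)) < 1e-8
        assert smish(1.0) == pytest.approx(0.4996, abs=1e-4)

    def test_no_overflow_at_extremes(self):
        out = smish(np.array([-1e4, -50.0, 0.0, 50.0, 1e4]))
        assert np.all(np.isfinite(out))
        assert out[-1] == pytest.approx(1e4 * np.tanh(np.log(2)), rel=1e-3)

    def test_tensor_and_array_paths_agree(self, rng):
        x = rng.normal(size=(20,))
        np.testing.assert_allclose(smish(x), smish(Tensor(x)).data, atol=1e-12)


class TestCBM:
    def test_output_shape_contract(self, rng):
        cbm = CBM("cbm", 100, 24, 3, rng)
        x = Tensor(rng.normal(size=(2, 7, 7, 100)).astype(np.float32))
        assert cbm.forward(x, training=False).shape == (2, 7, 7, 24)

    def test_eval_mode_with_unit_stats_is_smish_of_conv(self, rng):
        cbm = CBM("cbm", 3, 3, 1, rng)
        # identity 1x1 conv
        cbm.conv.w.data = np.eye(3, dtype=np.float32)
        cbm.conv.b.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 4, 4, 3)).astype(np.float32))
        out = cbm.forward(x, training=False)
        np.testing.assert_allclose(out.data, smish(x.data), atol=1e-4)

    def test_bounded_for_wild_inputs(self, rng):
        cbm = CBM("cbm", 4, 8, 3, rng)
        x = Tensor(rng.uniform(-10, 10, size=(3, 5, 5, 4)).astype(np.float32))
        assert np.all(np.isfinite(cbm.forward(x, training=True).data))

    def test_batch_of_one_warns_and_falls_back(self, rng):
        cbm = CBM("cbm", 2, 2, 1, rng)
        x = Tensor(rng.normal(size=(1, 3, 3, 2)).astype(np.float32))
        with pytest.warns(UserWarning, match="running statistics"):
            cbm.forward(x, training=True)


class TestSandglassBlock:
    def test_zeroed_residual_path_is_identity(self, rng):
        block = SandglassBlock("sg", 24, 4, rng)
        block.dw2.w.data[:] = 0.0
        block.dw2.b.data[:] = 0.0
        x = Tensor(rng.normal(size=(2, 7, 7, 24)).astype(np.float32))
        out = block.forward(x, training=False)
        np.testing.assert_allclose(out.data, x.data, atol=1e-6)

    def test_shape_preserved(self, rng):
        block = SandglassBlock("sg", 24, 4, rng)
        x = Tensor(rng.normal(size=(1, 7, 7, 24)).astype(np.float32))
        assert block.forward(x, training=False).shape == (1, 7, 7, 24)

    def test_indivisible_width_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            SandglassBlock("sg", 10, 4, rng)

    def test_shortcut_jacobian_is_identity_when_f_vanishes(self, rng):
        block = SandglassBlock("sg", 8, 4, rng)
        block.dw2.w.data[:] = 0.0
        block.dw2.b.data[:] = 0.0
        x0 = rng.normal(size=(1, 3, 3, 8)).astype(np.float64)
        eps = 1e-4
        for _ in range(3):
            i = tuple(rng.integers(0, s) for s in x0.shape)
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            diff = (block.forward(Tensor(xp), False).data[i]
                    - block.forward(Tensor(xm), False).data[i]) / (2 * eps)
            assert diff == pytest.approx(1.0, abs=1e-5)


class TestBranches:
    def test_ss_branch_reference_shapes(self, rng):
        """100 bands -> first-conv depth 47 -> pooled 60-vector."""
        model = HybridCSModel(ModelConfig(seed=0))
        x = rng.normal(size=(2, 7, 7, 100)).astype(np.float32)
        inter = {}
        f_ss = model.ss_branch(x, intermediates=inter)
        assert inter["ss_conv1"].shape == (2, 7, 7, 47, 24)
        assert inter["ss_conv2d"].shape == (2, 7, 7, 60)
        assert f_ss.shape == (2, 60)

    def test_ss_branch_deterministic_in_eval(self, rng):
        model = HybridCSModel(ModelConfig(seed=1))
        x = rng.normal(size=(1, 7, 7, 100)).astype(np.float32)
        a = model.ss_branch(x).data
        b = model.ss_branch(x).data
        np.testing.assert_array_equal(a, b)

    def test_zero_patch_zero_biases_gives_zero_feature(self):
        model = HybridCSModel(ModelConfig(seed=2))
        x = np.zeros((1, 7, 7, 100), dtype=np.float32)
        np.testing.assert_allclose(model.ss_branch(x).data, 0.0, atol=1e-7)

    def test_sandglass_branch_shapes(self, rng):
        model = HybridCSModel(ModelConfig(seed=3))
        x = rng.normal(size=(2, 7, 7, 100)).astype(np.float32)
        inter = {}
        f = model.sandglass_branch(x, intermediates=inter)
        assert inter["sg_pooled_map"].shape == (2, 7, 7, 24)
        assert f.shape == (2, 60)
        np.testing.assert_array_equal(
            f.data, model.sandglass_branch(x).data)

    def test_too_few_bands_for_first_kernel_rejected(self):
        with pytest.raises(ValueError, match="cannot fit"):
            ModelConfig(input_bands=5)


class TestFusionAndHead:
    def test_concatenation_length_then_projection(self, rng):
        model = HybridCSModel(ModelConfig(seed=4))
        f_ss = Tensor(rng.normal(size=(3, 60)).astype(np.float32))
        f_sand = Tensor(rng.normal(size=(3, 60)).astype(np.float32))
        assert model.fuse_proj.w.shape == (120, 60)    # concat is 60 + 60
        assert model.fuse(f_ss, f_sand).shape == (3, 60)

    def test_identity_projection_recovers_first_branch(self, rng):
        model = HybridCSModel(ModelConfig(seed=4))
        model.fuse_proj.w.data = np.vstack(
            [np.eye(60), np.zeros((60, 60))]).astype(np.float32)
        model.fuse_proj.b.data[:] = 0.0
        f_ss = Tensor(rng.normal(size=(2, 60)).astype(np.float32))
        f_sand = Tensor(rng.normal(size=(2, 60)).astype(np.float32))
        out = model.fuse(f_ss, f_sand)
        # default batch-norm running stats are (0, 1): fuse = smish(proj)
        np.testing.assert_allclose(out.data, smish(f_ss.data), atol=1e-4)

    def test_mismatched_feature_lengths_rejected(self, rng):
        model = HybridCSModel(ModelConfig(seed=4))
        with pytest.raises(ValueError, match="lengths"):
            model.fuse(Tensor(np.zeros((1, 60))), Tensor(np.zeros((1, 30))))

    def test_constant_bias_head_predicts_class_one(self, rng):
        model = HybridCSModel(ModelConfig(seed=5))
        model.head.w.data[:] = 0.0
        model.head.b.data[:] = 0.0
        model.head.b.data[0] = 1.0
        x = rng.normal(size=(4, 7, 7, 100)).astype(np.float32)
        assert np.all(model.predict(x) == 1)

    def test_head_width_equals_class_count(self):
        model = HybridCSModel(ModelConfig(n_classes=6))
        assert model.head.w.shape == (60, 6)
        model7 = HybridCSModel(ModelConfig(n_classes=7))
        assert model7.head.w.shape == (60, 7)


class TestModel:
    def test_seeded_rebuild_reproduces_scores(self, rng):
        cfg = ModelConfig(input_bands=12, seed=99)
        x = rng.normal(size=(3, 7, 7, 12)).astype(np.float32)
        a = HybridCSModel(cfg).forward(x).data
        b = HybridCSModel(cfg).forward(x).data
        np.testing.assert_array_equal(a, b)

    def test_parameter_count_reported(self):
        model = HybridCSModel(ModelConfig())
        assert model.n_parameters == sum(t.data.size
                                         for t in model.parameters())
        assert model.n_parameters > 10_000

    def test_checkpoint_round_trip(self, tmp_path, rng):
        cfg = ModelConfig(input_bands=10, seed=8)
        model = HybridCSModel(cfg)
        x = rng.normal(size=(2, 7, 7, 10)).astype(np.float32)
        before = model.forward(x).data
        path = tmp_path / "ckpt.h5"
        model.save(path)
        back = HybridCSModel.load(path)
        np.testing.assert_array_equal(back.forward(x).data, before)

    def test_loader_refuses_mismatched_shapes(self, tmp_path):
        model = HybridCSModel(ModelConfig(input_bands=10, seed=8))
        path = tmp_path / "ckpt.h5"
        model.save(path)
        with h5py.File(path, "a") as f:
            cfg = json.loads(f.attrs["config"])
            cfg["conv2d_out"] = 30       # no longer matches stored weights
            f.attrs["config"] = json.dumps(cfg)
        with pytest.raises(ValueError, match="mismatch"):
            HybridCSModel.load(path)

    def test_wrong_patch_shape_rejected(self, rng):
        model = HybridCSModel(ModelConfig(input_bands=10))
        with pytest.raises(ValueError, match="expected patches"):
            model.forward(rng.normal(size=(1, 5, 5, 10)).astype(np.float32))
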