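"""Architecture contracts of the SE/pyramid-pooling 3D U-Net."""

import numpy as np
import pytest

from segan3d.nn import Tensor
from segan3d.segnet import (FeatureMap, NetConfig, PredictionMap, PyramidPooling,
                            SEBlock, SegNet3D, SEModule, se_weights,
                            tensor_to_feature_map)


@pytest.fixture(scope="module")
def small_net():
    return SegNet3D(NetConfig(base_channels=2, seed=0))


class TestSEBlock:
    def test_weights_strictly_inside_unit_interval(self, rng):
        se = SEBlock(8, r=2, rng=rng)
        w = se.weights(Tensor(rng.normal(size=(2, 8, 3, 3, 3)).astype(np.float32)))
        assert np.all(w.data > 0) and np.all(w.data < 1)

    def test_bottleneck_width_is_channels_over_r(self, rng):
        assert SEBlock(8, r=2, rng=rng).hidden == 4
        assert SEBlock(2, r=8, rng=rng).hidden == 1  # floor at 1

    def test_zero_excitation_parameters_give_half_weights(self, rng):
        se = SEBlock(4, r=2, rng=rng)
        for p in se.parameters():
            p.data[...] = 0.0
        w = se.weights(Tensor(rng.normal(size=(1, 4, 2, 2, 2)).astype(np.float32)))
        assert np.allclose(w.data, 0.5)

    def test_zeroed_weight_kills_its_channel(self, rng):
        # parameter surgery: drive one channel's excitation to -inf
        se = SEBlock(4, r=2, rng=rng)
        se.fc2.weight.data[:, 1] = 0.0
        se.fc2.bias.data[1] = -1e9
        out = se(Tensor(rng.normal(size=(1, 4, 2, 2, 2)).astype(np.float32)))
        assert np.all(out.data[:, 1] == 0.0)
        assert np.any(out.data[:, 0] != 0.0)

    def test_se_weights_helper_accepts_feature_maps(self, rng):
        se = SEBlock(3, r=1, rng=rng)
        fm = FeatureMap(values=rng.normal(size=(2, 2, 2, 3)))
        w = se_weights(fm, se)
        assert w.shape == (3,) and np.all((w > 0) & (w < 1))


class TestSEModule:
    def test_stride_two_halves_every_axis(self, rng):
        mod = SEModule(3, 5, stride=2, cfg=NetConfig(), rng=rng)
        out = mod(Tensor(rng.normal(size=(1, 3, 8, 8, 4)).astype(np.float32)))
        assert out.shape == (1, 5, 4, 4, 2)

    def test_stride_one_preserves_shape_and_compresses_channels(self, rng):
        mod = SEModule(8, 4, stride=1, cfg=NetConfig(), rng=rng)
        out = mod(Tensor(rng.normal(size=(1, 8, 4, 4, 4)).astype(np.float32)))
        assert out.shape == (1, 4, 4, 4, 4)

    def test_odd_extent_with_stride_two_rejected(self, rng):
        mod = SEModule(2, 2, stride=2, cfg=NetConfig(), rng=rng)
        with pytest.raises(ValueError, match="axis y"):
            mod(Tensor(rng.normal(size=(1, 2, 4, 5, 4)).astype(np.float32)))


class TestPyramidPooling:
    def test_three_parallel_branches_by_default(self, rng):
        ppm = PyramidPooling(8, NetConfig(), rng=rng)
        assert len(ppm.branch_convs) == 3
        assert ppm.pool_sizes == (1, 2, 5)

    def test_output_spatial_size_equals_input(self, rng):
        ppm = PyramidPooling(8, NetConfig(), rng=rng)
        out = ppm(Tensor(rng.normal(size=(1, 8, 4, 4, 1)).astype(np.float32)))
        assert out.shape == (1, 8, 4, 4, 1)

    @pytest.mark.parametrize("seed", range(3))
    def test_spatially_constant_input_stays_constant(self, seed):
        rng = np.random.default_rng(seed)
        ppm = PyramidPooling(4, NetConfig(norm="none"), rng=rng)
        x = np.ones((1, 4, 4, 4, 2), np.float32) * rng.normal(size=(1, 4, 1, 1, 1)).astype(np.float32)
        out = ppm(Tensor(x)).data
        spatial_sd = out.std(axis=(2, 3, 4))
        assert spatial_sd.max() < 1e-5


class TestForward:
    def test_full_shape_contract(self, small_net):
        x = np.random.default_rng(0).random((64, 64, 16), dtype=np.float32)
        probs, taps = small_net.forward(x)
        assert probs.shape == (1, 3, 64, 64, 16)
        assert taps["bottleneck"].shape[2:] == (4, 4, 1)  # 4 halvings per axis
        assert taps["feature_match"].shape == (1, 2, 64, 64, 16)

    def test_softmax_normalisation_per_voxel(self, small_net):
        x = np.random.default_rng(1).random((32, 32, 16), dtype=np.float32)
        probs, _ = small_net.forward(x)
        assert probs.data.min() >= 0
        assert np.abs(probs.data.sum(axis=1) - 1.0).max() < 1e-6

    def test_indivisible_extent_names_the_axis(self, small_net):
        with pytest.raises(ValueError, match="axis z"):
            small_net.forward(np.zeros((32, 32, 24), np.float32))

    def test_divisible_by_16_succeeds_exactly(self, small_net):
        small_net.forward(np.zeros((16, 16, 16), np.float32))  # minimum size
        with pytest.raises(ValueError):
            small_net.forward(np.zeros((16, 16, 8), np.float32))

    def test_encoder_has_four_stride_two_stages(self, small_net):
        strides = [g.mod1.stride for g in small_net.encoder]
        assert strides == [2, 2, 2, 2]
        assert all(g.mod2.stride == 1 for g in small_net.encoder)

    def test_batched_input(self, small_net):
        probs, _ = small_net.forward(np.zeros((2, 16, 16, 16), np.float32))
        assert probs.shape == (2, 3, 16, 16, 16)


class TestPredictionMap:
    def test_validates_normalisation(self):
        bad = np.zeros((2, 2, 2, 3))
        with pytest.raises(ValueError):
            PredictionMap(probs=bad)

    def test_argmax_discards_fake_mass(self):
        probs = np.zeros((1, 1, 3, 3))
        probs[0, 0, 0] = [0.6, 0.3, 0.1]   # background
        probs[0, 0, 1] = [0.1, 0.6, 0.3]   # liver
        probs[0, 0, 2] = [0.1, 0.3, 0.6]   # fake mass discarded -> liver
        mask = PredictionMap(probs=probs).argmax_mask()
        assert mask.tolist() == [[[0, 1, 1]]]

    def test_ties_break_toward_lowest_class(self):
        probs = np.full((1, 1, 1, 3), 1 / 3)
        assert PredictionMap(probs=probs).argmax_mask()[0, 0, 0] == 0

    def test_tensor_to_feature_map_moves_channels_last(self, rng):
        t = Tensor(rng.normal(size=(1, 5, 2, 3, 4)).astype(np.float32))
        fm = tensor_to_feature_map(t, "bottleneck")
        assert fm.values.shape == (2, 3, 4, 5)
        assert fm.channels == 5 and fm.level_tag == "bottleneck"


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(base_channels=0)
        with pytest.raises(ValueError):
            NetConfig(depth=3)
        with pytest.raises(ValueError):
            NetConfig(pool_sizes=())
        with pytest.raises(ValueError):
            NetConfig(n_classes=2)

    def test_round_trip_dict(self):
        cfg = NetConfig(base_channels=4, pool_sizes=(1, 3), seed=9)
        assert NetConfig.from_dict(cfg.to_dict()) == cfg
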