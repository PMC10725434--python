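import numpy as np
import pytest

from neuroage import ModelSpec, build_model
from neuroage.attention import AttentionMap, average_attention, difference_attention, gradcam
from neuroage.model import Predictor
from neuroage.nn.layers import Dense, Flatten
from neuroage.types import SubjectRecord, VolumeImage


def linear_toy_model(conv_w, head_w, shape=(8, 8, 8)):
    """cnn_only predictor with one conv block rewired to be exactly linear.

    The conv kernel is a hand-set 1-hot (centre tap only), batch norm is
    the identity (gamma=1, beta=0, running stats 0/1) and the dense head
    applies hand-set weights directly to the flattened pooled activations,
    so every gradient is computable in closed form.
    """
    n_ch = conv_w.shape[0]
    spec = ModelSpec(variant="cnn_only", input_shape=shape, n_conv_blocks=1,
                     base_channels=n_ch, dropout_rate=0.0)
    model = build_model(spec, init_seed=0)
    conv = model.image_layers[0]
    w = np.zeros((27, n_ch), dtype=np.float32)
    w[13] = conv_w  # centre of the 3x3x3 kernel
    conv.params["w"] = w
    conv.params["b"] = np.zeros(n_ch, dtype=np.float32)
    bn = model.image_layers[1]
    bn.eps = 0.0  # fresh BN with running stats (0, 1) is then exactly identity
    # strip the dense image head down to a single linear readout
    pooled = tuple(s // 2 for s in shape)
    n_flat = n_ch * int(np.prod(pooled))
    readout = Dense(n_flat, model.n_image_features, dtype=np.float64)
    readout.params["w"] = np.zeros((n_flat, model.n_image_features), dtype=np.float32)
    readout.params["w"][:, 0] = head_w
    readout.params["b"] = np.zeros(model.n_image_features, dtype=np.float32)
    model.image_layers = [conv, model.image_layers[1], model.image_layers[2],
                          model.image_layers[3], Flatten(), readout]
    model.block_relu_idx = [2]
    final = Dense(model.n_image_features, 1, dtype=np.float64)
    final.params["w"] = np.zeros((model.n_image_features, 1), dtype=np.float32)
    final.params["w"][0, 0] = 1.0
    final.params["b"] = np.zeros(1, dtype=np.float32)
    model.head_layers = [final]
    return model, pooled


def record_from(data):
    return SubjectRecord("t", 50.0, "female", VolumeImage(np.asarray(data)))


class TestGradcamOracle:
    def test_two_channel_linear_model_matches_closed_form(self):
        """Map equals the hand-computed weighted activation sum (tol 1e-5)."""
        shape = (8, 8, 8)
        rng = np.random.default_rng(0)
        x = rng.random(shape) + 0.5  # positive input -> ReLU transparent
        conv_w = np.array([1.0, 2.0])  # channel c = c-th multiple of input
        pooled = (4, 4, 4)
        n_flat = 2 * 64
        head_w = rng.normal(0, 1, n_flat)
        model, _ = linear_toy_model(conv_w, head_w, shape)

        amap = gradcam(model, record_from(x), layer=0, normalized=False)

        # closed form: activations A_c = conv_w[c] * x; the readout weight
        # of each *pooled* cell is the gradient reaching it; the pre-pool
        # gradient lands on each cell's argmax voxel.
        acts = np.stack([conv_w[0] * x, conv_w[1] * x])
        head = head_w.reshape(2, *pooled)
        grads = np.zeros((2, *shape))
        for c in range(2):
            for i in range(4):
                for j in range(4):
                    for k in range(4):
                        block = acts[c, 2*i:2*i+2, 2*j:2*j+2, 2*k:2*k+2]
                        am = np.unravel_index(np.argmax(block), (2, 2, 2))
                        grads[c, 2*i+am[0], 2*j+am[1], 2*k+am[2]] = head[c, i, j, k]
        weights = grads.mean(axis=(1, 2, 3))
        expected = np.maximum((weights[:, None, None, None] * acts).sum(0), 0.0)
        np.testing.assert_allclose(amap.data, expected, atol=1e-5)

    def test_uniform_raw_map_normalizes_to_zeros(self):
        """Spatial-mean model -> constant raw map -> all-zero normalized map."""
        shape = (8, 8, 8)
        x = np.full(shape, 2.0)
        n_flat = 64
        model, _ = linear_toy_model(np.array([1.0]), np.full(n_flat, 1.0 / n_flat), shape)
        amap = gradcam(model, record_from(x), layer=0, normalized=True)
        np.testing.assert_array_equal(amap.data, 0.0)

    def test_normalized_range(self, tiny_cohort, tiny_trained):
        model, _ = tiny_trained
        amap = gradcam(model, tiny_cohort[0])
        assert amap.data.shape == model.spec.input_shape
        if amap.data.max() > 0:
            assert amap.data.min() == 0.0
            assert amap.data.max() == 1.0

    def test_layer_out_of_range_rejected(self, tiny_cohort, tiny_trained):
        model, _ = tiny_trained
        with pytest.raises(IndexError, match="block"):
            gradcam(model, tiny_cohort[0], layer=5)

    def test_batch_composition_invariance(self, tiny_cohort, tiny_trained):
        """Per-subject map unchanged by inference on other subjects."""
        model, _ = tiny_trained
        a = gradcam(model, tiny_cohort[0]).data
        for r in tiny_cohort[1:4]:
            gradcam(model, r)
        b = gradcam(model, tiny_cohort[0]).data
        np.testing.assert_array_equal(a, b)


class TestAggregation:
    def test_single_map_average_is_itself(self):
        m = AttentionMap(np.random.default_rng(0).random((4, 4, 4)), normalized=False)
        np.testing.assert_array_equal(average_attention([m]).data, m.data)

    def test_two_constant_maps(self):
        a = AttentionMap(np.zeros((4, 4, 4)), normalized=True)
        b = AttentionMap(np.ones((4, 4, 4)), normalized=True)
        np.testing.assert_array_equal(average_attention([a, b]).data, 0.5)

    def test_mean_bounded_by_inputs(self):
        rng = np.random.default_rng(1)
        maps = [AttentionMap(rng.random((4, 4, 4)), normalized=True) for _ in range(5)]
        stack = np.stack([m.data for m in maps])
        avg = average_attention(maps).data
        assert (avg >= stack.min(0) - 1e-12).all()
        assert (avg <= stack.max(0) + 1e-12).all()

    def test_empty_average_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            average_attention([])

    def test_shape_mismatch_rejected(self):
        a = AttentionMap(np.zeros((4, 4, 4)), normalized=True)
        b = AttentionMap(np.zeros((5, 5, 5)), normalized=True)
        with pytest.raises(ValueError, match="shapes"):
            average_attention([a, b])


class TestDifference:
    def test_identical_means_all_zero(self):
        rng = np.random.default_rng(2)
        m = [AttentionMap(rng.random((4, 4, 4)), normalized=True) for _ in range(3)]
        out = difference_attention(m, list(m))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_swap_negates_raw_difference(self):
        rng = np.random.default_rng(3)
        a = [AttentionMap(rng.random((4, 4, 4)), normalized=True)]
        b = [AttentionMap(rng.random((4, 4, 4)), normalized=True)]
        ab = difference_attention(a, b, normalized=False).data
        ba = difference_attention(b, a, normalized=False).data
        np.testing.assert_allclose(ab, -ba, atol=1e-12)

    def test_single_voxel_difference_is_unique_one(self):
        base = np.full((4, 4, 4), 0.5)
        bumped = base.copy()
        bumped[1, 2, 3] = 0.9
        out = difference_attention(
            [AttentionMap(bumped, normalized=True)],
            [AttentionMap(base, normalized=True)],
        )
        assert out.data[1, 2, 3] == 1.0
        assert (out.data == 1.0).sum() == 1

    def test_empty_group_rejected(self):
        m = [AttentionMap(np.zeros((4, 4, 4)), normalized=True)]
        with pytest.raises(ValueError, match="nonempty"):
            difference_attention(m, [])
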