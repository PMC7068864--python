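"""Reference operators, architecture builder, training engine, embedding."""

import numpy as np
import pytest

import oracles
from lesionclass import cnn
from lesionclass.cnn import (LayerSpec, Network, NetworkSpec, TrainConfig,
                             build_lesion_net, conv2d, maxpool,
                             multinomial_log_loss, propagate_shapes, relu,
                             softmax)
from lesionclass.errors import ParameterError, StateError


class TestConv2d:
    def test_identity_kernel(self):
        rng = np.random.default_rng(0)
        plane = rng.random((5, 6))
        assert conv2d(plane, np.array([[1.0]])) == pytest.approx(plane)

    def test_zero_kernel(self):
        plane = np.ones((4, 4))
        assert np.all(conv2d(plane, np.zeros((3, 3))) == 0.0)

    def test_flip_equals_rotated_kernel(self):
        rng = np.random.default_rng(3)
        plane = rng.random((5, 7))
        k = rng.random((3, 3))
        assert conv2d(plane, k, flip=True) == pytest.approx(
            conv2d(plane, k[::-1, ::-1], flip=False))

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(9)
        plane = rng.random((4, 4))
        k = rng.random((3, 3))
        for flip in (False, True):
            assert conv2d(plane, k, flip=flip) == pytest.approx(
                oracles.conv_by_loops(plane, k, flip=flip))

    def test_empty_kernel_rejected(self):
        with pytest.raises(ParameterError):
            conv2d(np.ones((3, 3)), np.empty((0, 0)))


class TestMaxPool:
    def test_single_window(self):
        out = maxpool(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert out.shape == (1, 1) and out[0, 0] == 4.0

    def test_constant_plane_quarter_size(self):
        out = maxpool(np.full((6, 8), 0.3))
        assert out.shape == (3, 4)
        assert np.all(out == 0.3)

    def test_matches_window_enumeration(self):
        rng = np.random.default_rng(1)
        plane = rng.random((8, 8))
        assert maxpool(plane) == pytest.approx(oracles.maxpool_by_loops(plane))

    def test_odd_trailing_dims_dropped(self):
        plane = np.arange(35, dtype=float).reshape(5, 7)
        assert maxpool(plane).shape == (2, 3)


class TestActivationsAndLoss:
    def test_relu_definition(self):
        assert relu(np.array([-3.0, 0.0, 2.0])) == pytest.approx([0, 0, 2])
        assert relu(np.array([-4.0]), leaky_slope=0.1)[0] == pytest.approx(-0.4)

    def test_softmax_symmetry_and_simplex(self):
        assert softmax(np.array([[1.2, 1.2]]))[0] == pytest.approx([0.5, 0.5])
        rng = np.random.default_rng(0)
        p = softmax(rng.normal(size=(6, 4)))
        assert p.sum(axis=1) == pytest.approx(np.ones(6))
        assert np.all(p > 0)

    def test_loss_floor_and_formula(self):
        perfect = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert multinomial_log_loss(perfect, np.array([0, 1])) == 0.0
        rng = np.random.default_rng(7)
        probs = softmax(rng.normal(size=(4, 2)))
        labels = np.array([0, 1, 1, 0])
        want = -np.mean([np.log(probs[i, labels[i]]) for i in range(4)])
        assert multinomial_log_loss(probs, labels) == pytest.approx(want)

    def test_label_out_of_range(self):
        with pytest.raises(ParameterError):
            multinomial_log_loss(np.array([[0.5, 0.5]]), np.array([2]))


class TestArchitecture:
    def test_default_build_counts_and_widths(self):
        spec = build_lesion_net()
        assert spec.count("conv") == 13
        assert spec.count("fc") == 3
        assert spec.trainable_layers == 16
        assert spec.count("maxpool") == 5
        fc = [l for l in spec.layers if l.kind == "fc"]
        assert [l.out_channels for l in fc] == [4096, 4096, 2]
        for l in spec.layers:
            if l.kind == "conv":
                assert l.kernel == (3, 3) and l.stride == 1 \
                    and l.zero_padding == 1

    def test_gaussian_filler_profile(self):
        spec = build_lesion_net()
        conv = [l for l in spec.layers if l.kind == "conv"]
        assert all(l.bias_filler == 0.2 for l in conv)
        fc = [l for l in spec.layers if l.kind == "fc"]
        assert [(l.filler_sd, l.bias_filler) for l in fc] == [
            (0.005, 1.0), (0.005, 1.0), (0.01, 0.0)]

    def test_shape_trace_64(self):
        spec = build_lesion_net((64, 64, 3), K=2)
        trace = propagate_shapes(spec)
        pools = [s for l, s in zip(spec.layers, trace) if l.kind == "maxpool"]
        assert [s[1] for s in pools] == [32, 16, 8, 4, 2]
        convs = [s for l, s in zip(spec.layers, trace) if l.kind == "conv"]
        assert [s[0] for s in convs] == [64, 64, 128, 128, 256, 256, 256,
                                         512, 512, 512, 512, 512, 512]
        assert trace[-1] == (2,)

    def test_indivisible_input_rejected(self):
        with pytest.raises(ParameterError):
            build_lesion_net((100, 100, 3))


def _tiny_spec(seed_channels=(4, 3)):
    layers = (
        LayerSpec(kind="conv", kernel=(3, 3), stride=1, zero_padding=1,
                  out_channels=seed_channels[0], bias_filler=0.1),
        LayerSpec(kind="relu"),
        LayerSpec(kind="maxpool", kernel=(2, 2), stride=2),
        LayerSpec(kind="conv", kernel=(3, 3), stride=1, zero_padding=1,
                  out_channels=seed_channels[1], bias_filler=0.1),
        LayerSpec(kind="relu"),
        LayerSpec(kind="fc", out_channels=6),
        LayerSpec(kind="relu"),
        LayerSpec(kind="fc", out_channels=5),
        LayerSpec(kind="relu"),
        LayerSpec(kind="fc", out_channels=2),
        LayerSpec(kind="softmax"),
    )
    return NetworkSpec(layers=layers, input_shape=(8, 8, 2), num_classes=2)


def test_backprop_matches_numerical_gradients():
    """Analytic layer gradients agree with central finite differences on a
    tiny network (float32 noise floor excluded)."""
    net = Network(_tiny_spec(), seed=0)
    rng = np.random.default_rng(1)
    x = rng.random((3, 2, 8, 8)).astype(np.float32)
    y = np.array([0, 1, 1])
    net._loss_and_grads(x, y, rng)
    grads = {(li, p): getattr(l, "d" + p).copy()
             for li, l in enumerate(net.layers) for p in l.params}

    def loss_at():
        logits = net._forward(x, train=True)
        return multinomial_log_loss(softmax(logits), y)

    eps = 5e-3
    for li, layer in enumerate(net.layers):
        for p in layer.params:
            P = getattr(layer, p)
            flat_idx = rng.choice(P.size, size=min(5, P.size), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, P.shape)
                orig = P[idx]
                P[idx] = orig + eps
                lp = loss_at()
                P[idx] = orig - eps
                lm = loss_at()
                P[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[(li, p)][idx]
                if abs(num) + abs(ana) > 1e-3:
                    assert ana == pytest.approx(num, rel=0.05, abs=2e-4)


def test_network_conv_layer_equals_reference_operator():
    """The batched conv layer reproduces per-channel sums of the
    reference cross-correlation operator."""
    net = Network(_tiny_spec(), seed=2)
    conv = net.layers[0]
    rng = np.random.default_rng(5)
    x = rng.random((1, 2, 8, 8)).astype(np.float32)
    got = conv.forward(x, train=False)[0]
    for o in range(conv.W.shape[0]):
        want = sum(oracles.conv_by_loops(x[0, c], conv.W[o, c])
                   for c in range(2)) + conv.b[o]
        assert got[o] == pytest.approx(want, abs=1e-5)


def test_embedding_matches_reference_op_forward():
    """FC7 embeddings equal a layer-by-layer recomputation using only the
    reference operators (conv2d / maxpool / relu / dot products)."""
    spec = _tiny_spec()
    net = Network(spec, seed=4)
    rng = np.random.default_rng(6)
    x = rng.random((1, 2, 8, 8)).astype(np.float32)
    net.trained = True
    got = net.embed(x)[0]

    out = [x[0, c].astype(float) for c in range(2)]
    fc_seen = 0
    for ls, layer in zip(spec.layers, net.layers):
        if ls.kind == "conv":
            out = [sum(oracles.conv_by_loops(p, layer.W[o, c])
                       for c, p in enumerate(out)) + layer.b[o]
                   for o in range(layer.W.shape[0])]
        elif ls.kind == "relu":
            out = [relu(p) for p in out]
            if fc_seen == 2:
                break
        elif ls.kind == "maxpool":
            out = [maxpool(p) for p in out]
        elif ls.kind == "fc":
            vec = np.concatenate([np.atleast_1d(np.asarray(p).ravel())
                                  for p in out])
            out = list(vec @ layer.W + layer.b)
            fc_seen += 1
    assert got == pytest.approx(np.asarray(out, dtype=float), abs=1e-4)


class TestTraining:
    def test_one_epoch_smoke_on_four_images(self, tmp_path):
        rng = np.random.default_rng(0)
        images = rng.random((4, 2, 8, 8)).astype(np.float32)
        labels = np.array([0, 1, 0, 1])
        path = tmp_path / "bundle.h5"
        cnn.save_bundle(str(path), images, labels)
        imgs, labs = cnn.load_bundle(str(path))
        net = Network(_tiny_spec(), seed=0)
        history = net.fit(imgs, labs, TrainConfig(epochs=1, batch_size=2))
        assert len(history) == 1 and np.isfinite(history[0])

    def test_loss_decreases_on_separable_data(self):
        rng = np.random.default_rng(3)
        n = 20
        images = np.zeros((n, 2, 8, 8), dtype=np.float32)
        labels = np.arange(n) % 2
        images[labels == 0, 0] = 0.9
        images[labels == 1, 1] = 0.9
        images += rng.normal(0, 0.05, images.shape).astype(np.float32)
        net = Network(_tiny_spec(), seed=1)
        history = net.fit(images, labels,
                          TrainConfig(epochs=20, batch_size=5, seed=1))
        assert history[-1] < history[0]

    def test_single_class_rejected(self):
        net = Network(_tiny_spec(), seed=0)
        with pytest.raises(Exception):
            net.fit(np.zeros((4, 2, 8, 8), dtype=np.float32),
                    np.zeros(4, dtype=int), TrainConfig(epochs=1))

    def test_training_reproducible_from_seed(self):
        rng = np.random.default_rng(2)
        images = rng.random((8, 2, 8, 8)).astype(np.float32)
        labels = np.array([0, 1] * 4)
        cfg = TrainConfig(epochs=3, batch_size=4, seed=9)
        h1 = Network(_tiny_spec(), seed=9).fit(images, labels, cfg)
        h2 = Network(_tiny_spec(), seed=9).fit(images, labels, cfg)
        assert h1 == h2


class TestEmbedding:
    def test_untrained_network_refuses(self):
        net = Network(_tiny_spec(), seed=0)
        with pytest.raises(StateError):
            net.embed(np.zeros((1, 2, 8, 8), dtype=np.float32))

    def test_deterministic_in_inference(self):
        net = Network(_tiny_spec(), seed=0)
        net.trained = True
        x = np.random.default_rng(1).random((2, 2, 8, 8)).astype(np.float32)
        assert np.array_equal(net.embed(x), net.embed(x))

    def test_default_spec_embedding_width_is_4096(self):
        spec = build_lesion_net()
        fc = [l for l in spec.layers if l.kind == "fc"]
        assert fc[1].out_channels == 4096


class TestAugmentation:
    def test_four_quarter_turns_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((10, 12, 3))
        assert np.array_equal(cnn.rotate90(img, 4), img)

    def test_flip_involution_and_bounds(self):
        rng = np.random.default_rng(1)
        img = rng.random((8, 8, 3))
        for axis in (0, 1):
            out = cnn.flip(cnn.flip(img, axis), axis)
            assert np.array_equal(out, img)
        assert cnn.rescale(img, 0.5).min() >= 0.0
        assert cnn.rescale(img, 2.0).max() <= 1.0

    def test_crop_translate_contracts(self):
        img = np.arange(48, dtype=float).reshape(4, 4, 3) / 48
        assert cnn.crop(img, 1, 1, 2, 2).shape == (2, 2, 3)
        with pytest.raises(ParameterError):
            cnn.crop(img, 3, 3, 4, 4)
        shifted = cnn.translate(img, 1, 0)
        assert np.all(shifted[0] == 0.0)
        assert np.array_equal(shifted[1:], img[:-1])


def test_pooling_reduction_75_percent():
    """2x2/stride-2 pooling keeps exactly 25% of the elements of any
    even-dimension plane."""
    rng = np.random.default_rng(0)
    for _ in range(10):
        h, w = 2 * rng.integers(1, 20), 2 * rng.integers(1, 20)
        plane = rng.random((int(h), int(w)))
        assert maxpool(plane).size == plane.size // 4
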