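"""Network engine: shape arithmetic, the T2F unit and its identities,
gradient correctness against central finite differences."""

import numpy as np
import pytest

from fatiguekit.network import (ArchSpec, T2FParams, activation_param_count,
                                build_cnn, layer_length, model_length_chain,
                                t2f_activation)
from fatiguekit.nn import (BatchNorm1D, Conv1D, Dense, Flatten, MaxPool1D,
                           Sequential, T2FActivation, softmax,
                           softmax_cross_entropy)

# Temporal lengths through the seven conv/pool blocks, anchored at a
# first-conv output of 2375.
LENGTH_CHAIN = [2375, 1187, 1187, 593, 593, 296, 296, 148,
                148, 74, 74, 37, 37, 18]


class TestLayerLength:
    @pytest.mark.parametrize("n_in,layer,n_out", [
        (2375, ("pool", 2, 2), 1187),
        (1187, ("conv", 3, 1), 1187),
        (37, ("pool", 2, 2), 18),
        (47500, ("conv", 128, 20), 2375),
        (15000, ("conv", 128, 20), 750),
    ])
    def test_known_lengths(self, n_in, layer, n_out):
        assert layer_length(n_in, layer) == n_out

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            layer_length(0, ("conv", 3, 1))

    def test_arch_chain_matches_reference(self):
        chain = ArchSpec().length_chain(47500)
        assert chain == LENGTH_CHAIN


class TestT2F:
    def test_zero_input_maps_to_zero(self):
        p = T2FParams(a=2.0, delta=0.4, alpha=0.7)
        assert t2f_activation(np.zeros(5), p).max() == 0.0

    def test_delta_zero_reduces_to_swish_for_any_blend(self):
        x = np.linspace(-4, 4, 101)
        sig = 1 / (1 + np.exp(-1.7 * x))
        swish = x * sig
        for alpha in (0.0, 0.3, 1.0):
            y = t2f_activation(x, T2FParams(a=1.7, delta=0.0, alpha=alpha))
            assert np.allclose(y, swish)

    def test_large_slope_approaches_rectifier(self):
        p = T2FParams(a=1e3, delta=0.0, alpha=0.5)
        assert t2f_activation(np.array([1.0]), p)[0] == pytest.approx(1.0,
                                                                      abs=1e-3)
        assert abs(t2f_activation(np.array([-1.0]), p)[0]) < 1e-3

    @pytest.mark.parametrize("kwargs", [{"a": 0.0}, {"a": -1.0},
                                        {"delta": 1.0}, {"alpha": 1.5}])
    def test_parameter_ranges_enforced(self, kwargs):
        with pytest.raises(ValueError):
            T2FParams(**kwargs)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        layer = T2FActivation(4)
        layer.a_raw.value[:] = rng.standard_normal(4) * 0.3
        layer.d_raw.value[:] = rng.standard_normal(4) * 0.3
        layer.al_raw.value[:] = rng.standard_normal(4) * 0.3
        x = rng.standard_normal((3, 4, 7))
        gy = rng.standard_normal((3, 4, 7))
        gx = layer.backward(_fwd(layer, x, gy))
        eps = 1e-6
        # input gradient
        num = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            x[i] += eps
            fp = (layer.forward(x, True) * gy).sum()
            x[i] -= 2 * eps
            fm = (layer.forward(x, True) * gy).sum()
            x[i] += eps
            num[i] = (fp - fm) / (2 * eps)
        assert np.abs(num - gx).max() < 1e-5
        # parameter gradients
        for p in layer.params():
            for j in range(p.value.size):
                p.value[j] += eps
                fp = (layer.forward(x, True) * gy).sum()
                p.value[j] -= 2 * eps
                fm = (layer.forward(x, True) * gy).sum()
                p.value[j] += eps
                assert (fp - fm) / (2 * eps) == pytest.approx(p.grad[j],
                                                              abs=1e-5)


def _fwd(layer, x, gy):
    layer.forward(x, True)
    return gy


class TestStackGradients:
    def test_full_stack_matches_finite_differences(self):
        """Conv + T2F + pool + batch-norm + dense, end to end."""
        rng = np.random.default_rng(0)
        model = Sequential([
            Conv1D(2, 3, 5, stride=2, rng=rng),
            T2FActivation(3),
            MaxPool1D(2),
            BatchNorm1D(3),
            Flatten(),
        ])
        x = rng.standard_normal((4, 2, 23))
        h = model.forward(x, True)
        model.layers.append(Dense(h.shape[1], 3, rng=rng))
        y = np.array([0, 1, 2, 0])

        def loss():
            return softmax_cross_entropy(model.forward(x, True), y)[0]

        model.zero_grad()
        val, gy, _ = softmax_cross_entropy(model.forward(x, True), y)
        model.backward(gy)
        eps = 1e-6
        for p in model.params():
            flat = p.value.ravel()
            gflat = p.grad.ravel()
            for j in range(0, flat.size, max(flat.size // 5, 1)):
                flat[j] += eps
                fp = loss()
                flat[j] -= 2 * eps
                fm = loss()
                flat[j] += eps
                assert (fp - fm) / (2 * eps) == pytest.approx(gflat[j],
                                                              abs=1e-5)


class TestBuildCNN:
    def test_measured_length_chain_matches_reference(self):
        model = build_cnn(ArchSpec(), 5, "t2f", input_len=47500)
        assert model_length_chain(model, 47500) == LENGTH_CHAIN

    @pytest.mark.parametrize("n_classes", [2, 3, 5])
    def test_softmax_width_and_normalization(self, n_classes):
        model = build_cnn(ArchSpec(), n_classes, "relu", input_len=15000)
        out = model.forward(np.random.default_rng(0).random((3, 1, 15000)),
                            training=False)
        assert out.shape == (3, n_classes)
        p = softmax(out)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_t2f_parameter_count_is_3c(self):
        model = build_cnn(ArchSpec(), 5, "t2f", input_len=15000)
        expected = 3 * sum(ArchSpec().filters)
        assert activation_param_count(model) == expected == 1104

    @pytest.mark.parametrize("variant", ["relu", "leaky_relu"])
    def test_fixed_activations_add_no_parameters(self, variant):
        model = build_cnn(ArchSpec(), 5, variant, input_len=15000)
        assert activation_param_count(model) == 0

    def test_invalid_class_count_rejected(self):
        with pytest.raises(ValueError):
            build_cnn(ArchSpec(), 4, "t2f")
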