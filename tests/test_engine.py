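"""Numerical gradient checks and mechanics of the NumPy layer engine.

Each layer's analytic backward pass is compared against central finite
differences of a scalar probe loss.  float32 arithmetic limits the
achievable agreement, so the step and tolerance are sized accordingly.
"""

import numpy as np
import pytest

from resmini import engine


def _probe_loss(layer, x, probe):
    return float((layer.forward(x, training=True) * probe).sum())


def _check_input_gradient(layer, x, rng, atol=2e-3, rtol=5e-2, n_coords=12):
    probe = rng.normal(size=layer.forward(x.copy(), training=True).shape)
    probe = probe.astype(np.float64)
    layer.forward(x, training=True)
    dx = layer.backward(probe.astype(engine.DTYPE))
    h = 1e-3
    flat_idx = rng.choice(x.size, size=min(n_coords, x.size), replace=False)
    for idx in flat_idx:
        pos = np.unravel_index(idx, x.shape)
        xp, xm = x.copy(), x.copy()
        xp[pos] += h
        xm[pos] -= h
        num = (_probe_loss(layer, xp, probe) - _probe_loss(layer, xm, probe)) / (2 * h)
        assert np.isclose(dx[pos], num, atol=atol, rtol=rtol), (
            f"input grad mismatch at {pos}: analytic {dx[pos]}, numeric {num}")


def _check_param_gradient(layer, x, key, rng, atol=2e-3, rtol=5e-2, n_coords=12):
    probe = rng.normal(size=layer.forward(x.copy(), training=True).shape)
    layer.forward(x, training=True)
    layer.backward(probe.astype(engine.DTYPE))
    analytic = layer.grads[key].copy()
    h = 1e-3
    w = layer.params[key]
    flat_idx = rng.choice(w.size, size=min(n_coords, w.size), replace=False)
    for idx in flat_idx:
        pos = np.unravel_index(idx, w.shape)
        orig = w[pos]
        w[pos] = orig + h
        fp = _probe_loss(layer, x, probe)
        w[pos] = orig - h
        fm = _probe_loss(layer, x, probe)
        w[pos] = orig
        num = (fp - fm) / (2 * h)
        assert np.isclose(analytic[pos], num, atol=atol, rtol=rtol), (
            f"{key} grad mismatch at {pos}: analytic {analytic[pos]}, numeric {num}")


@pytest.fixture
def x_small(rng):
    return rng.normal(size=(3, 2, 8, 7)).astype(engine.DTYPE)


class TestGradients:
    @pytest.mark.parametrize("stride,pad", [(1, 1), (2, 1), (1, 3)])
    def test_conv2d(self, rng, x_small, stride, pad):
        layer = engine.Conv2D(2, 4, 3, stride, pad, rng)
        _check_input_gradient(layer, x_small, rng)
        _check_param_gradient(layer, x_small, "W", rng)

    def test_batchnorm(self, rng, x_small):
        layer = engine.BatchNorm2D(2)
        # non-trivial scale/shift so the gradient exercises both params
        layer.params["gamma"][:] = [1.3, 0.7]
        layer.params["beta"][:] = [0.2, -0.1]
        _check_input_gradient(layer, x_small, rng, atol=5e-3)
        _check_param_gradient(layer, x_small, "gamma", rng)
        _check_param_gradient(layer, x_small, "beta", rng)

    def test_maxpool(self, rng, x_small):
        _check_input_gradient(engine.MaxPool2D(3, 2, 1), x_small, rng)

    def test_global_avg_pool(self, rng, x_small):
        _check_input_gradient(engine.GlobalAvgPool(), x_small, rng)

    def test_dense(self, rng):
        x = rng.normal(size=(5, 6)).astype(engine.DTYPE)
        layer = engine.Dense(6, 4, rng)
        _check_input_gradient(layer, x, rng)
        _check_param_gradient(layer, x, "W", rng)
        _check_param_gradient(layer, x, "b", rng)

    def test_residual_block(self, rng, x_small):
        block = engine.ResidualBlock(2, 4, 2, projection=True, rng=rng)
        _check_input_gradient(block, x_small, rng, atol=5e-3)


class TestMechanics:
    def test_conv_matches_direct_convolution(self, rng):
        """im2col conv agrees with an explicit loop-based oracle."""
        x = rng.normal(size=(2, 3, 6, 5)).astype(engine.DTYPE)
        layer = engine.Conv2D(3, 4, 3, 1, 1, rng)
        out = layer.forward(x, training=True)
        w = layer.params["W"]
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        expected = np.zeros_like(out)
        for n in range(2):
            for co in range(4):
                for i in range(6):
                    for j in range(5):
                        expected[n, co, i, j] = np.sum(
                            xp[n, :, i:i + 3, j:j + 3] * w[co])
        np.testing.assert_allclose(out, expected, rtol=1e-4, atol=1e-5)

    def test_maxpool_matches_naive_windows(self, rng):
        x = rng.normal(size=(1, 1, 7, 7)).astype(engine.DTYPE)
        out = engine.MaxPool2D(3, 2, 1).forward(x, training=True)
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)),
                    constant_values=-np.inf)
        for i in range(out.shape[2]):
            for j in range(out.shape[3]):
                assert out[0, 0, i, j] == xp[0, 0, 2 * i:2 * i + 3,
                                             2 * j:2 * j + 3].max()

    def test_batchnorm_normalizes_in_training_mode(self, rng):
        layer = engine.BatchNorm2D(3)
        x = rng.normal(loc=5.0, scale=2.0, size=(4, 3, 6, 6)).astype(engine.DTYPE)
        y = layer.forward(x, training=True)
        np.testing.assert_allclose(y.mean(axis=(0, 2, 3)), 0.0, atol=1e-5)
        np.testing.assert_allclose(y.std(axis=(0, 2, 3)), 1.0, atol=1e-2)

    def test_batchnorm_running_stats_drive_inference(self, rng):
        layer = engine.BatchNorm2D(2)
        x = rng.normal(loc=2.0, size=(8, 2, 4, 4)).astype(engine.DTYPE)
        for _ in range(200):
            layer.forward(x, training=True)
        y_eval = layer.forward(x, training=False)
        np.testing.assert_allclose(y_eval.mean(axis=(0, 2, 3)), 0.0, atol=0.05)

    def test_softmax_rows_on_simplex(self, rng):
        z = rng.normal(scale=10, size=(6, 4))
        p = engine.softmax(z)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p > 0).all()

    def test_adam_reduces_quadratic_loss(self, rng):
        """Adam on a dense layer decreases cross-entropy on a fixed batch."""
        layer = engine.Dense(4, 3, rng)
        net = engine.Network([layer], num_classes=3)
        x = rng.normal(size=(16, 4)).astype(engine.DTYPE)
        y = np.eye(3, dtype=engine.DTYPE)[rng.integers(0, 3, 16)]
        # bypass the image-shape guard: drive the layer directly
        opt = engine.Adam(net, learning_rate=0.05)
        losses = []
        for _ in range(30):
            probs = engine.softmax(layer.forward(x, training=True))
            losses.append(float(-np.mean(np.log((probs * y).sum(axis=1)))))
            layer.backward(((probs - y) / len(x)).astype(engine.DTYPE))
            opt.step()
        assert losses[-1] < losses[0] * 0.7
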