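import numpy as np
import pytest
from scipy import ndimage

import histotile.nn as nn
from histotile.nn import dilated_conv2d


def loop_dilated_conv(x, k, rate):
    """Brute-force dilated cross-correlation with 'same' zero padding."""
    c_out, c_in, kh, kw = k.shape
    c, h, w = x.shape
    ph, pw = rate * (kh - 1) // 2, rate * (kw - 1) // 2
    y = np.zeros((c_out, h, w))
    for co in range(c_out):
        for u in range(h):
            for v in range(w):
                acc = 0.0
                for ci in range(c_in):
                    for a in range(kh):
                        for b in range(kw):
                            uu, vv = u + a * rate - ph, v + b * rate - pw
                            if 0 <= uu < h and 0 <= vv < w:
                                acc += x[ci, uu, vv] * k[co, ci, a, b]
                y[co, u, v] = acc
    return y


class TestDilatedConv:
    def test_worked_value_all_ones(self):
        x = np.ones((1, 5, 5))
        k = np.ones((1, 1, 3, 3))
        out = dilated_conv2d(x, k, rate=2, padding="valid")
        assert out.shape == (1, 1, 1)
        assert out[0, 0, 0] == pytest.approx(9.0)

    def test_identity_kernel_any_rate(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 6, 7))
        k = np.zeros((2, 2, 1, 1))
        k[0, 0], k[1, 1] = 1.0, 1.0
        for rate in (1, 2, 3):
            np.testing.assert_allclose(dilated_conv2d(x, k, rate), x)

    def test_rate_one_equals_standard_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((1, 8, 8))
        k = rng.standard_normal((1, 1, 3, 3))
        ours = dilated_conv2d(x, k, rate=1)[0]
        ref = ndimage.correlate(x[0], k[0, 0], mode="constant", cval=0.0)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_exhaustive_small_instances_match_loop_oracle(self):
        rng = np.random.default_rng(2)
        for h in (3, 5, 9):
            for w in (4, 7, 9):
                for ks in (1, 3):
                    for rate in (1, 2, 3):
                        x = rng.standard_normal((2, h, w))
                        k = rng.standard_normal((3, 2, ks, ks))
                        np.testing.assert_allclose(
                            dilated_conv2d(x, k, rate),
                            loop_dilated_conv(x, k, rate),
                            atol=1e-10,
                            err_msg=f"h={h} w={w} k={ks} r={rate}",
                        )

    @pytest.mark.parametrize("rate", [1, 2, 3])
    @pytest.mark.parametrize("ks", [1, 3])
    def test_receptive_field_span(self, ks, rate):
        # a single bright pixel spreads over (K-1)*r + 1 output positions per axis
        x = np.zeros((1, 15, 15))
        x[0, 7, 7] = 1.0
        k = np.ones((1, 1, ks, ks))
        out = dilated_conv2d(x, k, rate)[0]
        rows = np.flatnonzero(out.any(axis=1))
        cols = np.flatnonzero(out.any(axis=0))
        span = (ks - 1) * rate + 1
        assert rows[-1] - rows[0] + 1 == span
        assert cols[-1] - cols[0] + 1 == span

    def test_even_kernel_same_padding_rejected(self):
        with pytest.raises(ValueError):
            dilated_conv2d(np.zeros((1, 4, 4)), np.zeros((1, 1, 2, 2)), rate=1)


def _numeric_grad(f, x, eps=1e-3):
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


class TestLayerGradients:
    """Backprop of each layer agrees with central finite differences."""

    def _check(self, layer, x, train=True, atol=2e-3):
        rng = np.random.default_rng(0)
        y = layer.forward(x, train=train)
        dy = rng.standard_normal(y.shape)

        def loss():
            return float((layer.forward(x, train=train) * dy).sum())

        for _, p in layer.params():
            p.grad[...] = 0.0
        dx = layer.backward(dy)
        num_dx = _numeric_grad(loss, x)
        np.testing.assert_allclose(dx, num_dx, atol=atol)
        for _, p in layer.params():
            num = _numeric_grad(loss, p.value)
            np.testing.assert_allclose(p.grad, num, atol=atol)

    def test_conv_stride_dilation(self):
        rng = np.random.default_rng(3)
        layer = nn.Conv2d(2, 3, kernel=3, stride=2, dilation=2, rng=rng)
        self._check(layer, rng.standard_normal((2, 2, 7, 7)).astype(np.float64))

    def test_batchnorm_train_mode(self):
        rng = np.random.default_rng(4)
        layer = nn.BatchNorm2d(3)
        layer.gamma.value[...] = rng.uniform(0.5, 1.5, 3)
        self._check(layer, rng.standard_normal((3, 3, 4, 4)).astype(np.float32),
                    atol=5e-3)

    def test_linear_and_upsample(self):
        rng = np.random.default_rng(5)
        self._check(nn.Linear(4, 3, rng=rng),
                    rng.standard_normal((5, 4)).astype(np.float64))
        self._check(nn.BilinearUpsample((6, 6)),
                    rng.standard_normal((2, 2, 3, 3)).astype(np.float64))


def test_bilinear_matrix_is_row_stochastic_and_exact_on_constants():
    a = nn._bilinear_matrix(10, 4)
    np.testing.assert_allclose(a.sum(axis=1), 1.0, atol=1e-12)
    up = nn.BilinearUpsample((9, 9))
    out = up.forward(np.full((1, 1, 4, 4), 3.5))
    np.testing.assert_allclose(out, 3.5, atol=1e-12)


def test_cross_entropy_gradient_matches_probability_simplex():
    rng = np.random.default_rng(6)
    logits = rng.standard_normal((4, 3))
    y = np.array([0, 2, 1, 0])
    loss, d = nn.cross_entropy(logits, y)
    assert loss > 0
    np.testing.assert_allclose(d.sum(axis=1), 0.0, atol=1e-12)
    num = _numeric_grad(lambda: nn.cross_entropy(logits, y)[0], logits)
    np.testing.assert_allclose(d, num, atol=1e-6)
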