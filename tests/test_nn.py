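"""Gradient correctness of the hand-written autodiff engine."""

import numpy as np
import pytest

from octreport._nn import AdaDelta, Parameter, Tensor, concat, softmax_cross_entropy


def _numeric_grad(f, arr, idx, eps=1e-2):
    orig = arr[idx]
    arr[idx] = orig + eps
    lp = f()
    arr[idx] = orig - eps
    lm = f()
    arr[idx] = orig
    return (lp - lm) / (2 * eps)


def test_conv2d_gradients_match_loop_reference():
    rng = np.random.default_rng(1)
    xd = rng.normal(size=(2, 3, 8, 10)).astype(np.float32)
    wd = (rng.normal(size=(5, 27)) * 0.1).astype(np.float32)
    bd = (rng.normal(size=5) * 0.1).astype(np.float32)
    r = rng.normal(size=(2, 5, 8, 10)).astype(np.float32)

    x = Tensor(xd, requires_grad=True)
    w = Parameter(wd)
    b = Parameter(bd)
    ((x.conv2d(w, b)) * Tensor(r)).sum().backward()

    x64 = xd.astype(np.float64)
    w64 = wd.astype(np.float64).reshape(5, 3, 3, 3)
    xp = np.pad(x64, ((0, 0), (0, 0), (1, 1), (1, 1)))
    gw = np.zeros_like(w64)
    gxp = np.zeros_like(xp)
    for oc_ in range(5):
        for c in range(3):
            for i in range(3):
                for j in range(3):
                    gw[oc_, c, i, j] = (r[:, oc_] * xp[:, c, i:i + 8, j:j + 10]).sum()
                    gxp[:, c, i:i + 8, j:j + 10] += w64[oc_, c, i, j] * r[:, oc_]
    assert np.allclose(w.grad, gw.reshape(5, 27), atol=1e-4)
    assert np.allclose(x.grad, gxp[:, :, 1:9, 1:11], atol=1e-5)
    assert np.allclose(b.grad, r.sum(axis=(0, 2, 3)), atol=1e-4)


@pytest.mark.parametrize("op", ["sigmoid", "tanh", "relu", "softmax", "maxpool"])
def test_elementwise_and_pool_gradients(op):
    rng = np.random.default_rng(7)
    xd = rng.normal(size=(3, 4, 4, 4)).astype(np.float32) * 2
    rd = rng.normal(size=(3, 4, 4, 4)).astype(np.float32)

    def forward():
        x = Tensor(xd, requires_grad=True)
        if op == "maxpool":
            y = x.maxpool2()
            return x, (y * Tensor(rd[:, :, :2, :2])).sum()
        y = getattr(x.reshape(3, 64), op)() if op == "softmax" else getattr(x, op)()
        r = Tensor(rd.reshape(3, 64)) if op == "softmax" else Tensor(rd)
        return x, (y * r).sum()

    x, loss = forward()
    loss.backward()
    flat = xd.ravel()
    # stay away from the relu kink / pooling argmax ties
    candidates = [i for i in range(flat.size) if abs(flat[i]) > 0.3][:4]
    for i in candidates:

        def f():
            _, l = forward()
            return float(l.data)

        gn = _numeric_grad(f, flat, i)
        ga = x.grad.ravel()[i]
        assert abs(gn - ga) < 5e-2 * max(1.0, abs(gn)), (op, i, gn, ga)


def test_softmax_cross_entropy_gradient_and_masking():
    rng = np.random.default_rng(3)
    zd = rng.normal(size=(4, 5)).astype(np.float32)
    targets = np.array([0, 2, 4, 1])
    weights = np.array([1.0, 1.0, 0.0, 1.0], dtype=np.float32)

    z = Tensor(zd.copy(), requires_grad=True)
    loss = softmax_cross_entropy(z, targets, weights)
    loss.backward()
    # masked row contributes no gradient
    assert np.allclose(z.grad[2], 0.0)
    flat = zd.ravel()
    for i in [0, 6, 19]:

        def f():
            z2 = Tensor(flat.reshape(4, 5), requires_grad=True)
            return float(softmax_cross_entropy(z2, targets, weights).data)

        gn = _numeric_grad(f, flat, i, eps=1e-2)
        assert abs(gn - z.grad.ravel()[i]) < 2e-3


def test_concat_matmul_broadcast_chain():
    rng = np.random.default_rng(5)
    a = Tensor(rng.normal(size=(3, 2)).astype(np.float32), requires_grad=True)
    b = Tensor(rng.normal(size=(3, 4)).astype(np.float32), requires_grad=True)
    w = Parameter(rng.normal(size=(6, 2)).astype(np.float32))
    out = (concat([a, b], axis=1) @ w + Parameter(np.zeros(2))).tanh().sum()
    out.backward()
    assert a.grad.shape == (3, 2)
    assert b.grad.shape == (3, 4)
    assert w.grad.shape == (6, 2)


def test_adadelta_reduces_quadratic():
    w = Parameter(np.array([4.0, -3.0]))
    opt = AdaDelta([w])
    for _ in range(2000):
        opt.zero_grad()
        loss = (w * w).sum()
        loss.backward()
        opt.step()
    assert float((w.data ** 2).sum()) < 0.5
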