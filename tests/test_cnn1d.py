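import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seclass.cnn1d import (
    CNNConfig,
    cnn_backward,
    cnn_forward,
    conv1d_valid,
    dimension_chain,
    fit_se1dcnn,
    init_params,
    maxpool1d,
    predict_se1dcnn,
    relu,
    squared_error_loss,
    _unpool,
)
from seclass.sample_expansion import ExpandedSet

TOY = CNNConfig(k1=2, k2=2, w1=5, w2=3, p1=2, p2=2, m6=6, seed=0)
TOY_M1 = 20  # chain 20 → 16 → 8 → 6 → 3


def toy_setup(n=3, C=2, seed=1):
    rng = np.random.default_rng(seed)
    params = init_params(TOY, TOY_M1, C, rng)
    X = rng.normal(0, 1, (n, TOY_M1))
    T = np.eye(C)[rng.integers(0, C, n)]
    return params, X, T


def test_valid_cross_correlation():
    out = conv1d_valid([1, 2, 3, 4, 5], [1, 0, -1])
    np.testing.assert_allclose(out, [-2, -2, -2])


def test_unit_kernel_is_identity():
    sig = np.array([3.0, -1.0, 2.0])
    np.testing.assert_allclose(conv1d_valid(sig, [1.0]), sig)


def test_conv_output_length_500_genes():
    out = conv1d_valid(np.zeros(500), np.zeros(21), bias=1.0)
    assert out.shape == (480,)


def test_kernel_longer_than_signal_rejected():
    with pytest.raises(ValueError):
        conv1d_valid(np.zeros(3), np.zeros(5))


def test_relu_behaviour():
    np.testing.assert_array_equal(relu(np.array([-1.0, 0.0, 2.0])), [0.0, 0.0, 2.0])
    x = np.array([0.5, 3.0])
    np.testing.assert_array_equal(relu(x), x)
    np.testing.assert_array_equal(relu(relu(np.array([-2.0, 4.0]))), relu(np.array([-2.0, 4.0])))


def test_maxpool_values_and_argmax():
    pooled, idx = maxpool1d(np.array([1.0, 3.0, 2.0, 5.0, 4.0, 0.0]), 2)
    np.testing.assert_array_equal(pooled, [3.0, 5.0, 4.0])
    np.testing.assert_array_equal(idx, [1, 1, 0])


def test_maxpool_constant_signal_and_tie_breaking():
    pooled, idx = maxpool1d(np.full(8, 2.5), 4)
    np.testing.assert_array_equal(pooled, [2.5, 2.5])
    np.testing.assert_array_equal(idx, [0, 0])  # first position wins ties


def test_maxpool_length_480_by_4():
    pooled, _ = maxpool1d(np.zeros(480), 4)
    assert pooled.shape == (120,)


def test_maxpool_requires_divisibility():
    with pytest.raises(ValueError):
        maxpool1d(np.zeros(7), 2)


def test_dimension_chain_of_the_500_gene_network():
    assert dimension_chain(500, 21, 4, 21, 4) == (480, 120, 100, 25)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    w1=st.integers(1, 10),
    p1=st.integers(1, 4),
    w2=st.integers(1, 6),
    p2=st.integers(1, 4),
    m5=st.integers(1, 8),
)
def test_dimension_chain_inverts_its_own_arithmetic(w1, p1, w2, p2, m5):
    """Any m1 built backwards through the layer formulas validates and
    reproduces the intermediate lengths."""
    m4 = m5 * p2
    m3 = m4 + w2 - 1
    m2 = m3 * p1
    m1 = m2 + w1 - 1
    assert dimension_chain(m1, w1, p1, w2, p2) == (m2, m3, m4, m5)


def test_invalid_pool_division_rejected_at_validation():
    cfg = CNNConfig(k1=2, k2=2, w1=4, w2=3, p1=4, p2=2, m6=4)
    # m2 = 20-4+1 = 17, not divisible by 4
    with pytest.raises(ValueError):
        cfg.validate(20)


def test_zero_network_outputs_half():
    params, X, _ = toy_setup()
    for arr in params.tensors().values():
        arr[...] = 0.0
    y, _ = cnn_forward(params, X, TOY)
    np.testing.assert_allclose(y, 0.5)


def test_forward_matches_straight_line_oracle():
    """Nested-loop forward pass (no vectorization) agrees to 1e-12."""
    params, X, _ = toy_setup(n=2)
    y, _ = cnn_forward(params, X, TOY)
    m2, m3, m4, m5 = dimension_chain(TOY_M1, TOY.w1, TOY.p1, TOY.w2, TOY.p2)
    for n in range(X.shape[0]):
        x = X[n]
        c1 = np.zeros((TOY.k1, m2))
        for k in range(TOY.k1):
            for t in range(m2):
                c1[k, t] = max(
                    0.0, sum(params.K1[k, j] * x[t + j] for j in range(TOY.w1)) + params.b1[k]
                )
        p1 = np.zeros((TOY.k1, m3))
        for k in range(TOY.k1):
            for t in range(m3):
                p1[k, t] = max(c1[k, t * TOY.p1 : (t + 1) * TOY.p1])
        c2 = np.zeros((TOY.k2, m4))
        for k in range(TOY.k2):
            for t in range(m4):
                acc = params.b2[k]
                for c in range(TOY.k1):
                    for j in range(TOY.w2):
                        acc += params.K2[k, c, j] * p1[c, t + j]
                c2[k, t] = max(0.0, acc)
        p2 = np.zeros((TOY.k2, m5))
        for k in range(TOY.k2):
            for t in range(m5):
                p2[k, t] = max(c2[k, t * TOY.p2 : (t + 1) * TOY.p2])
        flat = p2.reshape(-1)
        fc = np.maximum(0.0, params.W_fc @ flat + params.b_fc)
        logits = params.W_out @ fc + params.b_out
        expected = 1.0 / (1.0 + np.exp(-logits))
        np.testing.assert_allclose(y[n], expected, atol=1e-12)


def test_squared_error_loss_values():
    assert squared_error_loss([1.0, 0.0], [1.0, 0.0]) == 0.0
    assert squared_error_loss([1.0, 0.0], [0.0, 0.0]) == pytest.approx(0.5)
    assert squared_error_loss([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        squared_error_loss([1.0], [1.0, 0.0])


def test_gradients_match_finite_differences():
    params, X, T = toy_setup(n=3)
    _, cache = cnn_forward(params, X, TOY)
    grads = cnn_backward(params, cache, T, TOY)
    eps = 1e-5
    for name, arr in params.tensors().items():
        num = np.zeros_like(arr)
        for idx in np.ndindex(arr.shape):
            orig = arr[idx]
            arr[idx] = orig + eps
            cp = squared_error_loss(T, cnn_forward(params, X, TOY)[0])
            arr[idx] = orig - eps
            cm = squared_error_loss(T, cnn_forward(params, X, TOY)[0])
            arr[idx] = orig
            num[idx] = (cp - cm) / (2 * eps)
        rel = np.abs(num - grads[name]).max() / max(np.abs(num).max(), 1e-12)
        assert rel < 1e-5, name


def test_perfect_output_gives_zero_gradients():
    """With targets equal to the network output, every sensitivity vanishes."""
    params, X, _ = toy_setup(n=2)
    y, cache = cnn_forward(params, X, TOY)
    grads = cnn_backward(params, cache, y, TOY)
    for name, g in grads.items():
        np.testing.assert_allclose(g, 0.0, atol=1e-15, err_msg=name)


def test_unpool_conserves_delta_mass():
    """The routed deltas entering each pool window sum to the pooled delta."""
    rng = np.random.default_rng(0)
    delta = rng.normal(size=(3, 2, 5))
    idx = rng.integers(0, 4, size=(3, 2, 5))
    routed = _unpool(delta, idx, 4)
    windows = routed.reshape(3, 2, 5, 4)
    np.testing.assert_allclose(windows.sum(axis=-1), delta, atol=1e-15)


def _toy_expanded(n=30, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, TOY_M1))
    labels = (np.arange(n) % 2) + 1
    X[labels == 1, :5] += 1.5
    return ExpandedSet(
        values=X,
        labels=labels,
        source_sample=[f"s{i}" for i in range(n)],
        corrupted_indices=[np.array([], dtype=int)] * n,
    )


def test_training_loss_decreases():
    es = _toy_expanded()
    cfg = CNNConfig(k1=2, k2=2, w1=5, w2=3, p1=2, p2=2, m6=6,
                    learning_rate=0.5, epochs=30, seed=0)
    model = fit_se1dcnn(es, cfg, C=2)
    assert model.loss_history[-1] < model.loss_history[0]


def test_zero_learning_rate_step_leaves_parameters_unchanged():
    es = _toy_expanded()
    cfg = CNNConfig(k1=2, k2=2, w1=5, w2=3, p1=2, p2=2, m6=6,
                    learning_rate=0.0, epochs=3, seed=4)
    model = fit_se1dcnn(es, cfg, C=2)
    fresh = init_params(cfg, TOY_M1, 2, np.random.default_rng(4))
    for name, arr in model.params.tensors().items():
        np.testing.assert_array_equal(arr, fresh.tensors()[name])


def test_breast_table_configuration_accepted():
    cfg = CNNConfig(k1=11, k2=5, w1=21, w2=21, p1=4, p2=4)
    assert cfg.validate(500) == (480, 120, 100, 25)


def test_prediction_labels_and_dimension_check():
    es = _toy_expanded()
    cfg = CNNConfig(k1=2, k2=2, w1=5, w2=3, p1=2, p2=2, m6=6,
                    learning_rate=0.5, epochs=10, seed=1)
    model = fit_se1dcnn(es, cfg, C=2)
    pred = predict_se1dcnn(model, es.values[:5])
    assert set(pred.tolist()) <= {1, 2}
    with pytest.raises(ValueError):
        predict_se1dcnn(model, es.values[:, :10])
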