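import numpy as np
import pytest

from thorbfnn.metrics import compute_metrics
from thorbfnn.rbf_core import (
    RBFModel,
    TrainConfig,
    closed_form_weights,
    forward,
    interpolation_matrix,
    load_model,
    rmse_loss,
    save_model,
    train,
)


def naive_forward(X, centers, gamma, weights):
    """Straight double-loop evaluation of the network definition."""
    X, centers = np.atleast_2d(X), np.atleast_2d(centers)
    out = np.zeros(X.shape[0])
    for i in range(X.shape[0]):
        for j in range(centers.shape[0]):
            dist2 = np.sum((X[i] - centers[j]) ** 2)
            out[i] += weights[j] * np.exp(-gamma * dist2)
    return out


# ---------------------------------------------------------------------------
# interpolation matrix and forward pass


def test_activation_is_one_at_the_center():
    G = interpolation_matrix([[1.0, 2.0]], [[1.0, 2.0]], gamma=3.7)
    assert G[0, 0] == pytest.approx(1.0)


def test_activation_hand_value():
    G = interpolation_matrix([[0.0, 0.0]], [[1.0, 0.0]], gamma=1.0)
    assert G[0, 0] == pytest.approx(np.exp(-1.0))


def test_activation_decays_monotonically_in_gamma():
    vals = [
        interpolation_matrix([[0.0]], [[2.0]], gamma=g)[0, 0] for g in (0.1, 1.0, 10.0)
    ]
    assert vals[0] > vals[1] > vals[2] > 0


def test_activation_entries_in_unit_interval(rng):
    G = interpolation_matrix(rng.normal(size=(20, 3)), rng.normal(size=(5, 3)), 0.3)
    assert np.all(G > 0) and np.all(G <= 1)


def test_dimension_mismatch_raises():
    with pytest.raises(ValueError, match="dimension"):
        interpolation_matrix(np.zeros((3, 2)), np.zeros((4, 3)), 1.0)


def test_forward_hand_value():
    m = RBFModel(
        centers=[[0.0, 0.0], [1.0, 0.0]], gamma=1.0, weights=[1.0, 2.0],
        feature_names=["a", "b"],
    )
    assert forward(m, [[0.0, 0.0]])[0] == pytest.approx(1 + 2 * np.exp(-1))


def test_forward_single_unit_at_center_returns_weight():
    m = RBFModel(centers=[[2.0]], gamma=5.0, weights=[3.25], feature_names=["a"])
    assert forward(m, [[2.0]])[0] == pytest.approx(3.25)


def test_forward_zero_weights_zero_output(rng):
    m = RBFModel(centers=rng.normal(size=(4, 2)), gamma=0.2,
                 weights=np.zeros(4), feature_names=["a", "b"])
    assert np.all(forward(m, rng.normal(size=(10, 2))) == 0)


def test_forward_matches_naive_double_loop(rng):
    for _ in range(50):
        n, d, k = rng.integers(1, 51), rng.integers(1, 6), rng.integers(1, 11)
        X = rng.normal(size=(n, d))
        C = rng.normal(size=(k, d))
        w = rng.normal(size=k)
        gamma = rng.uniform(0.05, 0.5)
        m = RBFModel(centers=C, gamma=gamma, weights=w,
                     feature_names=[f"f{i}" for i in range(d)])
        np.testing.assert_allclose(
            forward(m, X), naive_forward(X, C, gamma, w), atol=1e-8
        )


def test_prediction_invariant_under_joint_permutation(rng):
    C, w = rng.normal(size=(6, 2)), rng.normal(size=6)
    X = rng.normal(size=(15, 2))
    perm = rng.permutation(6)
    m1 = RBFModel(centers=C, gamma=0.3, weights=w, feature_names=["a", "b"])
    m2 = RBFModel(centers=C[perm], gamma=0.3, weights=w[perm], feature_names=["a", "b"])
    # identical up to the non-associativity of float summation
    np.testing.assert_allclose(forward(m1, X), forward(m2, X), rtol=0, atol=1e-12)


# ---------------------------------------------------------------------------
# loss


@pytest.mark.parametrize(
    "y,yhat,expected",
    [
        ([1.0, 2.0], [1.0, 2.0], 0.0),
        ([0.0, 0.0], [1.0, 1.0], 1.0),
        ([1.0, 2.0, 3.0], [1.0, 2.0, 4.0], np.sqrt(1 / 3)),
    ],
)
def test_rmse_loss_values(y, yhat, expected):
    assert rmse_loss(y, yhat) == pytest.approx(expected)


def test_rmse_squared_is_the_metrics_mse(rng):
    y, yh = rng.normal(size=60), rng.normal(size=60)
    assert rmse_loss(y, yh) ** 2 == pytest.approx(
        compute_metrics(y, yh).mse, rel=1e-12
    )


# ---------------------------------------------------------------------------
# closed-form oracle


def test_closed_form_identity_system():
    w = closed_form_weights(np.eye(3), [1.0, 2.0, 3.0])
    np.testing.assert_allclose(w, [1.0, 2.0, 3.0])


def test_closed_form_exact_system(rng):
    G = interpolation_matrix(rng.normal(size=(8, 2)), rng.normal(size=(3, 2)), 0.3)
    wstar = rng.normal(size=3)
    w = closed_form_weights(G, G @ wstar)
    assert rmse_loss(G @ w, G @ wstar) == pytest.approx(0.0, abs=1e-9)


def test_closed_form_beats_random_perturbations(rng):
    G = rng.normal(size=(30, 5))
    y = rng.normal(size=30)
    w = closed_form_weights(G, y)
    base = np.linalg.norm(G @ w - y)
    for _ in range(25):
        wp = w + rng.normal(0, 0.1, size=5)
        assert base <= np.linalg.norm(G @ wp - y) + 1e-12


# ---------------------------------------------------------------------------
# training


def _recovery_problem(rng, n=120, k=6, noise=0.0):
    X = rng.normal(size=(n, 2))
    C = rng.normal(size=(k, 2)) * 2.0  # well-separated centers
    G = interpolation_matrix(X, C, 0.3)
    wstar = rng.normal(size=k)
    y = G @ wstar + (rng.normal(0, noise, size=n) if noise else 0.0)
    m = RBFModel(centers=C, gamma=0.3, weights=np.zeros(k),
                 feature_names=["a", "b"])
    return m, X, y, G


def test_trained_rmse_approaches_least_squares_oracle(rng):
    m, X, y, G = _recovery_problem(rng)
    fitted, hist = train(m, X, y, TrainConfig(seed=1))
    ls = rmse_loss(y, G @ closed_form_weights(G, y))
    assert rmse_loss(y, forward(fitted, X)) <= ls + 1e-3
    assert hist.final_loss <= hist.initial_loss


def test_zero_epochs_is_a_noop(rng):
    m, X, y, _ = _recovery_problem(rng)
    fitted, hist = train(m, X, y, TrainConfig(max_epochs=0, seed=3))
    assert hist.losses == []
    # weights equal the seeded initialization, untouched by any update
    init = np.random.default_rng(3).normal(0.0, 0.1, size=m.k)
    np.testing.assert_array_equal(fitted.weights, init)


def test_training_is_deterministic_given_seed(rng):
    m, X, y, _ = _recovery_problem(rng, noise=0.05)
    cfg = TrainConfig(max_epochs=200, seed=11)
    f1, _ = train(m, X, y, cfg)
    f2, _ = train(m, X, y, cfg)
    np.testing.assert_array_equal(f1.weights, f2.weights)


def test_best_epoch_weights_are_retained(rng):
    m, X, y, G = _recovery_problem(rng, noise=0.05)
    fitted, hist = train(m, X, y, TrainConfig(max_epochs=300, seed=5))
    assert rmse_loss(y, forward(fitted, X)) == pytest.approx(min(hist.losses))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(optimizer_decay=1.5)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-1)


# ---------------------------------------------------------------------------
# serialization


def test_model_roundtrip(tmp_path, rng):
    m = RBFModel(
        centers=rng.normal(size=(4, 3)), gamma=0.21, weights=rng.normal(size=4),
        feature_names=["Mass", "Tarsus.Length", "Sex"],
        scale_tags={"Mass": "log", "Tarsus.Length": "log"},
        encoding={"Sex": {"F": 0, "M": 1}},
    )
    p = tmp_path / "model.json"
    save_model(m, p)
    back = load_model(p)
    np.testing.assert_allclose(back.centers, m.centers)
    np.testing.assert_allclose(back.weights, m.weights)
    assert back.gamma == m.gamma
    assert back.feature_names == m.feature_names
    assert back.encoding == m.encoding
    X = rng.normal(size=(5, 3))
    np.testing.assert_allclose(forward(back, X), forward(m, X))


def test_load_rejects_unknown_schema(tmp_path):
    p = tmp_path / "bad.json"
    p.write_text('{"schema": "other/9"}')
    with pytest.raises(ValueError, match="schema"):
        load_model(p)
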