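"""Recurrent network mechanics: topology, gradients, training protocol."""

import numpy as np
import pytest

from asthmacast.nets import (
    HyperConfig,
    PatienceTracker,
    TrainSpec,
    build_model,
    predict,
    train,
)
from asthmacast.preprocess import WindowSet

CELLS = ["simple_recurrent", "lstm", "gru"]


def _windows(n=40, t=5, f=6, seed=0, target="linear"):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, t, f))
    if target == "linear":
        y = X[:, -1, 0] + 0.5 * X[:, -2, 1]
    elif target == "lag4":
        y = X[:, 0, 0]  # driven by the oldest step only
    else:
        y = rng.normal(size=n)
    ids = tuple((2015, i + 1) for i in range(n))
    return WindowSet(X=X, y=y, week_ids=ids)


class TestBuildModel:
    @pytest.mark.parametrize("cell", CELLS)
    def test_dense_param_count_formula(self, cell):
        cfg = HyperConfig(cell, 7, 5, 3)
        m = build_model(cfg, n_features=6)
        actual = sum(m.params[k].size for k in ("W1", "b1", "W2", "b2", "W3", "b3"))
        assert actual == cfg.dense_param_count == (7 + 1) * 5 + (5 + 1) * 3 + (3 + 1)

    def test_identical_dense_stacks_across_cells(self):
        models = [build_model(HyperConfig(c, 8, 6, 4), n_features=6, seed=3) for c in CELLS]
        for other in models[1:]:
            for k in ("W1", "W2", "W3"):
                assert np.array_equal(models[0].params[k], other.params[k])

    @pytest.mark.parametrize("cell", CELLS)
    def test_deterministic_forward_without_dropout(self, cell):
        w = _windows()
        m = build_model(HyperConfig(cell, 4, 4, 3), n_features=6, seed=1)
        assert np.array_equal(m.predict(w.X), m.predict(w.X))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            HyperConfig("lstm", 0, 4, 3)
        with pytest.raises(ValueError):
            HyperConfig("transformer", 4, 4, 3)
        with pytest.raises(ValueError):
            HyperConfig("lstm", 4, 4, 3, (0.5, 0.5))


class TestGradients:
    @pytest.mark.parametrize("cell", CELLS)
    def test_backward_matches_finite_differences(self, cell):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 5, 4))
        y = rng.normal(size=5)
        m = build_model(HyperConfig(cell, 3, 4, 3), n_features=4, seed=2)
        pred, cache = m.forward(X)
        grads = m.backward(2.0 * (pred - y) / len(y), cache)

        def loss_and_pattern():
            out, c = m.forward(X)
            pattern = (np.sign(c["a1"]), np.sign(c["a2"]))
            return float(np.mean((out - y) ** 2)), pattern

        eps = 1e-6
        checked = 0
        for k, p in m.params.items():
            g = np.asarray(grads[k]).reshape(p.shape)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                old = p[i]
                p[i] = old + eps
                lp, pat_p = loss_and_pattern()
                p[i] = old - eps
                lm, pat_m = loss_and_pattern()
                p[i] = old
                # a perturbation that flips a ReLU activation pattern makes
                # the central difference invalid at the kink — skip it
                if any(not np.array_equal(a, b) for a, b in zip(pat_p, pat_m)):
                    continue
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[i]) < 1e-4 * max(1.0, abs(num)), (k, i)
                checked += 1
        assert checked > 50  # the check must actually exercise the gradients


class TestPatienceTracker:
    def test_stops_exactly_patience_after_minimum(self):
        tr = PatienceTracker(50)
        stops = []
        seq = [10.0 - i for i in range(20)] + [5.0] * 100  # min at epoch 20
        for mse in seq:
            if tr.update(mse):
                stops.append(tr.epoch)
                break
        assert stops == [70]  # 20 + 50
        assert tr.best_epoch == 20

    def test_plateau_from_start(self):
        tr = PatienceTracker(3)
        assert [tr.update(1.0) for _ in range(5)][:4] == [False, False, False, True]

    def test_improvement_resets_counter(self):
        tr = PatienceTracker(2)
        assert not tr.update(5.0)
        assert not tr.update(5.0)
        assert not tr.update(4.0)  # strict improvement resets
        assert not tr.update(4.0)
        assert tr.update(4.0)


class TestTrain:
    def test_patience_beyond_max_epochs_runs_to_max(self):
        w = _windows()
        m = build_model(HyperConfig("lstm", 4, 4, 3), n_features=6, seed=1)
        spec = TrainSpec(max_epochs=15, patience_epochs=1000, seed=1)
        tr = train(m, w, w, spec)
        assert tr.stopping_epoch == 15
        assert len(tr.history) == 15

    def test_seeded_history_reproducible(self):
        w = _windows()
        spec = TrainSpec(max_epochs=20, seed=5)
        hists = []
        for _ in range(2):
            m = build_model(HyperConfig("gru", 4, 4, 3, (0.2,) * 4), n_features=6, seed=5)
            hists.append(train(m, w, w, spec).history)
        assert hists[0].equals(hists[1])

    def test_restore_best_contract(self):
        w = _windows()
        mon = _windows(seed=9)
        m = build_model(HyperConfig("lstm", 6, 6, 4), n_features=6, seed=2)
        spec = TrainSpec(max_epochs=120, patience_epochs=25, seed=2)
        tr = train(m, w, mon, spec)
        refit_mse = float(np.mean((m.predict(mon.X) - mon.y) ** 2))
        assert refit_mse == pytest.approx(tr.history["monitor_mse"].min(), rel=1e-12)
        assert tr.best_epoch == int(tr.history["monitor_mse"].idxmin()) + 1

    def test_nan_loss_reports_epoch(self):
        w = _windows()
        m = build_model(HyperConfig("simple_recurrent", 4, 4, 3), n_features=6, seed=1)
        m.params["W3"][:] = 1e200  # force overflow in the first forward pass
        spec = TrainSpec(max_epochs=10, seed=1)
        with pytest.raises(FloatingPointError, match="epoch"):
            train(m, w, w, spec)

    def test_empty_windows_rejected(self):
        w = _windows()
        empty = WindowSet(X=w.X[:0], y=w.y[:0], week_ids=())
        m = build_model(HyperConfig("lstm", 4, 4, 3), n_features=6)
        with pytest.raises(ValueError):
            train(m, empty, w, TrainSpec())


class TestPredict:
    def _trained(self, dropout=0.0):
        w = _windows()
        m = build_model(HyperConfig("lstm", 4, 4, 3, (dropout,) * 4), n_features=6, seed=1)
        return train(m, w, w, TrainSpec(max_epochs=30, seed=1)), w

    def test_inference_is_deterministic_even_with_dropout_config(self):
        tr, w = self._trained(dropout=0.3)
        assert np.array_equal(predict(tr, w), predict(tr, w))

    def test_output_length(self):
        tr, w = self._trained()
        assert len(predict(tr, w)) == len(w)

    def test_learns_constant_target(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5, 4))
        y = np.full(60, 0.5)
        w = WindowSet(X=X, y=y, week_ids=tuple((2015, i) for i in range(60)))
        m = build_model(HyperConfig("lstm", 4, 4, 3), n_features=4, seed=3)
        tr = train(m, w, w, TrainSpec(max_epochs=150, seed=3))
        pred = predict(tr, w)
        assert pred.var() < 0.01 * abs(y.mean())


def test_checkpoint_round_trip(tmp_path):
    from asthmacast.nets import load_weights, save_weights

    w = _windows()
    m = build_model(HyperConfig("gru", 4, 4, 3), n_features=6, seed=1)
    tr = train(m, w, w, TrainSpec(max_epochs=20, seed=1))
    path = tmp_path / "weights.npz"
    save_weights(tr, path)
    fresh = build_model(HyperConfig("gru", 4, 4, 3), n_features=6, seed=99)
    load_weights(fresh, path)
    assert np.array_equal(fresh.predict(w.X), m.predict(w.X))
    wrong = build_model(HyperConfig("gru", 5, 4, 3), n_features=6)
    with pytest.raises(ValueError):
        load_weights(wrong, path)


def test_five_week_window_carries_lag_signal():
    """An LSTM on 5-step windows beats the same architecture on 1-step
    windows when the target depends only on the week four steps back."""
    rng = np.random.default_rng(4)
    X = rng.normal(size=(120, 5, 4))
    y = X[:, 0, 0].copy()  # lag-4 driver
    ids = tuple((2015, i) for i in range(120))
    w5 = WindowSet(X=X, y=y, week_ids=ids)
    w1 = WindowSet(X=X[:, -1:, :], y=y, week_ids=ids)
    test = slice(80, 120)
    mses = {}
    for name, w in (("w5", w5), ("w1", w1)):
        wtr = WindowSet(w.X[:80], w.y[:80], w.week_ids[:80])
        wte = WindowSet(w.X[test], w.y[test], w.week_ids[test])
        m = build_model(HyperConfig("lstm", 8, 8, 4), n_features=4, seed=4)
        tr = train(m, wtr, wte, TrainSpec(max_epochs=200, seed=4))
        mses[name] = float(np.mean((predict(tr, wte) - wte.y) ** 2))
    assert mses["w5"] < mses["w1"]
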