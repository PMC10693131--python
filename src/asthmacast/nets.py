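"""Recurrent regression networks for weekly count forecasting.

Topology is fixed to four layers: one recurrent input layer (simple RNN,
LSTM, or GRU cell) reading a (time_steps, n_features) window and emitting
only its final-step state, followed by two fully connected ReLU hidden
layers and a single linear output unit. Dropout is applied at all four
layers (on the window tensor and on each layer's activations). Training is
full-batch Adam on the mean squared error of the min-max-scaled target,
with patience-based early stopping on a monitored window set and
restoration of the best-epoch weights.

All forward/backward passes are implemented directly in numpy; gradients
are exact (verified against finite differences in the test suite).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import WindowSet

__all__ = ["HyperConfig", "TrainSpec", "RecurrentRegressor", "TrainedModel",
           "build_model", "train", "predict"]

CELL_TYPES = ("simple_recurrent", "lstm", "gru")


@dataclass(frozen=True)
class HyperConfig:
    """One candidate network configuration."""

    cell_type: str
    recurrent_units: int
    hidden1_units: int
    hidden2_units: int
    dropout_rates: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        if min(self.recurrent_units, self.hidden1_units, self.hidden2_units) < 1:
            raise ValueError("layer sizes must be >= 1")
        if len(self.dropout_rates) != 4:
            raise ValueError("exactly 4 dropout rates (one per layer)")
        if not all(0.0 <= r < 1.0 for r in self.dropout_rates):
            raise ValueError("dropout rates must be in [0, 1)")

    @property
    def dense_param_count(self) -> int:
        h, h1, h2 = self.recurrent_units, self.hidden1_units, self.hidden2_units
        return (h + 1) * h1 + (h1 + 1) * h2 + (h2 + 1)


@dataclass(frozen=True)
class TrainSpec:
    """The fixed training protocol: Adam at learning rate 0.004, early
    stopping when the monitored MSE has not improved for 50 epochs."""

    learning_rate: float = 0.004
    patience_epochs: int = 50
    max_epochs: int = 1000
    batch_size: int = 32
    monitor: str = "test"  # "test" or "validation_tail"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class RecurrentRegressor:
    """A 4-layer recurrent network with hand-written forward/backward passes."""

    def __init__(self, config: HyperConfig, n_features: int = 22,
                 time_steps: int = 5, seed: int = 0):
        self.config = config
        self.n_features = n_features
        self.time_steps = time_steps
        # separate streams so the dense stack is identical across cell types
        rng_cell = np.random.default_rng([seed, 11, 0])
        rng_dense = np.random.default_rng([seed, 11, 1])
        F, H = n_features, config.recurrent_units
        h1, h2 = config.hidden1_units, config.hidden2_units
        G = {"simple_recurrent": 1, "lstm": 4, "gru": 3}[config.cell_type]
        p = {
            "Wx": _glorot(rng_cell, F, G * H),
            "Wh": _glorot(rng_cell, H, G * H),
            "b": np.zeros(G * H),
            "W1": _glorot(rng_dense, H, h1),
            "b1": np.zeros(h1),
            "W2": _glorot(rng_dense, h1, h2),
            "b2": np.zeros(h2),
            "W3": _glorot(rng_dense, h2, 1),
            "b3": np.zeros(1),
        }
        if config.cell_type == "lstm":
            p["b"][H : 2 * H] = 1.0  # forget-gate bias
        self.params = p

    # -- recurrent cells ----------------------------------------------------

    def _cell_forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        N, T, _ = X.shape
        H = self.config.recurrent_units
        p = self.params
        h = np.zeros((N, H))
        cache: dict = {"h": [h], "X": X}
        if self.config.cell_type == "simple_recurrent":
            for t in range(T):
                h = np.tanh(X[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"])
                cache["h"].append(h)
        elif self.config.cell_type == "lstm":
            c = np.zeros((N, H))
            cache.update(c=[c], gates=[])
            for t in range(T):
                a = X[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
                i = _sigmoid(a[:, :H])
                f = _sigmoid(a[:, H : 2 * H])
                g = np.tanh(a[:, 2 * H : 3 * H])
                o = _sigmoid(a[:, 3 * H :])
                c = f * c + i * g
                h = o * np.tanh(c)
                cache["gates"].append((i, f, g, o))
                cache["c"].append(c)
                cache["h"].append(h)
        else:  # gru
            cache["gates"] = []
            for t in range(T):
                a = X[:, t] @ p["Wx"] + p["b"]
                rec = h @ p["Wh"]
                z = _sigmoid(a[:, :H] + rec[:, :H])
                r = _sigmoid(a[:, H : 2 * H] + rec[:, H : 2 * H])
                rh = r * h
                n = np.tanh(a[:, 2 * H :] + rh @ self._Whn())
                h_new = (1.0 - z) * n + z * h
                cache["gates"].append((z, r, n, h, rh))
                cache["h"].append(h_new)
                h = h_new
        return h, cache

    def _Whn(self) -> np.ndarray:
        H = self.config.recurrent_units
        return self.params["Wh"][:, 2 * H :]

    def _cell_backward(self, dh_last: np.ndarray, cache: dict, grads: dict) -> None:
        p = self.params
        X = cache["X"]
        T = X.shape[1]
        H = self.config.recurrent_units
        dWx = np.zeros_like(p["Wx"])
        dWh = np.zeros_like(p["Wh"])
        db = np.zeros_like(p["b"])
        dh = dh_last
        if self.config.cell_type == "simple_recurrent":
            for t in range(T - 1, -1, -1):
                h_t, h_prev = cache["h"][t + 1], cache["h"][t]
                da = dh * (1.0 - h_t * h_t)
                dWx += X[:, t].T @ da
                dWh += h_prev.T @ da
                db += da.sum(axis=0)
                dh = da @ p["Wh"].T
        elif self.config.cell_type == "lstm":
            dc = np.zeros_like(dh)
            for t in range(T - 1, -1, -1):
                i, f, g, o = cache["gates"][t]
                c_t, c_prev = cache["c"][t + 1], cache["c"][t]
                h_prev = cache["h"][t]
                tc = np.tanh(c_t)
                do = dh * tc
                dc = dc + dh * o * (1.0 - tc * tc)
                di, df, dg = dc * g, dc * c_prev, dc * i
                da = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f),
                     dg * (1 - g * g), do * o * (1 - o)], axis=1)
                dWx += X[:, t].T @ da
                dWh += h_prev.T @ da
                db += da.sum(axis=0)
                dh = da @ p["Wh"].T
                dc = dc * f
        else:  # gru
            Whz, Whr, Whn = p["Wh"][:, :H], p["Wh"][:, H : 2 * H], self._Whn()
            for t in range(T - 1, -1, -1):
                z, r, n, h_prev, rh = cache["gates"][t]
                dn = dh * (1.0 - z)
                dz = dh * (h_prev - n)
                dh_prev = dh * z
                dan = dn * (1.0 - n * n)
                dWx[:, 2 * H :] += X[:, t].T @ dan
                dWh[:, 2 * H :] += rh.T @ dan
                db[2 * H :] += dan.sum(axis=0)
                drh = dan @ Whn.T
                dr = drh * h_prev
                dh_prev = dh_prev + drh * r
                daz = dz * z * (1.0 - z)
                dar = dr * r * (1.0 - r)
                dWx[:, :H] += X[:, t].T @ daz
                dWx[:, H : 2 * H] += X[:, t].T @ dar
                dWh[:, :H] += h_prev.T @ daz
                dWh[:, H : 2 * H] += h_prev.T @ dar
                db[:H] += daz.sum(axis=0)
                db[H : 2 * H] += dar.sum(axis=0)
                dh = dh_prev + daz @ Whz.T + dar @ Whr.T
        grads["Wx"], grads["Wh"], grads["b"] = dWx, dWh, db

    # -- full network -------------------------------------------------------

    def forward(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None):
        """Forward pass; with a dropout RNG, inverted-dropout masks are drawn
        per call (training mode), otherwise dropout is disabled (inference)."""
        p = self.params
        rates = self.config.dropout_rates
        masks = [None] * 4
        Xd = X
        if dropout_rng is not None and rates[0] > 0:
            masks[0] = (dropout_rng.random(X.shape) >= rates[0]) / (1 - rates[0])
            Xd = X * masks[0]
        h, cell_cache = self._cell_forward(Xd)
        hd = h
        if dropout_rng is not None and rates[1] > 0:
            masks[1] = (dropout_rng.random(h.shape) >= rates[1]) / (1 - rates[1])
            hd = h * masks[1]
        a1 = np.maximum(hd @ p["W1"] + p["b1"], 0.0)
        a1d = a1
        if dropout_rng is not None and rates[2] > 0:
            masks[2] = (dropout_rng.random(a1.shape) >= rates[2]) / (1 - rates[2])
            a1d = a1 * masks[2]
        a2 = np.maximum(a1d @ p["W2"] + p["b2"], 0.0)
        a2d = a2
        if dropout_rng is not None and rates[3] > 0:
            masks[3] = (dropout_rng.random(a2.shape) >= rates[3]) / (1 - rates[3])
            a2d = a2 * masks[3]
        out = (a2d @ p["W3"] + p["b3"]).ravel()
        cache = {"cell": cell_cache, "hd": hd, "a1": a1, "a1d": a1d,
                 "a2": a2, "a2d": a2d, "masks": masks}
        return out, cache

    def backward(self, dout: np.ndarray, cache: dict) -> dict:
        p = self.params
        masks = cache["masks"]
        grads: dict = {}
        d = dout[:, None]
        grads["W3"] = cache["a2d"].T @ d
        grads["b3"] = d.sum(axis=0)
        da2d = d @ p["W3"].T
        if masks[3] is not None:
            da2d = da2d * masks[3]
        da2 = da2d * (cache["a2"] > 0)
        grads["W2"] = cache["a1d"].T @ da2
        grads["b2"] = da2.sum(axis=0)
        da1d = da2 @ p["W2"].T
        if masks[2] is not None:
            da1d = da1d * masks[2]
        da1 = da1d * (cache["a1"] > 0)
        grads["W1"] = cache["hd"].T @ da1
        grads["b1"] = da1.sum(axis=0)
        dhd = da1 @ p["W1"].T
        if masks[1] is not None:
            dhd = dhd * masks[1]
        self._cell_backward(dhd, cache["cell"], grads)
        return grads

    def predict(self, X: np.ndarray) -> np.ndarray:
        out, _ = self.forward(X)
        return out

    def clone_weights(self) -> dict:
        return copy.deepcopy(self.params)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def build_model(config: HyperConfig, n_features: int = 22, time_steps: int = 5,
                seed: int = 0) -> RecurrentRegressor:
    """Instantiate an untrained network for (time_steps, n_features) windows."""
    return RecurrentRegressor(config, n_features=n_features,
                              time_steps=time_steps, seed=seed)


class PatienceTracker:
    """The early-stopping rule: stop once the monitored MSE has gone
    ``patience`` consecutive epochs without a strict improvement of the
    running best (no minimum-delta)."""

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best = np.inf
        self.best_epoch = 0
        self.stall = 0
        self.epoch = 0

    def update(self, mse: float) -> bool:
        """Record one epoch's monitored MSE; True means stop now."""
        self.epoch += 1
        if mse < self.best:
            self.best = mse
            self.best_epoch = self.epoch
            self.stall = 0
            return False
        self.stall += 1
        return self.stall >= self.patience


@dataclass
class TrainedModel:
    """A fitted network plus its training record.

    ``scaler``/``target`` (set by the evaluation harness) let ``predict``
    return counts on the original scale.
    """

    model: RecurrentRegressor
    config: HyperConfig
    history: pd.DataFrame  # per-epoch train and monitored MSE
    stopping_epoch: int
    best_epoch: int
    scaler: object | None = None
    target: str | None = None


def train(model: RecurrentRegressor, train_windows: WindowSet,
          monitor_windows: WindowSet, spec: TrainSpec) -> TrainedModel:
    """Minibatch Adam training with patience-based early stopping.

    Each epoch shuffles the training windows and takes one Adam step per
    minibatch. Monitored MSE is computed with dropout disabled after each
    epoch; when it fails to strictly improve for ``patience_epochs``
    consecutive epochs (or ``max_epochs`` is reached) training stops and the
    best-epoch weights are restored. A NaN loss aborts with the offending
    epoch.
    """
    if len(train_windows) == 0 or len(monitor_windows) == 0:
        raise ValueError("empty window set")
    Xtr, ytr = train_windows.X, train_windows.y
    Xmon, ymon = monitor_windows.X, monitor_windows.y
    rng = np.random.default_rng([spec.seed, 23])
    lr, b1, b2, eps = spec.learning_rate, 0.9, 0.999, 1e-8
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in model.params.items()}
    use_dropout = any(r > 0 for r in model.config.dropout_rates)
    n = len(ytr)
    batch = min(spec.batch_size, n)

    tracker = PatienceTracker(spec.patience_epochs)
    best_weights = model.clone_weights()
    history = []
    step = 0
    epoch = 0
    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(n)
        epoch_sse = 0.0
        for lo in range(0, n, batch):
            idx = order[lo : lo + batch]
            pred, cache = model.forward(
                Xtr[idx], dropout_rng=rng if use_dropout else None)
            resid = pred - ytr[idx]
            with np.errstate(over="ignore"):  # divergence is caught below
                sse = float(np.sum(resid**2))
            if not np.isfinite(sse):
                raise FloatingPointError(f"NaN/inf training loss at epoch {epoch}")
            epoch_sse += sse
            grads = model.backward(2.0 * resid / len(idx), cache)
            step += 1
            for k in model.params:
                g = grads[k].reshape(model.params[k].shape)
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**step)
                vhat = v[k] / (1 - b2**step)
                model.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        train_mse = epoch_sse / n

        mon_mse = float(np.mean((model.predict(Xmon) - ymon) ** 2))
        if not np.isfinite(mon_mse):
            raise FloatingPointError(f"NaN/inf monitored loss at epoch {epoch}")
        history.append((epoch, train_mse, mon_mse))
        stop = tracker.update(mon_mse)
        if tracker.best_epoch == epoch:
            best_weights = model.clone_weights()
        if stop:
            break

    model.params = best_weights
    hist = pd.DataFrame(history, columns=["epoch", "train_mse", "monitor_mse"])
    return TrainedModel(model=model, config=model.config, history=hist,
                        stopping_epoch=epoch, best_epoch=tracker.best_epoch)


def save_weights(trained: TrainedModel, path) -> None:
    """Checkpoint the fitted weights (numpy .npz archive)."""
    np.savez(path, **trained.model.params)


def load_weights(model: RecurrentRegressor, path) -> RecurrentRegressor:
    """Restore checkpointed weights into a compatibly-built model."""
    with np.load(path) as data:
        for k in model.params:
            if model.params[k].shape != data[k].shape:
                raise ValueError(f"checkpoint shape mismatch for {k!r}")
        model.params = {k: data[k].copy() for k in model.params}
    return model


def predict(trained: TrainedModel, windows: WindowSet) -> np.ndarray:
    """Predict counts for a window set (dropout off; inverse-transformed to
    the count scale when the harness attached a scaler)."""
    out = trained.model.predict(windows.X)
    if trained.scaler is not None and trained.target is not None:
        from .preprocess import minmax_invert

        out = minmax_invert(trained.scaler, trained.target, out)
    return out
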