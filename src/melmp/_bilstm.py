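"""A small bidirectional LSTM binary classifier in NumPy.

Two opposite LSTMs read the step sequence left-to-right and right-to-left;
their per-step hidden states are concatenated, mean-pooled over time, and
fed to a logistic head. Training is full-batch Adam on the binary
cross-entropy, with optional early stopping on a held-out validation split.

Gradients are hand-derived backpropagation through time; a numerical
gradient check lives in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BiLSTMClassifier"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _init_direction(rng: np.random.Generator, d: int, h: int) -> dict[str, np.ndarray]:
    scale = 1.0 / np.sqrt(max(d + h, 1))
    p = {
        "Wx": rng.normal(0.0, scale, size=(d, 4 * h)),
        "Wh": rng.normal(0.0, scale, size=(h, 4 * h)),
        "b": np.zeros(4 * h),
    }
    p["b"][h : 2 * h] = 1.0  # forget-gate bias: remember by default
    return p


def _lstm_forward(X: np.ndarray, p: dict[str, np.ndarray]) -> tuple[np.ndarray, list]:
    """Run one direction; returns hidden states (n, T, h) and a cache."""
    n, T, _ = X.shape
    h = p["Wh"].shape[0]
    hs = np.zeros((n, T, h))
    cs = np.zeros((n, T, h))
    cache = []
    h_prev = np.zeros((n, h))
    c_prev = np.zeros((n, h))
    for t in range(T):
        z = X[:, t, :] @ p["Wx"] + h_prev @ p["Wh"] + p["b"]
        i = _sigmoid(z[:, :h])
        f = _sigmoid(z[:, h : 2 * h])
        o = _sigmoid(z[:, 2 * h : 3 * h])
        g = np.tanh(z[:, 3 * h :])
        c = f * c_prev + i * g
        tanh_c = np.tanh(c)
        ht = o * tanh_c
        hs[:, t, :] = ht
        cs[:, t, :] = c
        cache.append((i, f, o, g, c_prev, h_prev, tanh_c))
        h_prev, c_prev = ht, c
    return hs, cache


def _lstm_backward(
    X: np.ndarray,
    p: dict[str, np.ndarray],
    cache: list,
    dhs: np.ndarray,
) -> dict[str, np.ndarray]:
    """BPTT for one direction given per-step external gradients ``dhs``."""
    n, T, _ = X.shape
    h = p["Wh"].shape[0]
    grads = {k: np.zeros_like(v) for k, v in p.items()}
    dh_next = np.zeros((n, h))
    dc_next = np.zeros((n, h))
    for t in range(T - 1, -1, -1):
        i, f, o, g, c_prev, h_prev, tanh_c = cache[t]
        dh = dhs[:, t, :] + dh_next
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c**2)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
                dg * (1.0 - g**2),
            ],
            axis=1,
        )
        grads["Wx"] += X[:, t, :].T @ dz
        grads["Wh"] += h_prev.T @ dz
        grads["b"] += dz.sum(axis=0)
        dh_next = dz @ p["Wh"].T
        dc_next = dc * f
    return grads


class BiLSTMClassifier:
    """Bidirectional LSTM with mean pooling and a logistic head.

    Parameters
    ----------
    hidden : hidden width per direction.
    epochs : maximum full-batch Adam epochs.
    lr : Adam step size.
    validation_fraction : share of the training set held out for early
        stopping (0 disables it).
    patience : epochs without validation improvement before stopping.
    seed : seeds initialisation and the validation split.
    """

    def __init__(
        self,
        hidden: int = 16,
        epochs: int = 60,
        lr: float = 0.01,
        validation_fraction: float = 0.1,
        patience: int = 8,
        seed: int = 0,
    ) -> None:
        self.hidden = hidden
        self.epochs = epochs
        self.lr = lr
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.seed = seed
        self.params_: dict[str, np.ndarray] | None = None
        self.loss_curve_: list[float] = []

    # -- forward / loss ----------------------------------------------------

    def _forward(self, X: np.ndarray, params: dict) -> tuple[np.ndarray, dict]:
        hs_f, cache_f = _lstm_forward(X, params["fwd"])
        hs_b, cache_b = _lstm_forward(X[:, ::-1, :], params["bwd"])
        gf = hs_f.mean(axis=1)
        gb = hs_b.mean(axis=1)
        logit = gf @ params["wf"] + gb @ params["wb"] + params["b_out"]
        proba = _sigmoid(logit)
        aux = {
            "cache_f": cache_f,
            "cache_b": cache_b,
            "hs_f": hs_f,
            "hs_b": hs_b,
            "gf": gf,
            "gb": gb,
        }
        return proba, aux

    def loss_and_grads(
        self, params: dict, X: np.ndarray, y: np.ndarray
    ) -> tuple[float, dict]:
        """Mean binary cross-entropy and its gradient w.r.t. every parameter."""
        n, T, _ = X.shape
        proba, aux = self._forward(X, params)
        eps = 1e-12
        loss = float(
            -np.mean(y * np.log(proba + eps) + (1 - y) * np.log(1 - proba + eps))
        )
        dlogit = (proba - y) / n  # (n,)
        grads = {
            "wf": aux["gf"].T @ dlogit,
            "wb": aux["gb"].T @ dlogit,
            "b_out": np.array(dlogit.sum()),
        }
        dhs_f = dlogit[:, None, None] * params["wf"][None, None, :] / T
        dhs_f = np.broadcast_to(dhs_f, aux["hs_f"].shape)
        dhs_b = dlogit[:, None, None] * params["wb"][None, None, :] / T
        dhs_b = np.broadcast_to(dhs_b, aux["hs_b"].shape)
        grads["fwd"] = _lstm_backward(X, params["fwd"], aux["cache_f"], dhs_f)
        grads["bwd"] = _lstm_backward(
            X[:, ::-1, :], params["bwd"], aux["cache_b"], dhs_b
        )
        return loss, grads

    # -- training ----------------------------------------------------------

    def _init_params(self, d: int) -> dict:
        rng = np.random.default_rng(self.seed)
        h = self.hidden
        return {
            "fwd": _init_direction(rng, d, h),
            "bwd": _init_direction(rng, d, h),
            "wf": rng.normal(0.0, 0.1, size=h),
            "wb": rng.normal(0.0, 0.1, size=h),
            "b_out": np.array(0.0),
        }

    @staticmethod
    def _flat_items(tree: dict, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        items: list[tuple[str, np.ndarray]] = []
        for k in sorted(tree):
            v = tree[k]
            if isinstance(v, dict):
                items.extend(BiLSTMClassifier._flat_items(v, prefix + k + "/"))
            else:
                items.append((prefix + k, v))
        return items

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BiLSTMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, n_steps, step_width)")
        n, _, d = X.shape
        rng = np.random.default_rng(self.seed + 1)

        if self.validation_fraction > 0 and n >= 10:
            n_val = max(1, int(round(self.validation_fraction * n)))
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X_tr, y_tr, X_val, y_val = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
        else:
            X_tr, y_tr, X_val, y_val = X, y, None, None

        params = self._init_params(d)
        mom = {k: np.zeros_like(v) for k, v in self._flat_items(params)}
        vel = {k: np.zeros_like(v) for k, v in self._flat_items(params)}
        beta1, beta2, eps = 0.9, 0.999, 1e-8

        best_val = np.inf
        best_params = None
        stall = 0
        self.loss_curve_ = []
        for epoch in range(1, self.epochs + 1):
            loss, grads = self.loss_and_grads(params, X_tr, y_tr)
            self.loss_curve_.append(loss)
            for (key, p), (_, g) in zip(
                self._flat_items(params), self._flat_items(grads)
            ):
                mom[key] = beta1 * mom[key] + (1 - beta1) * g
                vel[key] = beta2 * vel[key] + (1 - beta2) * g**2
                mhat = mom[key] / (1 - beta1**epoch)
                vhat = vel[key] / (1 - beta2**epoch)
                p -= self.lr * mhat / (np.sqrt(vhat) + eps)
            if X_val is not None:
                pv, _ = self._forward(X_val, params)
                e = 1e-12
                val = float(
                    -np.mean(
                        y_val * np.log(pv + e) + (1 - y_val) * np.log(1 - pv + e)
                    )
                )
                if val < best_val - 1e-5:
                    best_val = val
                    best_params = {
                        k: v.copy() for k, v in self._flat_items(params)
                    }
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break

        if best_params is not None:
            for key, p in self._flat_items(params):
                p[...] = best_params[key]
        self.params_ = params
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class for each row (1-d array)."""
        if self.params_ is None:
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        proba, _ = self._forward(X, self.params_)
        return proba
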