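"""Minimal dependency-free LSTM classifier core (numpy).

A small stacked-LSTM + softmax head with weighted cross-entropy loss,
full backpropagation through time, and an Adam optimizer.  Written for
CPU desk-scale problems: a few thousand short sequences, tens of hidden
units.  All randomness (initialization, batch shuffling) flows from the
generator handed in by the caller, so training is reproducible bit for
bit under a fixed seed.

Gate layout follows the usual convention: the stacked pre-activation
``z = x@Wx + h@Wh + b`` splits into input, forget, cell and output gates
in that order; the forget-gate bias starts at 1 to ease gradient flow
early in training.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LstmNetwork", "AdamOptimizer", "softmax", "weighted_cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def weighted_cross_entropy(probs: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Mean of -w * log p_y, normalized by the total weight."""
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, 1.0)
    return float(-(w * np.log(p)).sum() / w.sum())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


class LstmNetwork:
    """Stacked LSTM -> last hidden state -> dense softmax over classes."""

    def __init__(self, n_features: int, hidden_units: int, n_layers: int,
                 n_classes: int, rng: np.random.Generator):
        self.h = hidden_units
        self.layers = n_layers
        self.params: dict[str, np.ndarray] = {}
        fan_in = n_features
        for l in range(n_layers):
            h = hidden_units
            scale_x = np.sqrt(6.0 / (fan_in + 4 * h))
            scale_h = np.sqrt(6.0 / (h + 4 * h))
            self.params[f"Wx{l}"] = rng.uniform(-scale_x, scale_x, (fan_in, 4 * h))
            self.params[f"Wh{l}"] = rng.uniform(-scale_h, scale_h, (h, 4 * h))
            b = np.zeros(4 * h)
            b[h : 2 * h] = 1.0  # forget-gate bias
            self.params[f"b{l}"] = b
            fan_in = h
        scale_o = np.sqrt(6.0 / (hidden_units + n_classes))
        self.params["Wout"] = rng.uniform(-scale_o, scale_o, (hidden_units, n_classes))
        self.params["bout"] = np.zeros(n_classes)

    # -- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray):
        """x: (batch, time, features) -> (probs, cache)."""
        B, T, _ = x.shape
        H = self.h
        cache = {"x": x, "layers": []}
        seq = x
        for l in range(self.layers):
            Wx, Wh, b = self.params[f"Wx{l}"], self.params[f"Wh{l}"], self.params[f"b{l}"]
            h_t = np.zeros((B, H))
            c_t = np.zeros((B, H))
            steps = []
            outs = np.empty((B, T, H))
            for t in range(T):
                z = seq[:, t, :] @ Wx + h_t @ Wh + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H : 2 * H])
                g = np.tanh(z[:, 2 * H : 3 * H])
                o = _sigmoid(z[:, 3 * H :])
                c_prev = c_t
                c_t = f * c_prev + i * g
                tc = np.tanh(c_t)
                h_prev = h_t
                h_t = o * tc
                outs[:, t, :] = h_t
                steps.append((i, f, g, o, c_prev, tc, h_prev))
            cache["layers"].append({"in": seq, "steps": steps, "out": outs})
            seq = outs
        logits = seq[:, -1, :] @ self.params["Wout"] + self.params["bout"]
        probs = softmax(logits)
        cache["h_last"] = seq[:, -1, :]
        cache["probs"] = probs
        return probs, cache

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        parts = [self.forward(x[i : i + batch_size])[0] for i in range(0, len(x), batch_size)]
        return np.vstack(parts) if parts else np.zeros((0, self.params["bout"].shape[0]))

    # -- backward --------------------------------------------------------

    def backward(self, cache, y: np.ndarray, w: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the weighted cross-entropy w.r.t. every parameter."""
        probs = cache["probs"]
        B, C = probs.shape
        H = self.h
        onehot = np.zeros_like(probs)
        onehot[np.arange(B), y] = 1.0
        dlogits = (probs - onehot) * (w / w.sum())[:, None]
        grads = {
            "Wout": cache["h_last"].T @ dlogits,
            "bout": dlogits.sum(axis=0),
        }
        # gradient on the top layer's output sequence: only the last step
        T = cache["layers"][0]["out"].shape[1]
        dh_seq = np.zeros((B, T, H))
        dh_seq[:, -1, :] = dlogits @ self.params["Wout"].T
        for l in reversed(range(self.layers)):
            layer = cache["layers"][l]
            Wx, Wh = self.params[f"Wx{l}"], self.params[f"Wh{l}"]
            seq_in = layer["in"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros(4 * H)
            d_in = np.zeros_like(seq_in)
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            for t in reversed(range(T)):
                i, f, g, o, c_prev, tc, h_prev = layer["steps"][t]
                dh = dh_seq[:, t, :] + dh_next
                do = dh * tc
                dc = dh * o * (1.0 - tc * tc) + dc_next
                di = dc * g
                df = dc * c_prev
                dg = dc * i
                dc_next = dc * f
                dz = np.concatenate(
                    [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
                    axis=1,
                )
                dWx += seq_in[:, t, :].T @ dz
                dWh += h_prev.T @ dz
                db += dz.sum(axis=0)
                dh_next = dz @ Wh.T
                d_in[:, t, :] = dz @ Wx.T
            grads[f"Wx{l}"] = dWx
            grads[f"Wh{l}"] = dWh
            grads[f"b{l}"] = db
            if l > 0:
                dh_seq = d_in
        return grads

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


class AdamOptimizer:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
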