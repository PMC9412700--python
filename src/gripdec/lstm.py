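"""Stacked bidirectional-LSTM sequence classifier for variable-length trials.

The network consumes angular-velocity trials directly, without warping or
padding-dependent feature extraction: two stacked bidirectional LSTM layers
(forward and backward hidden states at every step, so each encoding carries
both past and future context), each followed by layer normalization and a
ReLU; the encoder output (last valid forward state concatenated with the
backward state that has consumed the whole sequence) feeds a 30-unit ReLU
hidden layer and a softmax output over the movement classes.  Training uses
cross-entropy loss with Adam, fixed epochs, mini-batches of ragged
sequences handled by length-bucketing, right-padding and state-freezing
masks, so a trial's encoding is unaffected by padding.

The implementation is pure numpy with hand-derived backpropagation through
time; gradients are validated against numerical differentiation in the test
suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import Trial

_LN_EPS = 1e-5


@dataclass
class LstmArchitecture:
    """Widths of the network: per-layer Bi-LSTM units (per direction),
    dense hidden width, and output classes."""

    hidden_units: tuple[int, int] = (100, 100)
    dense_units: int = 30

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_units) or self.dense_units < 1:
            raise ValueError("layer widths must be positive")


@dataclass
class TrainingParams:
    """Optimization settings: Adam on cross-entropy, fixed epoch count."""

    epochs: int = 64
    mini_batch: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.mini_batch < 1 or self.learning_rate <= 0:
            raise ValueError("training parameters must be positive")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


class BiLstmClassifier:
    """Two stacked Bi-LSTM layers + layer norm/ReLU blocks + dense softmax head.

    Parameters are stored in a flat dict of numpy arrays.  Gate ordering in
    the fused weight matrices is (input, forget, cell, output); forget-gate
    biases are initialized to 1.
    """

    def __init__(self, n_channels: int, n_classes: int,
                 arch: LstmArchitecture | None = None, seed: int = 0):
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.arch = arch or LstmArchitecture()
        self.classes: list[str] | None = None
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        in_dim = n_channels
        for layer, h in enumerate(self.arch.hidden_units):
            for d in ("f", "b"):
                p[f"W{layer}{d}"] = _glorot(rng, (in_dim, 4 * h))
                p[f"U{layer}{d}"] = _glorot(rng, (h, 4 * h))
                b = np.zeros(4 * h)
                b[h:2 * h] = 1.0  # forget gate bias
                p[f"b{layer}{d}"] = b
            p[f"ln{layer}_g"] = np.ones(2 * h)
            p[f"ln{layer}_b"] = np.zeros(2 * h)
            in_dim = 2 * h
        p["Wd"] = _glorot(rng, (in_dim, self.arch.dense_units))
        p["bd"] = np.zeros(self.arch.dense_units)
        p["Wo"] = _glorot(rng, (self.arch.dense_units, n_classes))
        p["bo"] = np.zeros(n_classes)
        self.params = p

    # ------------------------------------------------------------------
    # forward / backward primitives
    # ------------------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    @staticmethod
    def _lstm_forward(X, mask, W, U, b):
        """One direction over a padded batch; finished sequences freeze state.

        X: (B, T, in); mask: (B, T).  Returns the hidden-state sequence and
        the per-step cache needed for backpropagation.
        """
        B, T, _ = X.shape
        h = U.shape[0]
        hs = np.zeros((B, h))
        cs = np.zeros((B, h))
        H = np.empty((T, B, h))
        cache = {k: np.empty((T, B, h)) for k in
                 ("i", "f", "g", "o", "tc", "c_prev", "h_prev")}
        for t in range(T):
            z = X[:, t] @ W + hs @ U + b
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c_new = f * cs + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            m = mask[:, t][:, None]
            for k, v in (("i", i), ("f", f), ("g", g), ("o", o), ("tc", tc)):
                cache[k][t] = v
            cache["c_prev"][t] = cs
            cache["h_prev"][t] = hs
            cs = m * c_new + (1 - m) * cs
            hs = m * h_new + (1 - m) * hs
            H[t] = hs
        return H.transpose(1, 0, 2), cache

    @staticmethod
    def _lstm_backward(dH, X, mask, W, U, cache):
        """Backpropagate through one direction; dH is (B, T, h) w.r.t. the
        (post-mask) hidden sequence.  Returns dX and parameter gradients."""
        B, T, _ = X.shape
        h = U.shape[0]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros(4 * h)
        dX = np.zeros_like(X)
        dh_next = np.zeros((B, h))
        dc_next = np.zeros((B, h))
        for t in range(T - 1, -1, -1):
            m = mask[:, t][:, None]
            dh = dH[:, t] + dh_next
            dc = dc_next
            dh_new = m * dh
            dc_new = m * dc
            i, f, g, o = (cache[k][t] for k in ("i", "f", "g", "o"))
            tc = cache["tc"][t]
            c_prev = cache["c_prev"][t]
            h_prev = cache["h_prev"][t]
            do = dh_new * tc
            dc_new = dc_new + dh_new * o * (1 - tc * tc)
            di = dc_new * g
            dg = dc_new * i
            df = dc_new * c_prev
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dW += X[:, t].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dX[:, t] = dz @ W.T
            dh_next = dz @ U.T + (1 - m) * dh
            dc_next = dc_new * f + (1 - m) * dc
        return dX, dW, dU, db

    @staticmethod
    def _layernorm_forward(x, gamma, beta):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + _LN_EPS)
        xhat = (x - mu) * inv
        return gamma * xhat + beta, (xhat, inv)

    @staticmethod
    def _layernorm_backward(dy, gamma, cache):
        xhat, inv = cache
        dgamma = (dy * xhat).reshape(-1, dy.shape[-1]).sum(axis=0)
        dbeta = dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        dxhat = dy * gamma
        dx = inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
        return dx, dgamma, dbeta

    @staticmethod
    def _reverse_padded(X, lengths):
        """Reverse each sequence within its valid length, keeping pad at the
        tail (so the backward direction consumes samples last-to-first)."""
        out = np.zeros_like(X)
        for b, L in enumerate(lengths):
            out[b, :L] = X[b, :L][::-1]
        return out

    # ------------------------------------------------------------------
    # full forward pass
    # ------------------------------------------------------------------

    def _forward(self, X, lengths, want_cache=False):
        B, T, _ = X.shape
        mask = (np.arange(T)[None, :] < np.asarray(lengths)[:, None]).astype(float)
        p = self.params
        caches = []
        cur = X
        for layer, h in enumerate(self.arch.hidden_units):
            Xr = self._reverse_padded(cur, lengths)
            Hf, cf = self._lstm_forward(cur, mask, p[f"W{layer}f"],
                                        p[f"U{layer}f"], p[f"b{layer}f"])
            Hb_r, cb = self._lstm_forward(Xr, mask, p[f"W{layer}b"],
                                          p[f"U{layer}b"], p[f"b{layer}b"])
            Hb = self._reverse_padded(Hb_r, lengths)
            seq = np.concatenate([Hf, Hb], axis=2)          # (B, T, 2h)
            ln, ln_cache = self._layernorm_forward(
                seq, p[f"ln{layer}_g"], p[f"ln{layer}_b"])
            act = np.maximum(ln, 0.0)
            caches.append({"input": cur, "mask": mask, "cf": cf, "cb": cb,
                           "seq": seq, "ln_cache": ln_cache, "ln": ln,
                           "Xr": Xr})
            cur = act * mask[:, :, None]  # zero padded positions
        # encoder output: states at the last valid step of the final block
        last = np.asarray(lengths) - 1
        e = cur[np.arange(B), last]                          # (B, 2h)
        z1 = e @ p["Wd"] + p["bd"]
        a1 = np.maximum(z1, 0.0)
        logits = a1 @ p["Wo"] + p["bo"]
        logits = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(logits)
        probs = expz / expz.sum(axis=1, keepdims=True)
        if not want_cache:
            return probs
        return probs, {"caches": caches, "e": e, "z1": z1, "a1": a1,
                       "last": last, "mask": mask, "cur": cur}

    def _backward(self, probs, y_onehot, fw):
        """Gradient of mean cross-entropy w.r.t. every parameter."""
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        B = probs.shape[0]
        dlogits = (probs - y_onehot) / B
        grads["Wo"] = fw["a1"].T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        da1 = dlogits @ p["Wo"].T
        dz1 = da1 * (fw["z1"] > 0)
        grads["Wd"] = fw["e"].T @ dz1
        grads["bd"] = dz1.sum(axis=0)
        de = dz1 @ p["Wd"].T
        # scatter encoder gradient back to the last valid timestep
        dcur = np.zeros_like(fw["cur"])
        dcur[np.arange(B), fw["last"]] = de
        for layer in range(len(self.arch.hidden_units) - 1, -1, -1):
            c = fw["caches"][layer]
            mask = c["mask"]
            h = self.arch.hidden_units[layer]
            dact = dcur * mask[:, :, None]
            dln = dact * (c["ln"] > 0)
            dseq, dg, db_ = self._layernorm_backward(
                dln, p[f"ln{layer}_g"], c["ln_cache"])
            grads[f"ln{layer}_g"] = dg
            grads[f"ln{layer}_b"] = db_
            dHf = dseq[:, :, :h]
            dHb = dseq[:, :, h:]
            lengths = mask.sum(axis=1).astype(int)
            dHb_r = self._reverse_padded(dHb, lengths)
            dXf, dWf, dUf, dbf = self._lstm_backward(
                dHf, c["input"], mask, p[f"W{layer}f"], p[f"U{layer}f"], c["cf"])
            dXb_r, dWb, dUb, dbb = self._lstm_backward(
                dHb_r, c["Xr"], mask, p[f"W{layer}b"], p[f"U{layer}b"], c["cb"])
            dXb = self._reverse_padded(dXb_r, lengths)
            grads[f"W{layer}f"], grads[f"U{layer}f"], grads[f"b{layer}f"] = dWf, dUf, dbf
            grads[f"W{layer}b"], grads[f"U{layer}b"], grads[f"b{layer}b"] = dWb, dUb, dbb
            dcur = dXf + dXb
        return grads

    # ------------------------------------------------------------------
    # public API
    # ------------------------------------------------------------------

    def predict_proba(self, trials: list[Trial]) -> np.ndarray:
        """Class probabilities for a list of (possibly ragged) trials."""
        X, lengths = _pad_batch([t.values for t in trials])
        if X.shape[2] != self.n_channels:
            raise ValueError("channel count mismatch")
        return self._forward(X, lengths)

    def predict(self, trials: list[Trial]) -> tuple[np.ndarray, np.ndarray]:
        """Predicted labels (argmax of softmax; ties to the first class in
        sorted order) and the probability matrix."""
        if self.classes is None:
            raise RuntimeError("model is untrained: class list unset")
        probs = self.predict_proba(trials)
        idx = probs.argmax(axis=1)
        return np.array([self.classes[i] for i in idx]), probs

    def save(self, path: str | Path) -> None:
        """Checkpoint: npz of parameters + JSON architecture sidecar."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        path.with_suffix(".json").write_text(json.dumps({
            "n_channels": self.n_channels, "n_classes": self.n_classes,
            "hidden_units": list(self.arch.hidden_units),
            "dense_units": self.arch.dense_units,
            "classes": self.classes,
        }))

    @classmethod
    def load(cls, path: str | Path) -> "BiLstmClassifier":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(meta["n_channels"], meta["n_classes"],
                    LstmArchitecture(tuple(meta["hidden_units"]),
                                     meta["dense_units"]))
        model.classes = meta["classes"]
        with np.load(path.with_suffix(".npz")) as f:
            model.params = {k: f[k] for k in f.files}
        return model


def _pad_batch(arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad a list of (t_i x c) arrays into (B, T_max, c) + lengths."""
    lengths = np.array([a.shape[0] for a in arrays])
    T = int(lengths.max())
    X = np.zeros((len(arrays), T, arrays[0].shape[1]))
    for b, a in enumerate(arrays):
        X[b, : a.shape[0]] = a
    return X, lengths


def train(model: BiLstmClassifier, trials: list[Trial], labels,
          params: TrainingParams | None = None) -> list[float]:
    """Train in place with Adam on cross-entropy; returns per-epoch loss.

    Mini-batches are formed by sorting trials by length into buckets of
    ``mini_batch`` (minimizing padding) and shuffling bucket order each
    epoch; padded steps are masked out of the recurrence.  All randomness
    flows from ``params.seed``.
    """
    params = params or TrainingParams()
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if len(classes) != model.n_classes:
        raise ValueError(f"model has {model.n_classes} outputs but the labels "
                         f"carry {len(classes)} classes")
    model.classes = classes
    class_idx = {c: i for i, c in enumerate(classes)}
    y = np.array([class_idx[l] for l in labels])
    rng = np.random.default_rng(params.seed)

    order = np.argsort([t.n_samples for t in trials], kind="stable")
    buckets = [order[i:i + params.mini_batch]
               for i in range(0, len(order), params.mini_batch)]

    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    losses = []
    for _ in range(params.epochs):
        rng.shuffle(buckets)
        epoch_loss, n_seen = 0.0, 0
        for bucket in buckets:
            X, lengths = _pad_batch([trials[i].values for i in bucket])
            yb = y[bucket]
            onehot = np.eye(len(classes))[yb]
            probs, fw = model._forward(X, lengths, want_cache=True)
            loss = -np.mean(np.log(probs[np.arange(len(yb)), yb] + 1e-12))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at update {step}: {loss}")
            epoch_loss += loss * len(yb)
            n_seen += len(yb)
            grads = model._backward(probs, onehot, fw)
            step += 1
            lr_t = params.learning_rate * np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step)
            for k in model.params:
                g = grads[k]
                m_state[k] = beta1 * m_state[k] + (1 - beta1) * g
                v_state[k] = beta2 * v_state[k] + (1 - beta2) * g * g
                model.params[k] -= lr_t * m_state[k] / (np.sqrt(v_state[k]) + eps)
        losses.append(epoch_loss / n_seen)
    return losses


def grid_search(trials, labels, val_trials, val_labels, n_channels, n_classes,
                epochs_grid=(32, 64), batch_grid=(16,), hidden_grid=((100, 100),),
                seed: int = 0):
    """Small optional harness scanning epochs x batch x hidden widths; returns
    the best (params, arch, accuracy) on the validation split."""
    best = None
    for epochs in epochs_grid:
        for batch in batch_grid:
            for hidden in hidden_grid:
                arch = LstmArchitecture(hidden_units=tuple(hidden))
                model = BiLstmClassifier(n_channels, n_classes, arch, seed=seed)
                tp = TrainingParams(epochs=epochs, mini_batch=batch, seed=seed)
                train(model, trials, labels, tp)
                pred, _ = model.predict(val_trials)
                acc = float(np.mean(pred == np.asarray(val_labels)))
                if best is None or acc > best[2]:
                    best = (tp, arch, acc)
    return best
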