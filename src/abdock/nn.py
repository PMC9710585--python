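"""Minimal feed-forward binary classifier on numpy.

Architecture used by the residue-level binding-site predictors: dense
hidden layers with ReLU activations, batch normalisation inserted after
each hidden layer starting from the second (before the activation),
per-layer dropout, a sigmoid output unit, class-weighted binary
cross-entropy loss, Adam optimisation and early stopping with
restore-best-weights.  Fully deterministic given the seed.
"""

from __future__ import annotations

import copy

import numpy as np


def _relu(x):
    return np.maximum(x, 0.0)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class MLPBinaryClassifier:
    """Class-weighted binary MLP trained with Adam.

    Parameters
    ----------
    widths:
        Hidden-layer widths, one entry per hidden layer.
    dropout:
        Dropout rate applied after each hidden activation (scalar or
        per-layer sequence).
    batch_norm:
        Insert batch normalisation before the activation of hidden layers
        2..k (the first hidden layer is left plain).
    """

    def __init__(
        self,
        widths=(64, 64),
        dropout=0.2,
        batch_norm=True,
        lr=1e-3,
        batch_size=32,
        max_epochs=150,
        patience=12,
        seed=17,
        bn_momentum=0.9,
        weight_decay=0.0,
    ):
        self.widths = list(widths)
        self.dropout = (
            [float(dropout)] * len(self.widths)
            if np.isscalar(dropout)
            else [float(d) for d in dropout]
        )
        if any(not (0 <= d < 1) for d in self.dropout):
            raise ValueError("dropout rates must be in [0, 1)")
        self.batch_norm = batch_norm
        self.lr = lr
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed
        self.bn_momentum = bn_momentum
        self.weight_decay = weight_decay
        self.params_ = None
        self.history_ = None

    # ------------------------------------------------------------ init/state
    def _init_params(self, n_features, rng):
        params = []
        fan_in = n_features
        for li, w in enumerate(self.widths):
            layer = {
                "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, w)),
                "b": np.zeros(w),
            }
            if self.batch_norm and li >= 1:
                layer.update(
                    gamma=np.ones(w), beta=np.zeros(w),
                    run_mean=np.zeros(w), run_var=np.ones(w),
                )
            params.append(layer)
            fan_in = w
        params.append({"W": rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, 1)),
                       "b": np.zeros(1)})
        return params

    # ---------------------------------------------------------------- forward
    def _forward(self, X, params, training, rng=None):
        cache = []
        a = X
        for li, layer in enumerate(params[:-1]):
            z = a @ layer["W"] + layer["b"]
            c = {"a_in": a, "z": z}
            if "gamma" in layer:
                if training:
                    mu = z.mean(axis=0)
                    var = z.var(axis=0)
                    layer["run_mean"] = self.bn_momentum * layer["run_mean"] + (1 - self.bn_momentum) * mu
                    layer["run_var"] = self.bn_momentum * layer["run_var"] + (1 - self.bn_momentum) * var
                else:
                    mu, var = layer["run_mean"], layer["run_var"]
                zhat = (z - mu) / np.sqrt(var + 1e-5)
                z = layer["gamma"] * zhat + layer["beta"]
                c.update(zhat=zhat, var=var)
            h = _relu(z)
            c["z_act"] = z
            if training and self.dropout[li] > 0:
                mask = (rng.random(h.shape) >= self.dropout[li]) / (1 - self.dropout[li])
                h = h * mask
                c["mask"] = mask
            cache.append(c)
            a = h
        logits = (a @ params[-1]["W"] + params[-1]["b"]).ravel()
        cache.append({"a_in": a})
        return logits, cache

    @staticmethod
    def _bce_loss(logits, y, sample_weight):
        # numerically stable weighted BCE on logits
        per = np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))
        return float(np.sum(sample_weight * per) / np.sum(sample_weight))

    def _backward(self, logits, y, sample_weight, params, cache):
        grads = [dict() for _ in params]
        n = len(y)
        wsum = np.sum(sample_weight)
        p = _sigmoid(logits)
        delta = ((p - y) * sample_weight / wsum).reshape(-1, 1)
        a_last = cache[-1]["a_in"]
        grads[-1]["W"] = a_last.T @ delta
        grads[-1]["b"] = delta.sum(axis=0)
        da = delta @ params[-1]["W"].T
        for li in range(len(params) - 2, -1, -1):
            c = cache[li]
            layer = params[li]
            if "mask" in c:
                da = da * c["mask"]
            dz = da * (c["z_act"] > 0)
            if "gamma" in layer:
                zhat, var = c["zhat"], c["var"]
                m = dz.shape[0]
                grads[li]["gamma"] = np.sum(dz * zhat, axis=0)
                grads[li]["beta"] = np.sum(dz, axis=0)
                dzhat = dz * layer["gamma"]
                inv = 1.0 / np.sqrt(var + 1e-5)
                dz = inv * (
                    dzhat
                    - dzhat.mean(axis=0)
                    - zhat * np.mean(dzhat * zhat, axis=0)
                )
            grads[li]["W"] = c["a_in"].T @ dz
            grads[li]["b"] = dz.sum(axis=0)
            da = dz @ layer["W"].T
        return grads

    # -------------------------------------------------------------------- fit
    def fit(self, X, y, class_weight=None, validation=None):
        """Train on (X, y) with optional held-out (Xv, yv) early stopping.

        ``class_weight`` maps {0: w0, 1: w1}; defaults to equal weights.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite features")
        if len(np.unique(y)) < 2:
            raise ValueError("training labels are single-class")
        cw = {0: 1.0, 1: 1.0} if class_weight is None else class_weight
        sw = np.where(y > 0.5, cw[1], cw[0]).astype(float)
        rng = np.random.default_rng(self.seed)
        params = self._init_params(X.shape[1], rng)
        adam = [{k: (np.zeros_like(v), np.zeros_like(v)) for k, v in layer.items()
                 if k in ("W", "b", "gamma", "beta")} for layer in params]
        step = 0
        best_loss, best_params, wait = np.inf, None, 0
        history = []
        n = len(y)
        if validation is not None:
            Xv = np.asarray(validation[0], dtype=float)
            yv = np.asarray(validation[1], dtype=float).ravel()
            swv = np.where(yv > 0.5, cw[1], cw[0]).astype(float)
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                if len(idx) < 2:
                    continue
                logits, cache = self._forward(X[idx], params, training=True, rng=rng)
                grads = self._backward(logits, y[idx], sw[idx], params, cache)
                step += 1
                b1, b2, eps = 0.9, 0.999, 1e-8
                for layer, g, st in zip(params, grads, adam):
                    for k in g:
                        m, v = st[k]
                        m = b1 * m + (1 - b1) * g[k]
                        v = b2 * v + (1 - b2) * g[k] ** 2
                        st[k] = (m, v)
                        mhat = m / (1 - b1**step)
                        vhat = v / (1 - b2**step)
                        update = mhat / (np.sqrt(vhat) + eps)
                        if k == "W" and self.weight_decay > 0:
                            update = update + self.weight_decay * layer[k]
                        layer[k] = layer[k] - self.lr * update
            if validation is not None:
                logits_v, _ = self._forward(Xv, params, training=False)
                mon = self._bce_loss(logits_v, yv, swv)
            else:
                logits_t, _ = self._forward(X, params, training=False)
                mon = self._bce_loss(logits_t, y, sw)
            history.append(mon)
            if mon < best_loss - 1e-6:
                best_loss, wait = mon, 0
                best_params = copy.deepcopy(params)
            else:
                wait += 1
                if wait >= self.patience:
                    break
        self.params_ = best_params if best_params is not None else params
        self.history_ = {"monitored_loss": history, "best_loss": best_loss,
                         "epochs": len(history)}
        return self

    def predict_proba(self, X) -> np.ndarray:
        if self.params_ is None:
            raise RuntimeError("model is not fitted")
        logits, _ = self._forward(np.asarray(X, dtype=float), self.params_, training=False)
        return _sigmoid(logits)

    # -------------------------------------------------------- (de)serialise
    def state_dict(self) -> dict:
        flat = {}
        for i, layer in enumerate(self.params_):
            for k, v in layer.items():
                flat[f"{i}.{k}"] = v
        return flat

    def load_state_dict(self, flat: dict) -> "MLPBinaryClassifier":
        layers: dict[int, dict] = {}
        for key, v in flat.items():
            i, k = key.split(".", 1)
            layers.setdefault(int(i), {})[k] = np.asarray(v)
        self.params_ = [layers[i] for i in sorted(layers)]
        return self
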