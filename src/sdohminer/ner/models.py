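"""Sequence taggers trained from scratch, plus the model-family registry.

The three recurrent families (simple RNN, GRU, bidirectional LSTM) are
implemented directly on numpy with manual backpropagation through time,
Adam, sparse cross-entropy with per-class/per-token weights, and inverted
dropout.  They are deliberately small: the harness exists to exercise the
training/evaluation protocol, not to chase state of the art.

Any object exposing ``predict_scores(corpus) -> (n_tokens, n_labels)``
rows on the probability simplex and ``label_list`` can be evaluated, so
externally fine-tuned transformer checkpoints plug in through
:func:`register_model_family`.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

from ..corpus import LabeledCorpus


class BackendUnavailableError(RuntimeError):
    pass


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng: np.random.Generator, *shape: int) -> np.ndarray:
    scale = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-scale, scale, shape)


class _RNNCell:
    def __init__(self, rng, d_in: int, d_hidden: int, prefix: str):
        self.h = d_hidden
        self.prefix = prefix
        self.params = {
            f"{prefix}Wx": _glorot(rng, d_in, d_hidden),
            f"{prefix}Wh": _glorot(rng, d_hidden, d_hidden),
            f"{prefix}b": np.zeros(d_hidden),
        }

    def forward(self, X: np.ndarray, mask: np.ndarray):
        # X: (T, B, D); mask: (T, B)
        p = self.params
        T, B, _ = X.shape
        H = np.zeros((T, B, self.h))
        hn_all = np.zeros_like(H)
        h = np.zeros((B, self.h))
        hprev_all = np.zeros_like(H)
        for t in range(T):
            hprev_all[t] = h
            hn = np.tanh(X[t] @ p[f"{self.prefix}Wx"] + h @ p[f"{self.prefix}Wh"] + p[f"{self.prefix}b"])
            h = mask[t][:, None] * hn
            hn_all[t] = hn
            H[t] = h
        return H, (X, mask, hn_all, hprev_all)

    def backward(self, dH: np.ndarray, cache):
        X, mask, hn_all, hprev_all = cache
        p = self.params
        T = X.shape[0]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dX = np.zeros_like(X)
        dh_next = np.zeros((X.shape[1], self.h))
        for t in range(T - 1, -1, -1):
            dh = (dH[t] + dh_next) * mask[t][:, None]
            da = dh * (1.0 - hn_all[t] ** 2)
            grads[f"{self.prefix}Wx"] += X[t].T @ da
            grads[f"{self.prefix}Wh"] += hprev_all[t].T @ da
            grads[f"{self.prefix}b"] += da.sum(axis=0)
            dX[t] = da @ p[f"{self.prefix}Wx"].T
            dh_next = da @ p[f"{self.prefix}Wh"].T
        return dX, grads


class _GRUCell:
    def __init__(self, rng, d_in: int, d_hidden: int, prefix: str):
        self.h = d_hidden
        self.prefix = prefix
        self.params = {}
        for g in ("z", "r", "h"):
            self.params[f"{prefix}W{g}"] = _glorot(rng, d_in, d_hidden)
            self.params[f"{prefix}U{g}"] = _glorot(rng, d_hidden, d_hidden)
            self.params[f"{prefix}b{g}"] = np.zeros(d_hidden)

    def forward(self, X: np.ndarray, mask: np.ndarray):
        p, pre = self.params, self.prefix
        T, B, _ = X.shape
        H = np.zeros((T, B, self.h))
        zs, rs, hhs, hprevs = (np.zeros_like(H) for _ in range(4))
        h = np.zeros((B, self.h))
        for t in range(T):
            hprevs[t] = h
            z = _sigmoid(X[t] @ p[f"{pre}Wz"] + h @ p[f"{pre}Uz"] + p[f"{pre}bz"])
            r = _sigmoid(X[t] @ p[f"{pre}Wr"] + h @ p[f"{pre}Ur"] + p[f"{pre}br"])
            hh = np.tanh(X[t] @ p[f"{pre}Wh"] + (r * h) @ p[f"{pre}Uh"] + p[f"{pre}bh"])
            hn = (1.0 - z) * h + z * hh
            h = mask[t][:, None] * hn
            zs[t], rs[t], hhs[t], H[t] = z, r, hh, h
        return H, (X, mask, zs, rs, hhs, hprevs)

    def backward(self, dH: np.ndarray, cache):
        X, mask, zs, rs, hhs, hprevs = cache
        p, pre = self.params, self.prefix
        T = X.shape[0]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dX = np.zeros_like(X)
        dh_next = np.zeros((X.shape[1], self.h))
        for t in range(T - 1, -1, -1):
            z, r, hh, h_prev = zs[t], rs[t], hhs[t], hprevs[t]
            dhn = (dH[t] + dh_next) * mask[t][:, None]
            dz = dhn * (hh - h_prev)
            dhh = dhn * z
            dh_prev = dhn * (1.0 - z)
            dah = dhh * (1.0 - hh ** 2)
            drh = dah @ p[f"{pre}Uh"].T
            dr = drh * h_prev
            dh_prev += drh * r
            daz = dz * z * (1.0 - z)
            dar = dr * r * (1.0 - r)
            dX[t] = daz @ p[f"{pre}Wz"].T + dar @ p[f"{pre}Wr"].T + dah @ p[f"{pre}Wh"].T
            dh_prev += daz @ p[f"{pre}Uz"].T + dar @ p[f"{pre}Ur"].T
            grads[f"{pre}Wz"] += X[t].T @ daz
            grads[f"{pre}Uz"] += h_prev.T @ daz
            grads[f"{pre}bz"] += daz.sum(axis=0)
            grads[f"{pre}Wr"] += X[t].T @ dar
            grads[f"{pre}Ur"] += h_prev.T @ dar
            grads[f"{pre}br"] += dar.sum(axis=0)
            grads[f"{pre}Wh"] += X[t].T @ dah
            grads[f"{pre}Uh"] += (r * h_prev).T @ dah
            grads[f"{pre}bh"] += dah.sum(axis=0)
            dh_next = dh_prev
        return dX, grads


class _LSTMCell:
    def __init__(self, rng, d_in: int, d_hidden: int, prefix: str):
        self.h = d_hidden
        self.prefix = prefix
        self.params = {}
        for g in ("i", "f", "o", "g"):
            self.params[f"{prefix}W{g}"] = _glorot(rng, d_in, d_hidden)
            self.params[f"{prefix}U{g}"] = _glorot(rng, d_hidden, d_hidden)
            self.params[f"{prefix}b{g}"] = np.zeros(d_hidden)
        self.params[f"{prefix}bf"] += 1.0  # forget-gate bias

    def forward(self, X: np.ndarray, mask: np.ndarray):
        p, pre = self.params, self.prefix
        T, B, _ = X.shape
        H = np.zeros((T, B, self.h))
        store = {k: np.zeros_like(H) for k in ("i", "f", "o", "g", "cn", "hprev", "cprev")}
        h = np.zeros((B, self.h))
        c = np.zeros((B, self.h))
        for t in range(T):
            store["hprev"][t], store["cprev"][t] = h, c
            i = _sigmoid(X[t] @ p[f"{pre}Wi"] + h @ p[f"{pre}Ui"] + p[f"{pre}bi"])
            f = _sigmoid(X[t] @ p[f"{pre}Wf"] + h @ p[f"{pre}Uf"] + p[f"{pre}bf"])
            o = _sigmoid(X[t] @ p[f"{pre}Wo"] + h @ p[f"{pre}Uo"] + p[f"{pre}bo"])
            g = np.tanh(X[t] @ p[f"{pre}Wg"] + h @ p[f"{pre}Ug"] + p[f"{pre}bg"])
            cn = f * c + i * g
            hn = o * np.tanh(cn)
            m = mask[t][:, None]
            h, c = m * hn, m * cn
            for k, v in (("i", i), ("f", f), ("o", o), ("g", g), ("cn", cn)):
                store[k][t] = v
            H[t] = h
        return H, (X, mask, store)

    def backward(self, dH: np.ndarray, cache):
        X, mask, st = cache
        p, pre = self.params, self.prefix
        T = X.shape[0]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dX = np.zeros_like(X)
        dh_next = np.zeros((X.shape[1], self.h))
        dc_next = np.zeros((X.shape[1], self.h))
        for t in range(T - 1, -1, -1):
            m = mask[t][:, None]
            i, f, o, g = st["i"][t], st["f"][t], st["o"][t], st["g"][t]
            cn, h_prev, c_prev = st["cn"][t], st["hprev"][t], st["cprev"][t]
            tc = np.tanh(cn)
            dhn = (dH[t] + dh_next) * m
            dcn = dc_next * m + dhn * o * (1.0 - tc ** 2)
            do = dhn * tc
            di = dcn * g
            df = dcn * c_prev
            dg = dcn * i
            dc_next = dcn * f
            da = {
                "i": di * i * (1.0 - i),
                "f": df * f * (1.0 - f),
                "o": do * o * (1.0 - o),
                "g": dg * (1.0 - g ** 2),
            }
            dx_t = np.zeros_like(X[t])
            dh_prev = np.zeros_like(dh_next)
            for k, d in da.items():
                grads[f"{pre}W{k}"] += X[t].T @ d
                grads[f"{pre}U{k}"] += h_prev.T @ d
                grads[f"{pre}b{k}"] += d.sum(axis=0)
                dx_t += d @ p[f"{pre}W{k}"].T
                dh_prev += d @ p[f"{pre}U{k}"].T
            dX[t] = dx_t
            dh_next = dh_prev
        return dX, grads


class RecurrentTagger:
    """Embedding -> recurrent encoder -> softmax token classifier."""

    def __init__(
        self,
        family: str,
        vocab,
        label_list: Sequence[str],
        embed_dim: int = 24,
        hidden_size: int = 32,
        dropout: float = 0.1,
        seed: int = 0,
    ):
        if not (0.0 <= dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        self.family = family
        self.vocab = vocab
        self.label_list = list(label_list)
        self.dropout = dropout
        rng = np.random.default_rng(seed)
        self._rng = rng
        V, D, H, L = len(vocab), embed_dim, hidden_size, len(label_list)
        self.params: dict[str, np.ndarray] = {
            "E": rng.normal(0.0, 0.1, (V, D))
        }
        if family == "rnn":
            self.cells = [_RNNCell(rng, D, H, "rnn.")]
            out_dim = H
        elif family == "gru":
            self.cells = [_GRUCell(rng, D, H, "gru.")]
            out_dim = H
        elif family == "bilstm":
            self.cells = [_LSTMCell(rng, D, H, "fwd."), _LSTMCell(rng, D, H, "bwd.")]
            out_dim = 2 * H
        else:
            raise ValueError(f"unknown recurrent family {family!r}")
        for c in self.cells:
            self.params.update(c.params)
        self.params["Wout"] = _glorot(rng, out_dim, L)
        self.params["bout"] = np.zeros(L)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self.loss_history: list[float] = []
        # cells hold views into self.params; keep them shared
        for c in self.cells:
            for k in c.params:
                c.params[k] = self.params[k]

    # ---- forward/backward ----------------------------------------------
    def _encode_hidden(self, ids: np.ndarray, mask: np.ndarray, train: bool):
        # ids, mask: (B, T)
        X = self.params["E"][ids].transpose(1, 0, 2)  # (T, B, D)
        m = mask.T.astype(float)  # (T, B)
        caches = []
        if self.family == "bilstm":
            Hf, cf = self.cells[0].forward(X, m)
            Hb_rev, cb = self.cells[1].forward(X[::-1], m[::-1])
            H = np.concatenate([Hf, Hb_rev[::-1]], axis=-1)
            caches = [cf, cb]
        else:
            H, c = self.cells[0].forward(X, m)
            caches = [c]
        drop_mask = None
        if train and self.dropout > 0:
            drop_mask = (
                self._rng.random(H.shape) >= self.dropout
            ).astype(float) / (1.0 - self.dropout)
            H = H * drop_mask
        return X, m, H, caches, drop_mask

    def _forward(self, ids, mask, train=False):
        X, m, H, caches, drop_mask = self._encode_hidden(ids, mask, train)
        logits = H @ self.params["Wout"] + self.params["bout"]
        probs = _softmax(logits)
        return probs, (X, m, H, caches, drop_mask, ids)

    def _backward(self, probs, label_ids, token_weights, cache):
        """label_ids: (B, T) with negative = ignored; token_weights same shape."""
        X, m, H, caches, drop_mask, ids = cache
        # probs arrives as (T, B, L) from forward
        y = label_ids.T  # (T, B)
        w = token_weights.T  # (T, B)
        valid = y >= 0
        w = np.where(valid, w, 0.0)
        wsum = w.sum()
        if wsum <= 0:
            return None, 0.0
        onehot = np.zeros_like(probs)
        tt, bb = np.nonzero(valid)
        onehot[tt, bb, y[tt, bb]] = 1.0
        eps = 1e-12
        loss = -(np.log(probs[tt, bb, y[tt, bb]] + eps) * w[tt, bb]).sum() / wsum
        dlogits = (probs - onehot) * w[:, :, None] / wsum
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        Hd = H
        grads["Wout"] = Hd.reshape(-1, Hd.shape[-1]).T @ dlogits.reshape(-1, dlogits.shape[-1])
        grads["bout"] = dlogits.sum(axis=(0, 1))
        dH = dlogits @ self.params["Wout"].T
        if drop_mask is not None:
            dH = dH * drop_mask
        if self.family == "bilstm":
            hsz = self.cells[0].h
            dXf, gf = self.cells[0].backward(dH[..., :hsz], caches[0])
            dXb_rev, gb = self.cells[1].backward(dH[::-1, :, hsz:], caches[1])
            dX = dXf + dXb_rev[::-1]
            grads.update(gf)
            grads.update(gb)
        else:
            dX, gc = self.cells[0].backward(dH, caches[0])
            grads.update(gc)
        dE = grads["E"]
        np.add.at(dE, ids.T, dX)
        return grads, float(loss)

    def _adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # ---- public API ----------------------------------------------------
    def fit(
        self,
        sequences: Sequence[tuple[np.ndarray, np.ndarray]],
        epochs: int,
        learning_rate: float,
        class_weights: Optional[np.ndarray] = None,
        sample_weights: Optional[Sequence[np.ndarray]] = None,
        batch_size: int = 32,
        shuffle_seed: int = 0,
    ) -> "RecurrentTagger":
        """Mini-batch Adam on (word_ids, label_ids) sequences.

        Per-token loss weight = class_weight[label] * sample_weight; padded
        and ignored positions contribute nothing.
        """
        rng = np.random.default_rng(shuffle_seed)
        n = len(sequences)
        L = len(self.label_list)
        cw = np.ones(L) if class_weights is None else np.asarray(class_weights, float)
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                batch = [sequences[i] for i in idx]
                maxT = max(len(s[0]) for s in batch)
                B = len(batch)
                ids = np.zeros((B, maxT), dtype=np.int64)
                labs = np.full((B, maxT), -1, dtype=np.int64)
                mask = np.zeros((B, maxT), dtype=np.int64)
                tw = np.zeros((B, maxT))
                for bi, (si, (seq_ids, seq_labs)) in enumerate(zip(idx, batch)):
                    tlen = len(seq_ids)
                    ids[bi, :tlen] = seq_ids
                    labs[bi, :tlen] = seq_labs
                    mask[bi, :tlen] = 1
                    sw = (
                        sample_weights[si]
                        if sample_weights is not None
                        else np.ones(tlen)
                    )
                    safe = np.clip(seq_labs, 0, None)
                    tw[bi, :tlen] = np.where(seq_labs >= 0, cw[safe] * sw, 0.0)
                probs, cache = self._forward(ids, mask, train=True)
                grads, loss = self._backward(probs, labs, tw, cache)
                if grads is None:
                    continue
                self._adam_step(grads, learning_rate)
                epoch_loss += loss
                n_batches += 1
            self.loss_history.append(epoch_loss / max(n_batches, 1))
        return self

    def predict_scores(self, corpus: LabeledCorpus) -> np.ndarray:
        """Per-token probability rows over ``label_list``, in corpus order."""
        rows = []
        sents = [s for d in corpus.documents for s in d.sentences]
        for start in range(0, len(sents), 64):
            batch = sents[start : start + 64]
            maxT = max(len(s) for s in batch)
            ids = np.zeros((len(batch), maxT), dtype=np.int64)
            mask = np.zeros((len(batch), maxT), dtype=np.int64)
            for bi, s in enumerate(batch):
                for ti, tok in enumerate(s.tokens):
                    ids[bi, ti] = self.vocab.id(tok.text)
                mask[bi, : len(s)] = 1
            probs, _ = self._forward(ids, mask, train=False)
            probs = probs.transpose(1, 0, 2)  # (B, T, L)
            for bi, s in enumerate(batch):
                rows.append(probs[bi, : len(s)])
        return np.concatenate(rows, axis=0) if rows else np.zeros(
            (0, len(self.label_list))
        )

    def predict_labels(self, corpus: LabeledCorpus) -> list[str]:
        scores = self.predict_scores(corpus)
        return [self.label_list[i] for i in scores.argmax(axis=1)]


def _unavailable_transformer(*_args, **_kwargs):
    raise BackendUnavailableError(
        "no transformer fine-tuning backend is registered; register one with "
        "sdohminer.ner.register_model_family('transformer_finetune', factory) "
        "— any tagger exposing predict_scores(corpus) and label_list can be "
        "evaluated by this harness"
    )


MODEL_FAMILIES: dict[str, Callable] = {
    "rnn": lambda **kw: RecurrentTagger("rnn", **kw),
    "gru": lambda **kw: RecurrentTagger("gru", **kw),
    "bilstm": lambda **kw: RecurrentTagger("bilstm", **kw),
    "transformer_finetune": _unavailable_transformer,
}


def register_model_family(name: str, factory: Callable) -> None:
    MODEL_FAMILIES[name] = factory
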