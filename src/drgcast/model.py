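"""Single-label DRG classifier: convolutional encoder with per-label attention.

The architecture follows the convolutional-attention design used for
automatic clinical coding (CAML), adapted to single-label DRG prediction:

    H   = tanh(conv1d(embed(x)))          # one feature vector per position
    a_l = softmax(H' u_l)                 # one attention vector per DRG code
    v_l = H a_l                           # label-specific document vector
    s_l = b_l' v_l + c_l                  # per-label score
    p   = softmax(s)                      # single-label posterior

Training minimises cross-entropy; a regression variant (one shared attention
vector, linear head, mean-absolute-error objective) predicts the DRG payment
weight directly.  Everything is plain NumPy with hand-derived gradients and
Adam, which keeps the dependency surface small and CPU training deterministic
under a fixed seed.

Positions holding padding are masked to -inf before the attention softmax, so
appending padding never changes scores (the pad embedding row is pinned to
zero as well).  A fully padded (empty) document gets zero attention mass and
is scored by the output bias alone.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .synthgen import DrgCatalog
from .textprep import EncodedDoc, Vocab

CLASSIFY = "classify"
REGRESS = "regress"

_NEG = -1e30


class CatalogMismatchError(KeyError):
    """Raised when a predicted code has no entry in the supplied catalog."""


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the classifier.

    The kernel width of 5 makes the attention windows 5-grams, the unit the
    model's n-gram inspection reports.  The remaining defaults are declared
    package choices, all configurable.
    """

    seed: int
    embed_dim: int = 100
    kernel_width: int = 5
    n_filters: int = 50
    dropout: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_size: int = 16
    head: str = CLASSIFY
    val_frac: float = 0.1

    def validate(self) -> None:
        if self.kernel_width < 1:
            raise ValueError("kernel_width must be >= 1")
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if self.head not in (CLASSIFY, REGRESS):
            raise ValueError(f"unknown head {self.head!r}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass(frozen=True)
class PredictionResult:
    stay_id: str
    cutoff_hpa: float
    prob: np.ndarray | None  # posterior over label_space (None for regression)
    pred_code: str | None
    pred_weight: float


@dataclass
class DrgModel:
    """Trained parameters plus the label space and vocabulary they index."""

    params: dict[str, np.ndarray]
    label_space: tuple[str, ...]
    vocab: Vocab
    config: ModelConfig

    # -- forward ------------------------------------------------------------

    def _forward_batch(self, ids: np.ndarray, train_rng: np.random.Generator | None = None,
                       want_cache: bool = False):
        """Run the network on an id matrix (B, L); returns scores, attention.

        With ``want_cache`` the intermediates needed for backprop are returned.
        """
        p = self.params
        E, W, b_conv, U, B_cls, b_out = (p["E"], p["W"], p["b_conv"], p["U"],
                                         p["B"], p["b_out"])
        k = self.config.kernel_width
        d = E.shape[1]
        Bn, L = ids.shape
        emb = E[ids]  # (B, L, d)
        drop_mask = None
        if train_rng is not None and self.config.dropout > 0.0:
            keep = 1.0 - self.config.dropout
            drop_mask = (train_rng.random(emb.shape) < keep) / keep
            emb = emb * drop_mask
        left = k // 2
        right = k - 1 - left
        emb_pad = np.pad(emb, ((0, 0), (left, right), (0, 0)))
        # (B, L, d, k) -> (B, L, k, d) -> (B, L, k*d)
        windows = sliding_window_view(emb_pad, k, axis=1)
        windows = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(Bn, L, k * d)
        Z = windows @ W.T + b_conv
        H = np.tanh(Z)

        valid = ids != self.vocab.pad_id  # (B, L)
        logits = np.einsum("blf,cf->bcl", H, U)
        logits = np.where(valid[:, None, :], logits, _NEG)
        m = logits.max(axis=2, keepdims=True)
        ex = np.exp(logits - m) * valid[:, None, :]
        denom = ex.sum(axis=2, keepdims=True)
        alpha = np.divide(ex, denom, out=np.zeros_like(ex), where=denom > 0)

        v = np.einsum("bcl,blf->bcf", alpha, H)
        scores = np.einsum("bcf,cf->bc", v, B_cls) + b_out
        if not want_cache:
            return scores, alpha
        cache = dict(ids=ids, windows=windows, H=H, alpha=alpha, v=v,
                     drop_mask=drop_mask, left=left, L=L, k=k, d=d)
        return scores, alpha, cache

    def forward(self, doc: EncodedDoc) -> tuple[np.ndarray, np.ndarray]:
        """Posterior over labels and the (n_labels x positions) attention map.

        Each attention row sums to 1 (or to 0 for an empty document).
        """
        ids = doc.token_ids[None, :]
        scores, alpha = self._forward_batch(ids)
        if self.config.head == REGRESS:
            return scores[0], alpha[0]
        return _softmax(scores)[0], alpha[0]

    def predict_proba(self, docs: Sequence[EncodedDoc], batch_size: int = 64) -> np.ndarray:
        """Posterior matrix (n_docs x n_labels), computed in batches."""
        out = []
        for i in range(0, len(docs), batch_size):
            ids = np.stack([d.token_ids for d in docs[i:i + batch_size]])
            scores, _ = self._forward_batch(ids)
            out.append(_softmax(scores) if self.config.head == CLASSIFY else scores)
        return np.vstack(out)

    def predict_weights(self, docs: Sequence[EncodedDoc], catalog: DrgCatalog,
                        batch_size: int = 64) -> np.ndarray:
        """Predicted payment weight per document.

        Classification head: catalog weight of the argmax code.  Regression
        head: the linear head's output directly.
        """
        if self.config.head == REGRESS:
            return self.predict_proba(docs, batch_size)[:, 0]
        probs = self.predict_proba(docs, batch_size)
        idx = probs.argmax(axis=1)
        return np.array([_lookup_weight(catalog, self.label_space[i]) for i in idx])

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Binary checkpoint (npz) plus a JSON sidecar describing it."""
        path = Path(path)
        with open(path, "wb") as fh:  # keep the exact filename (no .npz suffixing)
            np.savez(fh, **self.params)
        vocab_blob = json.dumps(sorted(self.vocab.token_to_id.items())).encode()
        sidecar = {
            "config": asdict(self.config),
            "label_space": list(self.label_space),
            "vocab_sha256": hashlib.sha256(vocab_blob).hexdigest(),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path, vocab: Vocab) -> "DrgModel":
        path = Path(path)
        with np.load(path) as npz:
            params = {k: npz[k] for k in npz.files}
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(params=params, label_space=tuple(sidecar["label_space"]),
                   vocab=vocab, config=ModelConfig(**sidecar["config"]))


def _softmax(s: np.ndarray) -> np.ndarray:
    e = np.exp(s - s.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def _lookup_weight(catalog: DrgCatalog, code: str) -> float:
    if code not in catalog:
        raise CatalogMismatchError(f"predicted code {code!r} missing from catalog")
    return catalog.weight_of(code)


def forward(doc: EncodedDoc, model: DrgModel) -> tuple[np.ndarray, np.ndarray]:
    """Functional form of :meth:`DrgModel.forward`."""
    return model.forward(doc)


# ---------------------------------------------------------------------------
# Training


def _init_params(rng: np.random.Generator, vocab_size: int, n_labels: int,
                 cfg: ModelConfig) -> dict[str, np.ndarray]:
    d, f, k = cfg.embed_dim, cfg.n_filters, cfg.kernel_width
    E = rng.normal(0.0, 0.1, size=(vocab_size, d))
    E[0] = 0.0  # pad row stays zero for good
    scale = np.sqrt(2.0 / (k * d + f))
    return {
        "E": E,
        "W": rng.normal(0.0, scale, size=(f, k * d)),
        "b_conv": np.zeros(f),
        "U": rng.normal(0.0, 0.1, size=(n_labels, f)),
        "B": rng.normal(0.0, 0.1, size=(n_labels, f)),
        "b_out": np.zeros(n_labels),
    }


def _backward(model: DrgModel, cache: dict, ds: np.ndarray) -> dict[str, np.ndarray]:
    """Gradients of the loss w.r.t. every parameter, given dL/dscores."""
    p = model.params
    H, alpha, v, windows, ids = cache["H"], cache["alpha"], cache["v"], cache["windows"], cache["ids"]
    k, d, L, left = cache["k"], cache["d"], cache["L"], cache["left"]
    Bn = ids.shape[0]

    grads: dict[str, np.ndarray] = {}
    grads["b_out"] = ds.sum(axis=0)
    grads["B"] = np.einsum("bc,bcf->cf", ds, v)
    dv = ds[:, :, None] * p["B"][None, :, :]                    # (B, C, F)
    dalpha = np.einsum("bcf,blf->bcl", dv, H)
    dH = np.einsum("bcl,bcf->blf", alpha, dv)
    dlog = alpha * (dalpha - (alpha * dalpha).sum(axis=2, keepdims=True))
    grads["U"] = np.einsum("bcl,blf->cf", dlog, H)
    dH += np.einsum("bcl,cf->blf", dlog, p["U"])
    dZ = dH * (1.0 - H * H)
    grads["W"] = np.einsum("blf,blm->fm", dZ, windows)
    grads["b_conv"] = dZ.sum(axis=(0, 1))

    dwin = (dZ @ p["W"]).reshape(Bn, L, k, d)
    demb_pad = np.zeros((Bn, L + k - 1, d))
    for j in range(k):
        demb_pad[:, j:j + L, :] += dwin[:, :, j, :]
    demb = demb_pad[:, left:left + L, :]
    if cache["drop_mask"] is not None:
        demb = demb * cache["drop_mask"]
    dE = np.zeros_like(p["E"])
    np.add.at(dE, ids.ravel(), demb.reshape(-1, d))
    dE[0] = 0.0  # never move the pad embedding
    grads["E"] = dE
    return grads


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
        params["E"][0] = 0.0


def train(train_docs: Sequence[EncodedDoc], labels: Sequence, config: ModelConfig, *,
          label_space: Sequence[str], vocab: Vocab,
          val_docs: Sequence[EncodedDoc] | None = None,
          val_labels: Sequence | None = None) -> DrgModel:
    """Fit the model and return the epoch snapshot with the best validation score.

    ``labels`` are DRG codes for the classification head, positive payment
    weights for the regression head.  If no validation set is supplied, a
    ``config.val_frac`` slice of the training data is held out for epoch
    selection.  Deterministic given ``config.seed`` (single-threaded numerics).
    """
    config.validate()
    if len(train_docs) == 0:
        raise ValueError("empty training set")
    if len(train_docs) != len(labels):
        raise ValueError("docs and labels length mismatch")
    label_space = tuple(label_space)
    classify = config.head == CLASSIFY
    if classify:
        index = {c: i for i, c in enumerate(label_space)}
        try:
            y_all = np.array([index[c] for c in labels], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"label {exc.args[0]!r} outside label_space") from exc
        n_out = len(label_space)
    else:
        y_all = np.asarray(labels, dtype=float)
        if np.any(y_all <= 0):
            raise ValueError("regression targets must be positive weights")
        n_out = 1

    rng = np.random.default_rng(config.seed)
    model = DrgModel(params=_init_params(rng, len(vocab), n_out, config),
                     label_space=label_space if classify else (),
                     vocab=vocab, config=config)
    opt = _Adam(model.params, config.learning_rate)

    ids_all = np.stack([d.token_ids for d in train_docs])
    if val_docs is None:
        n_val = max(1, int(round(config.val_frac * len(train_docs)))) \
            if len(train_docs) > 2 else 0
        perm = rng.permutation(len(train_docs))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            tr_idx, val_idx = perm, perm[:0]
        ids_val, y_val = ids_all[val_idx], y_all[val_idx]
        ids_tr, y_tr = ids_all[tr_idx], y_all[tr_idx]
    else:
        ids_tr, y_tr = ids_all, y_all
        ids_val = np.stack([d.token_ids for d in val_docs]) if len(val_docs) else ids_all[:0]
        y_val = (np.array([ {c: i for i, c in enumerate(label_space)}[c] for c in val_labels],
                          dtype=np.int64) if classify
                 else np.asarray(val_labels, dtype=float)) if len(val_docs) else y_all[:0]

    best_metric = -np.inf
    best_params = copy.deepcopy(model.params)
    n_tr = len(ids_tr)
    for _epoch in range(config.epochs):
        order = rng.permutation(n_tr)
        for i in range(0, n_tr, config.batch_size):
            sel = order[i:i + config.batch_size]
            ids_b, y_b = ids_tr[sel], y_tr[sel]
            scores, _alpha, cache = model._forward_batch(
                ids_b, train_rng=rng if config.dropout > 0 else None, want_cache=True)
            if classify:
                prob = _softmax(scores)
                ds = prob.copy()
                ds[np.arange(len(sel)), y_b] -= 1.0
                ds /= len(sel)
            else:
                ds = np.sign(scores[:, 0] - y_b)[:, None] / len(sel)
            opt.step(model.params, _backward(model, cache, ds))
        metric = _val_metric(model, ids_val if len(ids_val) else ids_tr,
                             y_val if len(ids_val) else y_tr, classify)
        if metric > best_metric:
            best_metric = metric
            best_params = copy.deepcopy(model.params)
    model.params = best_params
    return model


def _val_metric(model: DrgModel, ids: np.ndarray, y: np.ndarray, classify: bool) -> float:
    out = []
    for i in range(0, len(ids), 64):
        scores, _ = model._forward_batch(ids[i:i + 64])
        out.append(scores)
    scores = np.vstack(out)
    if classify:
        return float(np.mean(scores.argmax(axis=1) == y))
    return -float(np.mean(np.abs(scores[:, 0] - y)))  # higher is better


# ---------------------------------------------------------------------------
# Inference utilities


def predict(model: DrgModel, doc: EncodedDoc, catalog: DrgCatalog) -> PredictionResult:
    """Argmax decision (ties broken toward the lowest label index) + weight lookup."""
    if model.config.head == REGRESS:
        scores, _ = model._forward_batch(doc.token_ids[None, :])
        return PredictionResult(doc.stay_id, doc.cutoff_hpa, prob=None,
                                pred_code=None, pred_weight=float(scores[0, 0]))
    prob, _att = model.forward(doc)
    idx = int(np.argmax(prob))  # first maximum = lowest label index on ties
    code = model.label_space[idx]
    return PredictionResult(doc.stay_id, doc.cutoff_hpa, prob=prob,
                            pred_code=code, pred_weight=_lookup_weight(catalog, code))


def top_attended_ngrams(model: DrgModel, doc: EncodedDoc, label: str,
                        top_n: int = 3) -> list[tuple[tuple[str, ...], float]]:
    """The ``top_n`` attention peaks for ``label``, each as its n-gram window.

    Windows are ``kernel_width`` tokens centred on the peak position per the
    convolution alignment, clipped to the document's real tokens; weights are
    returned non-increasing.  An empty document has no attended positions.
    """
    if label not in model.label_space:
        raise ValueError(f"label {label!r} not in label_space")
    if doc.true_length == 0:
        return []
    _prob, att = model.forward(doc)
    row = att[model.label_space.index(label)][:doc.true_length]
    order = np.argsort(-row, kind="stable")[:top_n]
    k = model.config.kernel_width
    half = k // 2
    out = []
    for t in order:
        start = max(0, int(t) - half)
        end = min(doc.true_length, int(t) - half + k)
        tokens = tuple(model.vocab.decode(doc.token_ids[start:end]))
        out.append((tokens, float(row[t])))
    return out
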