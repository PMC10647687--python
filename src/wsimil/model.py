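"""Multi-branch gated-attention network for multiple-instance learning.

One bag (a patient's tile feature vectors, shape (n, d)) is mapped to class
probabilities as follows.  A shared fully connected trunk with ReLU embeds
every tile, h_k = relu(W1 x_k + b1).  Each class c then owns a gated
attention branch: a tanh transform and a sigmoid gate are combined
elementwise and scored,

    s_{c,k} = w_c^T ( tanh(V_c h_k) * sigmoid(U_c h_k) ),

the scores are softmax-normalized over the bag's tiles into attention
weights a_{c,k}, the bag representation is the attention-weighted average
z_c = sum_k a_{c,k} h_k (identical to global average pooling of the weighted
vectors, since the weights sum to one), and a per-class linear scorer gives
the class logit.  Class probabilities are the softmax over logits; the
predicted label is the argmax (no threshold tuning).

Training uses categorical cross-entropy, one patient bag per optimization
step, Adam (learning rate 1e-4, weight decay 1e-5), class-balanced epoch
sampling limited by the minority class, and early stopping on the validation
loss (patience 25 epochs, suppressed before a minimum number of epochs);
the best-validation-loss checkpoint is returned.

Everything here is plain NumPy: the forward pass, the hand-derived backward
pass (verified against finite differences in the test suite), and Adam.
"""
from __future__ import annotations

import copy
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import AttentionOutput, FeatureBag, TrainConfig, TrainHistory
from .features import discard_augment

__all__ = [
    "init_params",
    "gated_attention",
    "forward_bag",
    "loss_and_grads",
    "train_model",
    "predict_label",
    "AttentionMILClassifier",
]

_PARAM_KEYS = ("W1", "b1", "V", "bV", "U", "bU", "w", "bw", "Wc", "bc")


def init_params(dim: int, n_classes: int, hidden_trunk: int = 512,
                hidden_gate: int = 256,
                rng: np.random.Generator | int | None = None) -> dict:
    """Glorot-initialized parameter arrays.

    Shapes: W1 (d, h1), V/U (C, h1, h2), w (C, h2), Wc (C, h1); biases zero.
    All class branches share identical shapes.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(rng)
    d, h1, h2, C = dim, hidden_trunk, hidden_gate, n_classes

    def glorot(*shape, fan_in, fan_out):
        s = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-s, s, size=shape)

    return {
        "W1": glorot(d, h1, fan_in=d, fan_out=h1),
        "b1": np.zeros(h1),
        "V": glorot(C, h1, h2, fan_in=h1, fan_out=h2),
        "bV": np.zeros((C, h2)),
        "U": glorot(C, h1, h2, fan_in=h1, fan_out=h2),
        "bU": np.zeros((C, h2)),
        "w": glorot(C, h2, fan_in=h2, fan_out=1),
        "bw": np.zeros(C),
        "Wc": glorot(C, h1, fan_in=h1, fan_out=1),
        "bc": np.zeros(C),
    }


def _sigmoid(x):
    from scipy.special import expit
    return expit(x)


def _softmax(x, axis=-1):
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def gated_attention(hidden: np.ndarray, V: np.ndarray, bV: np.ndarray,
                    U: np.ndarray, bU: np.ndarray, w: np.ndarray,
                    bw: float = 0.0) -> np.ndarray:
    """Raw gated-attention scores for one branch.

    ``hidden`` is (n, h1); returns one finite score per tile,
    w^T (tanh(V h) * sigmoid(U h)) + bw, permutation-equivariant in tiles.
    """
    A = np.tanh(hidden @ V + bV)
    G = _sigmoid(hidden @ U + bU)
    return (A * G) @ w + bw


def _forward(X: np.ndarray, p: dict, dropout: float = 0.0,
             rng: np.random.Generator | None = None) -> dict:
    """Full forward pass; returns every intermediate needed for backward.

    Dropout (inverted scaling) is applied to the trunk output and to the
    gated product when ``dropout`` > 0 and an rng is given (training mode).
    """
    X = np.asarray(X, dtype=np.float64)
    pre1 = X @ p["W1"] + p["b1"]                        # (n, h1)
    H = np.maximum(pre1, 0.0)
    train = dropout > 0.0 and rng is not None
    if train:
        mask_h = (rng.random(H.shape) >= dropout) / (1.0 - dropout)
        H = H * mask_h
    else:
        mask_h = None
    # tensordot -> BLAS; (n, C, h2) -> (C, n, h2)
    A = np.tanh(np.tensordot(H, p["V"], axes=(1, 1)).transpose(1, 0, 2)
                + p["bV"][:, None, :])
    G = _sigmoid(np.tensordot(H, p["U"], axes=(1, 1)).transpose(1, 0, 2)
                 + p["bU"][:, None, :])
    M = A * G                                           # (C, n, h2)
    if train:
        mask_m = (rng.random(M.shape) >= dropout) / (1.0 - dropout)
        Md = M * mask_m
    else:
        mask_m, Md = None, M
    s = (Md * p["w"][:, None, :]).sum(axis=2) + p["bw"][:, None]
    attn = _softmax(s, axis=1)                          # (C, n)
    z = attn @ H                                        # (C, h1)
    logits = (z * p["Wc"]).sum(axis=1) + p["bc"]        # (C,)
    probs = _softmax(logits)
    return dict(X=X, pre1=pre1, H=H, mask_h=mask_h, A=A, G=G, M=M,
                mask_m=mask_m, Md=Md, s=s, attn=attn, z=z,
                logits=logits, probs=probs)


def forward_bag(bag: FeatureBag | np.ndarray, params: dict) -> AttentionOutput:
    """Evaluate one bag: per-class attention weights and class probabilities.

    Invariant to tile permutation and to duplicating every tile (weights
    halve, the weighted average is unchanged).
    """
    X = bag.features if isinstance(bag, FeatureBag) else np.asarray(bag)
    if X.shape[1] != params["W1"].shape[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} != model dim {params['W1'].shape[0]}")
    c = _forward(X, params)
    return AttentionOutput(attention=c["attn"], probabilities=c["probs"],
                           scores=c["logits"])


def loss_and_grads(params: dict, X: np.ndarray, y: int, dropout: float = 0.0,
                   rng: np.random.Generator | None = None) -> tuple[float, dict]:
    """Cross-entropy loss for one bag and analytic gradients for all params."""
    p = params
    c = _forward(X, p, dropout=dropout, rng=rng)
    H, A, G, attn, z = c["H"], c["A"], c["G"], c["attn"], c["z"]
    logits, probs = c["logits"], c["probs"]
    C = len(probs)

    lse = np.log(np.sum(np.exp(logits - logits.max()))) + logits.max()
    loss = float(lse - logits[y])

    dlogits = probs.copy()
    dlogits[y] -= 1.0
    g = {}
    g["Wc"] = dlogits[:, None] * z
    g["bc"] = dlogits
    dz = dlogits[:, None] * p["Wc"]                     # (C, h1)
    dH = attn.T @ dz                                    # (n, h1)
    dattn = (H @ dz.T).T                                # (C, n)
    ds = attn * (dattn - (attn * dattn).sum(axis=1, keepdims=True))
    g["w"] = (c["Md"] * ds[:, :, None]).sum(axis=1)
    g["bw"] = ds.sum(axis=1)
    dMd = ds[:, :, None] * p["w"][:, None, :]           # (C, n, h2)
    dM = dMd * c["mask_m"] if c["mask_m"] is not None else dMd
    dA = dM * G
    dG = dM * A
    dpreV = dA * (1.0 - A * A)
    dpreU = dG * G * (1.0 - G)
    g["V"] = np.tensordot(H, dpreV, axes=(0, 1)).transpose(1, 0, 2)
    g["bV"] = dpreV.sum(axis=1)
    g["U"] = np.tensordot(H, dpreU, axes=(0, 1)).transpose(1, 0, 2)
    g["bU"] = dpreU.sum(axis=1)
    dH += np.tensordot(dpreV, p["V"], axes=([0, 2], [0, 2]))
    dH += np.tensordot(dpreU, p["U"], axes=([0, 2], [0, 2]))
    if c["mask_h"] is not None:
        dH = dH * c["mask_h"]
    dpre1 = dH * (c["pre1"] > 0)
    g["W1"] = c["X"].T @ dpre1
    g["b1"] = dpre1.sum(axis=0)
    return loss, g


class _Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(self, params: dict, lr: float = 1e-4, weight_decay: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k in params:
            gk = grads[k] + self.wd * params[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _bag_loss(params: dict, bag: FeatureBag, y: int) -> float:
    c = _forward(bag.features, params)
    logits = c["logits"]
    lse = np.log(np.sum(np.exp(logits - logits.max()))) + logits.max()
    return float(lse - logits[y])


def train_model(bags: Sequence[FeatureBag], labels: Sequence[int],
                train_idx: Sequence[int], val_idx: Sequence[int],
                config: TrainConfig) -> tuple[dict, TrainHistory]:
    """Train the network on one split; returns the best checkpoint + history.

    Per epoch, an equal number of patients per class (the minority-class
    count) is drawn without replacement from the training set, one bag per
    Adam step; validation loss is computed on a freshly drawn class-balanced
    subset of the validation patients each epoch.  Stops at ``max_epochs`` or
    when the validation loss has not improved for ``patience`` epochs, never
    before ``min_epochs``; the returned parameters are the checkpoint with
    the lowest validation loss seen.  Fully reproducible given
    ``config.seed``.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    train_by_class = {c: [i for i in train_idx if labels[i] == c] for c in classes}
    val_by_class = {c: [i for i in val_idx if labels[i] == c] for c in classes}
    for c in classes:
        if not train_by_class[c]:
            raise ValueError(f"class {c} absent from the training split")
        if not val_by_class[c]:
            raise ValueError(f"class {c} absent from the validation split")
    class_pos = {c: j for j, c in enumerate(classes)}

    rng = np.random.default_rng(config.seed)
    dim = bags[train_idx[0]].dim
    params = init_params(dim, len(classes), config.hidden_trunk,
                         config.hidden_gate, rng)
    opt = _Adam(params, lr=config.learning_rate, weight_decay=config.weight_decay)
    hist = TrainHistory()
    n_per_class = min(len(v) for v in train_by_class.values())
    n_val_per_class = min(len(v) for v in val_by_class.values())
    best_loss = np.inf
    best_params = copy.deepcopy(params)
    since_best = 0

    for epoch in range(1, config.max_epochs + 1):
        chosen = []
        for c in classes:
            pool = train_by_class[c]
            chosen.extend(rng.choice(pool, size=n_per_class, replace=False))
        rng.shuffle(chosen)
        epoch_loss = 0.0
        for i in chosen:
            bag = bags[i]
            if config.discard_augment_frac > 0:
                bag = discard_augment(bag, config.discard_augment_frac, rng)
            loss, grads = loss_and_grads(params, bag.features,
                                         class_pos[labels[i]],
                                         dropout=config.dropout, rng=rng)
            opt.step(params, grads)
            epoch_loss += loss
        hist.train_loss.append(epoch_loss / max(len(chosen), 1))

        val_chosen = []
        for c in classes:
            val_chosen.extend(rng.choice(val_by_class[c], size=n_val_per_class,
                                         replace=False))
        val_loss = np.mean([_bag_loss(params, bags[i], class_pos[labels[i]])
                            for i in val_chosen])
        hist.val_loss.append(float(val_loss))

        if val_loss < best_loss:
            best_loss = float(val_loss)
            best_params = copy.deepcopy(params)
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
        if epoch >= config.min_epochs and since_best >= config.patience:
            hist.stop_reason = "early_stop"
            break
    else:
        hist.stop_reason = "max_epochs"
    return best_params, hist


def predict_label(probs: np.ndarray) -> int:
    """Argmax decision; exact ties resolve to the lowest class index."""
    probs = np.asarray(probs)
    if probs.ndim != 1 or not np.all(probs >= 0) or abs(probs.sum() - 1) > 1e-6:
        raise ValueError("not a valid probability vector")
    return int(np.argmax(probs))


class AttentionMILClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn-style front end to the gated-attention MIL network.

    ``X`` is a list of bags — :class:`FeatureBag` objects or plain
    (n_tiles, d) arrays — and ``y`` the slide-level labels.  When no
    validation set is passed to :meth:`fit`, a stratified ``val_fraction`` of
    the training bags is held out for early stopping.

    Parameters mirror :class:`TrainConfig`; fitted attributes are
    ``classes_``, ``params_`` (the best-validation checkpoint) and
    ``history_``.
    """

    def __init__(self, hidden_trunk: int = 512, hidden_gate: int = 256,
                 dropout: float = 0.25, learning_rate: float = 1e-4,
                 weight_decay: float = 1e-5, max_epochs: int = 400,
                 min_epochs: int = 100, patience: int = 25,
                 discard_augment_frac: float = 0.0, val_fraction: float = 0.1,
                 random_state: int | None = None):
        self.hidden_trunk = hidden_trunk
        self.hidden_gate = hidden_gate
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.min_epochs = min_epochs
        self.patience = patience
        self.discard_augment_frac = discard_augment_frac
        self.val_fraction = val_fraction
        self.random_state = random_state

    @staticmethod
    def _as_bags(X) -> list[FeatureBag]:
        bags = []
        for i, x in enumerate(X):
            if isinstance(x, FeatureBag):
                bags.append(x)
            else:
                arr = np.asarray(x, dtype=np.float64)
                tiles = None
                from .datatypes import TileRef
                tiles = [TileRef(slide_id=f"bag{i}", magnification="40x",
                                 grid_xy=(k, 0), origin_level0=(k * 256, 0))
                         for k in range(len(arr))]
                bags.append(FeatureBag(patient_id=f"bag{i}", features=arr,
                                       tiles=tiles))
        return bags

    def _config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, weight_decay=self.weight_decay,
            max_epochs=self.max_epochs, min_epochs=self.min_epochs,
            patience=self.patience, hidden_trunk=self.hidden_trunk,
            hidden_gate=self.hidden_gate, dropout=self.dropout,
            discard_augment_frac=self.discard_augment_frac,
            seed=0 if self.random_state is None else int(self.random_state),
        )

    def fit(self, X, y, X_val=None, y_val=None):
        bags = self._as_bags(X)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        enc = {c: j for j, c in enumerate(self.classes_)}
        y_idx = np.array([enc[v] for v in y])

        if X_val is not None:
            vbags = self._as_bags(X_val)
            yv = np.array([enc[v] for v in np.asarray(y_val)])
            all_bags = bags + vbags
            all_y = np.concatenate([y_idx, yv])
            train_idx = list(range(len(bags)))
            val_idx = list(range(len(bags), len(all_bags)))
        else:
            rng = np.random.default_rng(self._config().seed)
            train_idx, val_idx = [], []
            for c in range(len(self.classes_)):
                idx = np.flatnonzero(y_idx == c)
                idx = rng.permutation(idx)
                n_val = max(1, int(round(self.val_fraction * len(idx))))
                if n_val >= len(idx):
                    raise ValueError(f"class {self.classes_[c]} too small to "
                                     "hold out validation bags")
                val_idx.extend(idx[:n_val])
                train_idx.extend(idx[n_val:])
            all_bags, all_y = bags, y_idx

        self.params_, self.history_ = train_model(
            all_bags, all_y, train_idx, val_idx, self._config())
        self.n_features_in_ = all_bags[0].dim
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        return np.stack([forward_bag(b, self.params_).probabilities
                         for b in self._as_bags(X)])

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    def attention(self, bag) -> AttentionOutput:
        """Per-class attention weights and probabilities for one bag."""
        check_is_fitted(self, "params_")
        return forward_bag(self._as_bags([bag])[0], self.params_)
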