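"""Shallow feed-forward fissure classifier and its averaging ensemble.

Architecture: input layer (one node per texture feature), one dense
hidden layer of five tanh units, and a two-node softmax output layer.
Each network is trained full-batch by gradient descent with momentum and
an adaptive learning rate: after every epoch the step is rejected (and
the learning rate decreased) if the training loss grew by more than a
tolerated factor, otherwise accepted, with the rate increased on
improvement.  The weights from the first epoch achieving the minimum
early-stop-set loss are returned.

The ensemble averages the fissure-class probability of many members that
differ only in their initialization (and early-stop split) seeds; member
``i`` uses seed ``base_seed + i``, so predictions are reproducible.
Features are z-scored with statistics estimated from the ensemble's
training data and stored on the model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "NetworkWeights",
    "TrainConfig",
    "EnsembleModel",
    "forward",
    "train",
    "train_ensemble",
    "ensemble_predict",
    "ensemble_logit",
    "classify",
]

N_HIDDEN = 5


@dataclass
class NetworkWeights:
    """Weights of one input->5 tanh->2 softmax network."""

    W1: np.ndarray  # (n_in, 5)
    b1: np.ndarray  # (5,)
    W2: np.ndarray  # (5, 2)
    b2: np.ndarray  # (2,)

    @property
    def n_in(self) -> int:
        return self.W1.shape[0]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.W1.copy(), self.b1.copy(),
                              self.W2.copy(), self.b2.copy())

    @classmethod
    def init(cls, n_in: int, rng: np.random.Generator) -> "NetworkWeights":
        # uniform +-1/sqrt(fan_in)
        lim1 = 1.0 / np.sqrt(n_in)
        lim2 = 1.0 / np.sqrt(N_HIDDEN)
        return cls(
            W1=rng.uniform(-lim1, lim1, size=(n_in, N_HIDDEN)),
            b1=rng.uniform(-lim1, lim1, size=N_HIDDEN),
            W2=rng.uniform(-lim2, lim2, size=(N_HIDDEN, 2)),
            b2=rng.uniform(-lim2, lim2, size=2),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent-with-momentum / adaptive-learning-rate settings."""

    max_epochs: int = 5000
    lr0: float = 0.01
    momentum: float = 0.9
    lr_inc: float = 1.05
    lr_dec: float = 0.7
    max_perf_inc: float = 1.04
    standardize: bool = True
    early_stop_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.momentum < 1.0:
            raise ValueError("momentum must be in (0, 1)")
        if not (self.lr_inc > 1.0 > self.lr_dec > 0.0):
            raise ValueError("need lr_inc > 1 > lr_dec > 0")
        if self.max_epochs < 1 or self.lr0 <= 0:
            raise ValueError("max_epochs >= 1 and lr0 > 0 required")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(x: np.ndarray, w: NetworkWeights) -> np.ndarray:
    """Class probabilities ``(P(no fissure), P(fissure))`` for input(s) x.

    ``x`` is a standardized feature vector (or an ``(n, n_in)`` batch);
    h = tanh(x W1 + b1), output = softmax(h W2 + b2).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != w.n_in:
        raise ValueError(f"input has {X.shape[1]} features, network expects "
                         f"{w.n_in}")
    h = np.tanh(X @ w.W1 + w.b1)
    p = _softmax(h @ w.W2 + w.b2)
    return p[0] if single else p


def _loss(X: np.ndarray, Y: np.ndarray, w: NetworkWeights) -> float:
    p = forward(X, w)
    return float(-np.mean(np.sum(Y * np.log(np.clip(p, 1e-12, None)), axis=1)))


def _grad(X: np.ndarray, Y: np.ndarray, w: NetworkWeights):
    n = X.shape[0]
    h = np.tanh(X @ w.W1 + w.b1)
    p = _softmax(h @ w.W2 + w.b2)
    dz2 = (p - Y) / n
    gW2 = h.T @ dz2
    gb2 = dz2.sum(axis=0)
    dh = dz2 @ w.W2.T * (1.0 - h * h)
    gW1 = X.T @ dh
    gb1 = dh.sum(axis=0)
    return gW1, gb1, gW2, gb2


def _one_hot(y: np.ndarray) -> np.ndarray:
    Y = np.zeros((y.size, 2))
    Y[np.arange(y.size), y.astype(int)] = 1.0
    return Y


def train(X: np.ndarray, y: np.ndarray,
          X_val: np.ndarray, y_val: np.ndarray,
          cfg: TrainConfig,
          return_history: bool = False):
    """Train one network; return the first-best-validation weights.

    Full-batch gradient descent with momentum (``v <- m v - lr grad``,
    ``w <- w + v``).  After each epoch, if the training loss grew by a
    factor above ``max_perf_inc`` the step is reverted, the momentum
    buffer cleared and the learning rate multiplied by ``lr_dec``;
    otherwise the step is accepted and the rate multiplied by ``lr_inc``
    when the loss improved.  The early-stop set is scored every epoch and
    the weights of the FIRST epoch reaching its minimum loss are
    returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.shape[0] == 0 or np.asarray(X_val).shape[0] == 0:
        raise ValueError("training and early-stop sets must be nonempty")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    Y = _one_hot(y)
    Xv = np.asarray(X_val, dtype=float)
    Yv = _one_hot(np.asarray(y_val).astype(int))

    rng = np.random.default_rng(cfg.seed)
    w = NetworkWeights.init(X.shape[1], rng)
    v = [np.zeros_like(a) for a in (w.W1, w.b1, w.W2, w.b2)]
    lr = cfg.lr0
    loss = _loss(X, Y, w)
    best_val = _loss(Xv, Yv, w)
    best_w = w.copy()
    history = {"train": [loss], "val": [best_val], "accepted": []}

    for _ in range(cfg.max_epochs):
        g = _grad(X, Y, w)
        prev = w.copy()
        prev_v = [a.copy() for a in v]
        for buf, grad_a in zip(v, g):
            buf *= cfg.momentum
            buf -= lr * grad_a
        w.W1 += v[0]
        w.b1 += v[1]
        w.W2 += v[2]
        w.b2 += v[3]
        new_loss = _loss(X, Y, w)
        if new_loss > loss * cfg.max_perf_inc:
            w = prev
            v = [np.zeros_like(a) for a in prev_v]
            lr *= cfg.lr_dec
            history["accepted"].append(False)
            if lr < 1e-14:
                break
            continue
        if new_loss < loss:
            lr *= cfg.lr_inc
        loss = new_loss
        history["accepted"].append(True)
        history["train"].append(loss)
        val_loss = _loss(Xv, Yv, w)
        history["val"].append(val_loss)
        if val_loss < best_val - 1e-15:
            best_val = val_loss
            best_w = w.copy()

    if return_history:
        return best_w, history
    return best_w


@dataclass
class EnsembleModel:
    """An averaging ensemble of shallow networks plus its standardization."""

    members: List[NetworkWeights]
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    registry_fingerprint: str = ""
    threshold: float = 0.5

    def __post_init__(self):
        if not self.members:
            raise ValueError("ensemble must have at least one member")
        n_in = self.members[0].n_in
        if any(m.n_in != n_in for m in self.members):
            raise ValueError("all members must share the same input size")

    @property
    def n_in(self) -> int:
        return self.members[0].n_in

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_mean) / self.feature_sd

    # -- serialization ------------------------------------------------------
    def to_json(self) -> dict:
        return {
            "members": [{k: getattr(m, k).tolist()
                         for k in ("W1", "b1", "W2", "b2")}
                        for m in self.members],
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "registry_fingerprint": self.registry_fingerprint,
            "threshold": self.threshold,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_json()))

    @classmethod
    def from_json(cls, obj: dict) -> "EnsembleModel":
        members = [NetworkWeights(**{k: np.asarray(m[k]) for k in
                                     ("W1", "b1", "W2", "b2")})
                   for m in obj["members"]]
        return cls(members=members,
                   feature_mean=np.asarray(obj["feature_mean"]),
                   feature_sd=np.asarray(obj["feature_sd"]),
                   registry_fingerprint=obj.get("registry_fingerprint", ""),
                   threshold=float(obj.get("threshold", 0.5)))

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        return cls.from_json(json.loads(Path(path).read_text()))


def _inner_split(n: int, y: np.ndarray, fraction: float,
                 rng: np.random.Generator):
    """Class-stratified inner train/early-stop split."""
    idx = np.arange(n)
    val: List[int] = []
    for cls in np.unique(y):
        members = idx[y == cls]
        # at least one member of every class stays in the training set
        k = min(max(1, int(round(fraction * members.size))),
                members.size - 1)
        if k > 0:
            val.extend(rng.choice(members, size=k, replace=False))
    val_idx = np.array(sorted(val))
    tr_idx = np.setdiff1d(idx, val_idx)
    return tr_idx, val_idx


def train_ensemble(X: np.ndarray, y: np.ndarray, size: int,
                   cfg: Optional[TrainConfig] = None,
                   base_seed: int = 0,
                   X_val: Optional[np.ndarray] = None,
                   y_val: Optional[np.ndarray] = None,
                   registry_fingerprint: str = "") -> EnsembleModel:
    """Train an ensemble of ``size`` members with seeds ``base_seed + i``.

    By default each member carves its own stratified 20% early-stop split
    out of the training data; passing ``X_val``/``y_val`` instead uses
    that fixed set for every member (the "paper-faithful" mode where the
    held-out fold doubles as the early-stop set).
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mean) / sd if cfg.standardize else X
    if not cfg.standardize:
        mean, sd = np.zeros(X.shape[1]), np.ones(X.shape[1])
    fixed_val = X_val is not None
    if fixed_val:
        Xvs = (np.asarray(X_val, dtype=float) - mean) / sd
        yv = np.asarray(y_val).astype(int)

    members = []
    for i in range(size):
        member_seed = base_seed + i
        mcfg = replace(cfg, seed=member_seed)
        if fixed_val:
            members.append(train(Xs, y, Xvs, yv, mcfg))
        else:
            rng = np.random.default_rng((member_seed, 1))
            tr, va = _inner_split(len(y), y, cfg.early_stop_fraction, rng)
            members.append(train(Xs[tr], y[tr], Xs[va], y[va], mcfg))
    return EnsembleModel(members=members, feature_mean=mean, feature_sd=sd,
                         registry_fingerprint=registry_fingerprint)


def ensemble_predict(x: np.ndarray, model: EnsembleModel) -> np.ndarray:
    """Mean fissure-class probability over all ensemble members.

    Accepts a single raw (unstandardized) feature vector or a batch;
    returns a scalar or an ``(n,)`` array.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Xs = model.standardize(np.atleast_2d(x))
    probs = np.mean([forward(Xs, m)[:, 1] for m in model.members], axis=0)
    return float(probs[0]) if single else probs


def ensemble_logit(x: np.ndarray, model: EnsembleModel) -> np.ndarray:
    """Mean fissure log-odds (pre-softmax score difference) over members.

    The softmax pair is monotone in ``z1 - z0``, so this is the same
    classification score on a scale that never saturates -- useful when
    probing a confident ensemble (p ~= 1) with small perturbations.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Xs = model.standardize(np.atleast_2d(x))
    logits = []
    for m in model.members:
        h = np.tanh(Xs @ m.W1 + m.b1)
        z = h @ m.W2 + m.b2
        logits.append(z[:, 1] - z[:, 0])
    out = np.mean(logits, axis=0)
    return float(out[0]) if single else out


def classify(prob, threshold: float = 0.5):
    """Dichotomize a fissure probability; the boundary counts as positive."""
    p = np.asarray(prob, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = p >= threshold
    return bool(out) if out.ndim == 0 else out
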