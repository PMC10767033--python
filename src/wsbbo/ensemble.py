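"""Ensembles of sequence-activity classifiers trained on subsampled splits.

Each of the k training splits (all positives + one fifth of the
negatives) trains one binary classifier mapping a fixed-length amino-acid
sequence to the probability of the positive (binding) class.  The
ensemble exposes, per query sequence, the mean of the k predicted
probabilities (the activity estimate) and their standard deviation (the
prediction instability).

Two architectures share the interface:

``logistic``
    A linear classifier on the flattened one-hot encoding, trained by
    full-batch Adam on the cross-entropy loss.  Deterministic (zero
    initialization), fast, and the default for desk-scale runs.

``birnn``
    A bidirectional vanilla recurrent network over the one-hot residue
    sequence (shared input weights, tanh hidden units, hidden size 10 by
    default); the two final hidden states feed a logistic output unit.
    Trained by full-batch Adam with manual backpropagation through time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA20, one_hot, one_hot_flat
from .enrichment import LabeledDataset, TrainingSplit

__all__ = [
    "PredictorConfig",
    "PredictorEnsemble",
    "train_member",
    "train_ensemble",
    "ensemble_predict",
]


@dataclass
class PredictorConfig:
    """Hyperparameters for one ensemble member.

    Defaults follow the reference protocol for the recurrent net: one
    hidden layer of size 10, 25 epochs, learning rate 1e-3, one-hot
    sequence encoding.
    """

    hidden_size: int = 10
    epochs: int = 25
    learning_rate: float = 0.001
    encoding: str = "one_hot"
    architecture: str = "logistic"
    seed: int = 0
    alphabet: str = AA20
    l2: float = 0.0   # weight decay; tempers over-confident probabilities

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.encoding != "one_hot":
            raise ValueError(f"unsupported encoding {self.encoding!r}")
        if self.architecture not in {"logistic", "birnn"}:
            raise ValueError(f"unsupported architecture {self.architecture!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))


class _Adam:
    """Minimal Adam optimizer over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class LogisticPredictor:
    """Linear classifier on the flattened one-hot encoding."""

    def __init__(self, config: PredictorConfig, sequence_length: int):
        self.config = config
        self.sequence_length = sequence_length
        n_features = sequence_length * len(config.alphabet)
        self.w = np.zeros(n_features)
        self.b = 0.0
        self.trained = False

    def fit(self, sequences: list[str], labels: np.ndarray) -> "LogisticPredictor":
        X = one_hot_flat(sequences, self.config.alphabet)
        y = np.asarray(labels, dtype=float)
        w, b = self.w, np.zeros(1)
        opt = _Adam([w, b], self.config.learning_rate)
        for _ in range(self.config.epochs):
            p = _sigmoid(X @ w + b[0])
            err = p - y
            opt.step([X.T @ err / len(y) + self.config.l2 * w,
                      np.array([err.mean()])])
        self.b = float(b[0])
        self.trained = True
        return self

    def predict_proba(self, sequences: list[str]) -> np.ndarray:
        self._check(sequences)
        X = one_hot_flat(sequences, self.config.alphabet)
        return _sigmoid(X @ self.w + self.b)

    def _check(self, sequences: list[str]) -> None:
        for s in sequences:
            if len(s) != self.sequence_length:
                raise ValueError(
                    f"sequence length {len(s)} != model length {self.sequence_length}"
                )

    def state(self) -> dict[str, np.ndarray]:
        return {"w": self.w, "b": np.array([self.b])}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.w = np.asarray(state["w"])
        self.b = float(np.asarray(state["b"])[0])
        self.trained = True


class BiRNNPredictor:
    """Bidirectional vanilla RNN with a logistic output unit.

    Forward and backward passes share the input projection shape but not
    weights; hidden update h_t = tanh(Wx x_t + Wh h_{t-1} + bh).  The
    concatenated final hidden states of the two directions feed a single
    sigmoid output.  Gradients are computed by backpropagation through
    time and applied full-batch with Adam.
    """

    def __init__(self, config: PredictorConfig, sequence_length: int):
        self.config = config
        self.sequence_length = sequence_length
        A, H = len(config.alphabet), config.hidden_size
        rng = np.random.default_rng(config.seed)
        scale = 1.0 / np.sqrt(max(A, H))
        self.params = {
            "Wx_f": rng.normal(0, scale, (A, H)), "Wh_f": rng.normal(0, scale, (H, H)),
            "bh_f": np.zeros(H),
            "Wx_b": rng.normal(0, scale, (A, H)), "Wh_b": rng.normal(0, scale, (H, H)),
            "bh_b": np.zeros(H),
            "Wo": rng.normal(0, scale, 2 * H), "bo": np.zeros(1),
        }
        self.trained = False

    def _encode(self, sequences: list[str]) -> np.ndarray:
        self._check(sequences)
        return np.stack([one_hot(s, self.config.alphabet) for s in sequences])

    def _check(self, sequences: list[str]) -> None:
        for s in sequences:
            if len(s) != self.sequence_length:
                raise ValueError(
                    f"sequence length {len(s)} != model length {self.sequence_length}"
                )

    def _run_direction(self, X: np.ndarray, suffix: str) -> tuple[np.ndarray, list]:
        """Run one direction; X is (n, L, A) already time-ordered."""
        p = self.params
        Wx, Wh, bh = p[f"Wx_{suffix}"], p[f"Wh_{suffix}"], p[f"bh_{suffix}"]
        n, L, _ = X.shape
        h = np.zeros((n, Wh.shape[0]))
        cache = []
        for t in range(L):
            pre = X[:, t] @ Wx + h @ Wh + bh
            h_new = np.tanh(pre)
            cache.append((h, h_new, X[:, t]))
            h = h_new
        return h, cache

    def _forward(self, X: np.ndarray):
        hf, cf = self._run_direction(X, "f")
        hb, cb = self._run_direction(X[:, ::-1], "b")
        feats = np.concatenate([hf, hb], axis=1)
        prob = _sigmoid(feats @ self.params["Wo"] + self.params["bo"][0])
        return prob, feats, cf, cb

    def fit(self, sequences: list[str], labels: np.ndarray) -> "BiRNNPredictor":
        X = self._encode(sequences)
        y = np.asarray(labels, dtype=float)
        p = self.params
        names = list(p)
        opt = _Adam([p[k] for k in names], self.config.learning_rate)
        H = self.config.hidden_size
        for _ in range(self.config.epochs):
            prob, feats, cf, cb = self._forward(X)
            delta = (prob - y) / len(y)          # d loss / d logit
            grads = {k: np.zeros_like(v) for k, v in p.items()}
            grads["Wo"] = feats.T @ delta
            grads["bo"] = np.array([delta.sum()])
            dfeat = np.outer(delta, p["Wo"])
            self._backward_direction(dfeat[:, :H], cf, "f", grads)
            self._backward_direction(dfeat[:, H:], cb, "b", grads)
            opt.step([grads[k] for k in names])
        self.trained = True
        return self

    def _backward_direction(self, dh: np.ndarray, cache: list, suffix: str,
                            grads: dict[str, np.ndarray]) -> None:
        p = self.params
        Wh = p[f"Wh_{suffix}"]
        for h_prev, h_new, x_t in reversed(cache):
            dpre = dh * (1 - h_new ** 2)
            grads[f"Wx_{suffix}"] += x_t.T @ dpre
            grads[f"Wh_{suffix}"] += h_prev.T @ dpre
            grads[f"bh_{suffix}"] += dpre.sum(axis=0)
            dh = dpre @ Wh.T

    def predict_proba(self, sequences: list[str]) -> np.ndarray:
        X = self._encode(sequences)
        prob, *_ = self._forward(X)
        return prob

    def state(self) -> dict[str, np.ndarray]:
        return dict(self.params)

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        self.params = {k: np.asarray(v) for k, v in state.items()}
        self.trained = True


_ARCHITECTURES = {"logistic": LogisticPredictor, "birnn": BiRNNPredictor}


def train_member(split: TrainingSplit, config: PredictorConfig,
                 sequence_length: int | None = None):
    """Train one classifier on one subsampled split.

    The split must contain both classes; training is deterministic given
    ``config.seed``.
    """
    if not split.positives or not split.negatives:
        raise ValueError("training split must contain both classes")
    if sequence_length is None:
        sequence_length = len(split.sequences[0])
    model = _ARCHITECTURES[config.architecture](config, sequence_length)
    return model.fit(split.sequences, split.labels)


@dataclass
class PredictorEnsemble:
    """k trained classifiers over a common alphabet and sequence length."""

    members: list = field(default_factory=list)
    alphabet: str = AA20
    sequence_length: int = 0

    @property
    def k(self) -> int:
        return len(self.members)

    def predict_matrix(self, sequences: list[str]) -> np.ndarray:
        """(k, n) matrix of member probabilities."""
        if not self.members:
            raise ValueError("ensemble has no trained members")
        return np.stack([m.predict_proba(sequences) for m in self.members])


def train_ensemble(dataset: LabeledDataset, config: PredictorConfig) -> PredictorEnsemble:
    """Train one member per split of *dataset* (seeds derived per member)."""
    if not dataset.splits:
        raise ValueError("dataset has no splits; call split_negatives first")
    length = len(dataset.splits[0].sequences[0])
    members = []
    for i, split in enumerate(dataset.splits):
        cfg = PredictorConfig(**{**config.__dict__, "seed": config.seed + i})
        members.append(train_member(split, cfg, length))
    return PredictorEnsemble(members=members, alphabet=config.alphabet,
                             sequence_length=length)


def ensemble_predict(
    ensemble: PredictorEnsemble, sequence: str, sample_std: bool = False
) -> tuple[float, float]:
    """Mean and standard deviation of the member probabilities for one sequence.

    The population form (divisor k) is the default; ``sample_std=True``
    switches to divisor k-1.
    """
    probs = ensemble.predict_matrix([sequence])[:, 0]
    ddof = 1 if sample_std else 0
    return float(probs.mean()), float(probs.std(ddof=ddof))
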