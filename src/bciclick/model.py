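"""Many-to-one LSTM-FC rest/grasp classifier.

One second of feature history (10 frames x channels) feeds an LSTM with
25 hidden units, then two fully connected layers (10 units, eLU; 2 units,
softmax).  Training uses categorical cross-entropy, Adam, 45-sample
batches, 75 epochs, 30% dropout on the LSTM and FC1 outputs, and
He-normal initialization of every weight matrix.

The network is small (~16k parameters) so forward, backpropagation
through time, and input gradients (needed for integrated-gradients
saliency) are implemented directly in NumPy.  With the stated layer sizes
and a standard single-bias LSTM the trainable parameter count is
4*((d+h)*h + h) + (h*f1 + f1) + (f1*2 + 2) = 15,682 at d=128, h=25,
f1=10.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

SERIALIZATION_VERSION = 1


@dataclass
class ModelConfig:
    input_dim: int = 128
    seq_len: int = 10
    lstm_units: int = 25
    fc1_units: int = 10
    out_units: int = 2
    dropout: float = 0.30
    epochs: int = 75
    batch_size: int = 45
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seq_len < 1 or self.input_dim < 1:
            raise ValueError("invalid input dimensions")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.out_units != 2:
            raise ValueError("binary rest/grasp head expects 2 output units")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class LSTMClassifier:
    """The trainable network.  Gate layout along the 4H axis: i, f, g, o."""

    PARAM_NAMES = ("Wx", "Wh", "b", "W1", "b1", "W2", "b2")

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        d, h, f1, k = cfg.input_dim, cfg.lstm_units, cfg.fc1_units, cfg.out_units
        rng = np.random.default_rng(cfg.seed)

        def he(shape):
            return rng.normal(0.0, np.sqrt(2.0 / shape[0]), size=shape)

        self.params = {
            "Wx": he((d, 4 * h)),
            "Wh": he((h, 4 * h)),
            "b": np.zeros(4 * h),
            "W1": he((h, f1)),
            "b1": np.zeros(f1),
            "W2": he((f1, k)),
            "b2": np.zeros(k),
        }
        self.epoch_losses: list[float] = []
        self.metadata: dict = {"seed": cfg.seed}

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # ------------------------------------------------------------------ forward

    def _forward(self, X: np.ndarray, drop_rng: np.random.Generator | None = None):
        """X: (B, T, D).  Returns (probs, logits, cache)."""
        cfg = self.cfg
        if X.ndim == 2:
            X = X[None]
        B, T, D = X.shape
        if T != cfg.seq_len or D != cfg.input_dim:
            raise ValueError(
                f"expected input ({cfg.seq_len}, {cfg.input_dim}), got ({T}, {D})"
            )
        p = self.params
        h = cfg.lstm_units
        hs = np.zeros((T + 1, B, h))
        cs = np.zeros((T + 1, B, h))
        gates = np.empty((T, B, 4 * h))
        for t in range(T):
            z = X[:, t] @ p["Wx"] + hs[t] @ p["Wh"] + p["b"]
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            cs[t + 1] = f * cs[t] + i * g
            hs[t + 1] = o * np.tanh(cs[t + 1])
            gates[t] = np.concatenate([i, f, g, o], axis=1)
        hT = hs[T]
        if drop_rng is not None and cfg.dropout > 0:
            m1 = (drop_rng.uniform(size=hT.shape) >= cfg.dropout) / (1 - cfg.dropout)
        else:
            m1 = np.ones_like(hT)
        hd = hT * m1
        a1 = hd @ p["W1"] + p["b1"]
        z1 = _elu(a1)
        if drop_rng is not None and cfg.dropout > 0:
            m2 = (drop_rng.uniform(size=z1.shape) >= cfg.dropout) / (1 - cfg.dropout)
        else:
            m2 = np.ones_like(z1)
        zd = z1 * m2
        logits = zd @ p["W2"] + p["b2"]
        cache = dict(X=X, hs=hs, cs=cs, gates=gates, m1=m1, hd=hd, a1=a1, z1=z1, m2=m2, zd=zd)
        return _softmax(logits), logits, cache

    def _backward(self, cache: dict, dlogits: np.ndarray):
        """Gradients of sum(dlogits * logits) w.r.t. params and inputs."""
        cfg = self.cfg
        p = self.params
        h = cfg.lstm_units
        X, hs, cs, gates = cache["X"], cache["hs"], cache["cs"], cache["gates"]
        B, T, _ = X.shape
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["W2"] = cache["zd"].T @ dlogits
        grads["b2"] = dlogits.sum(axis=0)
        dz1 = (dlogits @ p["W2"].T) * cache["m2"]
        da1 = dz1 * np.where(cache["a1"] > 0, 1.0, cache["z1"] + 1.0)  # eLU'
        grads["W1"] = cache["hd"].T @ da1
        grads["b1"] = da1.sum(axis=0)
        dh = (da1 @ p["W1"].T) * cache["m1"]
        dc = np.zeros((B, h))
        dX = np.zeros_like(X)
        for t in range(T - 1, -1, -1):
            i, f, g, o = (gates[t][:, j * h : (j + 1) * h] for j in range(4))
            tc = np.tanh(cs[t + 1])
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di = dc * g
            dg = dc * i
            df = dc * cs[t]
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            grads["Wx"] += X[:, t].T @ dz
            grads["Wh"] += hs[t].T @ dz
            grads["b"] += dz.sum(axis=0)
            dX[:, t] = dz @ p["Wx"].T
            dh = dz @ p["Wh"].T
            dc = dc * f
        return grads, dX

    # ---------------------------------------------------------------- inference

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs, _, _ = self._forward(np.asarray(X, dtype=np.float64))
        return probs

    def score(self, X: np.ndarray, class_idx: int = 1, target: str = "logit") -> np.ndarray:
        """Per-sample class score: pre-softmax logit (default) or probability."""
        probs, logits, _ = self._forward(np.asarray(X, dtype=np.float64))
        out = logits if target == "logit" else probs
        return out[:, class_idx]

    def input_gradient(
        self, X: np.ndarray, class_idx: int = 1, target: str = "logit"
    ) -> np.ndarray:
        """d score / d input, evaluated without dropout.  X: (B, T, D) or (T, D)."""
        X = np.asarray(X, dtype=np.float64)
        squeeze = X.ndim == 2
        probs, _, cache = self._forward(X)
        B = cache["X"].shape[0]
        dlogits = np.zeros((B, self.cfg.out_units))
        if target == "logit":
            dlogits[:, class_idx] = 1.0
        elif target == "prob":
            # d softmax_c / d logits = p_c * (onehot_c - p)
            pc = probs[:, class_idx]
            dlogits = -probs * pc[:, None]
            dlogits[:, class_idx] += pc
        else:
            raise ValueError("target must be 'logit' or 'prob'")
        _, dX = self._backward(cache, dlogits)
        return dX[0] if squeeze else dX

    # ----------------------------------------------------------------- training

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int | None = None,
        seed: int | None = None,
    ) -> "LSTMClassifier":
        """Adam / categorical cross-entropy training with per-epoch loss log."""
        cfg = self.cfg
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        epochs = cfg.epochs if epochs is None else epochs
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        onehot = np.eye(cfg.out_units)[y]
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(val) for k, val in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(X)
        for _ in range(epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                probs, _, cache = self._forward(X[idx], drop_rng=rng)
                yb = onehot[idx]
                total += -np.sum(np.log(np.maximum((probs * yb).sum(axis=1), 1e-12)))
                dlogits = (probs - yb) / len(idx)
                grads, _ = self._backward(cache, dlogits)
                step += 1
                for k in self.params:
                    m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                    v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                    mh = m[k] / (1 - beta1**step)
                    vh = v[k] / (1 - beta2**step)
                    self.params[k] -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
            self.epoch_losses.append(total / n)
        self.metadata["n_train"] = n
        return self

    # ------------------------------------------------------------- persistence

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(
            path.with_suffix(".npz"),
            version=SERIALIZATION_VERSION,
            config=json.dumps(asdict(self.cfg)),
            metadata=json.dumps(self.metadata),
            epoch_losses=np.asarray(self.epoch_losses),
            **self.params,
        )

    @classmethod
    def load(cls, path: str | Path) -> "LSTMClassifier":
        z = np.load(Path(path).with_suffix(".npz"))
        if int(z["version"]) != SERIALIZATION_VERSION:
            raise ValueError("serialized model version mismatch")
        cfg = ModelConfig(**json.loads(str(z["config"])))
        model = cls(cfg)
        for k in cls.PARAM_NAMES:
            model.params[k] = z[k]
        model.epoch_losses = list(z["epoch_losses"])
        model.metadata = json.loads(str(z["metadata"]))
        return model


def build_model(cfg: ModelConfig) -> LSTMClassifier:
    return LSTMClassifier(cfg)


# ---------------------------------------------------------------------------
# Sequence assembly and streaming prediction


def make_sequences(X_frames: np.ndarray, indices: np.ndarray, seq_len: int) -> np.ndarray:
    """History windows ending at each index; indices earlier than seq_len-1
    cannot form a full window and are rejected."""
    indices = np.asarray(indices)
    if (indices < seq_len - 1).any():
        raise ValueError("some indices precede a full history window")
    return np.stack([X_frames[i - seq_len + 1 : i + 1] for i in indices])


def predict_stream(model: LSTMClassifier, X_frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (label, p_grasp) at the feature cadence.

    The first ``seq_len - 1`` frames predate a full history buffer and emit
    rest (p_grasp = 0) by convention.
    """
    X_frames = np.asarray(X_frames, dtype=np.float64)
    n = len(X_frames)
    L = model.cfg.seq_len
    labels = np.zeros(n, dtype=int)
    p_grasp = np.zeros(n)
    if n >= L:
        idx = np.arange(L - 1, n)
        probs = model.predict_proba(make_sequences(X_frames, idx, L))
        labels[idx] = probs.argmax(axis=1)
        p_grasp[idx] = probs[:, 1]
    return labels, p_grasp


# ---------------------------------------------------------------------------
# Cross-validation


@dataclass
class CVResult:
    accuracies: np.ndarray  # (repetitions, k)
    confusion: np.ndarray  # (2, 2) rows = true class, pooled over folds and reps
    models: list = field(default_factory=list)  # [rep][fold] trained models
    val_indices: list = field(default_factory=list)  # [fold] frame indices

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def fold_mean_accuracies(self) -> np.ndarray:
        """Per-fold accuracy averaged over repetitions."""
        return self.accuracies.mean(axis=0)


def cross_validate(
    X_frames: np.ndarray,
    labels: np.ndarray,
    folds,
    cfg: ModelConfig,
    repetitions: int = 1,
    base_seed: int = 0,
    keep_models: bool = False,
) -> CVResult:
    """The k-fold protocol: each fold validates a model trained on the rest.

    ``folds`` is a :class:`~bciclick.labeling.FoldAssignment`; samples whose
    history window would precede frame 0 are dropped from training and
    validation alike.
    """
    L = cfg.seq_len
    usable = [idx[idx >= L - 1] for idx in folds.fold_indices]
    k = len(usable)
    accs = np.zeros((repetitions, k))
    confusion = np.zeros((2, 2), dtype=int)
    models: list[list[LSTMClassifier]] = []
    for rep in range(repetitions):
        rep_models = []
        for fi in range(k):
            train_idx = np.concatenate([usable[j] for j in range(k) if j != fi])
            val_idx = usable[fi]
            seed = base_seed + 1000 * rep + fi
            model = LSTMClassifier(
                ModelConfig(**{**asdict(cfg), "seed": seed})
            )
            model.fit(
                make_sequences(X_frames, train_idx, L), labels[train_idx], seed=seed
            )
            pred = model.predict_proba(make_sequences(X_frames, val_idx, L)).argmax(axis=1)
            truth = labels[val_idx]
            accs[rep, fi] = float((pred == truth).mean())
            for t, pr in zip(truth, pred):
                confusion[t, pr] += 1
            if keep_models:
                rep_models.append(model)
        if keep_models:
            models.append(rep_models)
    return CVResult(
        accuracies=accs, confusion=confusion, models=models, val_indices=usable
    )
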