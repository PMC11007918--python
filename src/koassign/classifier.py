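"""KO / non-KO gate: architectures, training protocol, and metrics.

The production path is an MLP head over per-protein embeddings (two fully
connected layers, hidden size 100, logistic output). Two token-level
baselines are provided for comparison: an embedding -> 1-D convolution ->
max-pooling front end feeding either an LSTM layer or a single additive
attention layer. All models train with binary cross-entropy and Adam, hold
out a seeded validation split, stop early when validation loss stalls, and
return the best-on-validation parameter snapshot.

Classifier metrics (precision*/recall*/F1*) are starred to distinguish them
from the whole-pipeline metrics in :mod:`koassign.evaluation`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from .records import STANDARD_AA

logger = logging.getLogger(__name__)

__all__ = [
    "ClassifierConfig",
    "ClassifierCounts",
    "ClassifierMetrics",
    "TrainingHistory",
    "encode_sequence",
    "build_model",
    "train",
    "predict_ko",
    "predict_scores",
    "classifier_metrics",
    "counts_from_predictions",
    "save_model",
    "load_model",
]

_AA_TO_INT = {aa: i + 1 for i, aa in enumerate(STANDARD_AA)}  # A=1 ... Y=20
_CONV_KERNEL = 3
_POOL_WINDOW = 5


@dataclass(frozen=True)
class ClassifierConfig:
    architecture: str = "mlp"
    hidden_size: int = 100
    token_embed_dim: int = 128
    conv_filters: int = 64
    recurrent_units: int = 100
    max_len: int = 600
    decision_threshold: float = 0.5
    validation_fraction: float = 0.2
    patience: int = 5
    max_epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("mlp", "lstm", "attention"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def encode_sequence(sequence: str, max_len: int) -> np.ndarray:
    """Integer-encode a sequence (A=1 ... Y=20 alphabetically), 0-padded."""
    if len(sequence) > max_len:
        raise ValueError(f"sequence length {len(sequence)} exceeds max_len {max_len}")
    encoded = np.zeros(max_len, dtype=np.int64)
    for i, letter in enumerate(sequence):
        code = _AA_TO_INT.get(letter)
        if code is None:
            raise ValueError(f"invalid amino-acid letter {letter!r}")
        encoded[i] = code
    return encoded


class _Model:
    """Shared parameter-dict plumbing for the three architectures."""

    architecture: str
    input_kind: str  # "embedding" (float vectors) or "encoding" (int tokens)

    def __init__(self) -> None:
        self.params: dict[str, ad.Tensor] = {}

    def _param(self, name: str, shape, rng: np.random.Generator, fan_in: int):
        self.params[name] = ad.parameter(
            rng.standard_normal(shape) / np.sqrt(max(fan_in, 1))
        )

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = snap[k].copy()

    def forward(self, X: np.ndarray) -> ad.Tensor:
        raise NotImplementedError


class MLPModel(_Model):
    """dense(hidden, ReLU) -> dense(1, logistic) over embeddings."""

    architecture = "mlp"
    input_kind = "embedding"

    def __init__(self, input_dim: int, hidden_size: int, rng: np.random.Generator):
        super().__init__()
        self.input_dim = input_dim
        self.hidden_size = hidden_size
        self._param("W1", (input_dim, hidden_size), rng, input_dim)
        self.params["b1"] = ad.parameter(np.zeros(hidden_size))
        self._param("W2", (hidden_size, 1), rng, hidden_size)
        self.params["b2"] = ad.parameter(np.zeros(1))

    def forward(self, X: np.ndarray) -> ad.Tensor:
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"embedding dim {X.shape[1]} != model input dim {self.input_dim}"
            )
        h = ad.relu(ad.add(ad.matmul(ad.constant(X), self.params["W1"]),
                           self.params["b1"]))
        return ad.sigmoid(ad.add(ad.matmul(h, self.params["W2"]), self.params["b2"]))


class _TokenFrontEnd(_Model):
    """token embedding -> conv1d(filters, k=3, ReLU) -> max pool (w=5, s=5)."""

    input_kind = "encoding"

    def __init__(self, cfg: ClassifierConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d, f = cfg.token_embed_dim, cfg.conv_filters
        self._param("E", (21, d), rng, d)  # row 0 is the padding token
        self._param("Wc", (_CONV_KERNEL * d, f), rng, _CONV_KERNEL * d)
        self.params["bc"] = ad.parameter(np.zeros(f))

    def _front(self, tokens: np.ndarray) -> ad.Tensor:
        tokens = np.asarray(tokens, dtype=np.int64)
        if tokens.ndim != 2:
            raise ValueError("token input must be (batch, max_len)")
        T = tokens.shape[1]
        emb = ad.take(self.params["E"], tokens)  # (B, T, d)
        win_idx = np.arange(T - _CONV_KERNEL + 1)[:, None] + np.arange(_CONV_KERNEL)
        windows = ad.take(emb, win_idx, axis=1)  # (B, T', k, d)
        windows = ad.reshape(
            windows, (tokens.shape[0], win_idx.shape[0], -1)
        )
        conv = ad.relu(ad.add(ad.matmul(windows, self.params["Wc"]),
                              self.params["bc"]))  # (B, T', f)
        t_pool = win_idx.shape[0] // _POOL_WINDOW
        if t_pool < 1:
            raise ValueError("sequence too short for conv+pool front end")
        trimmed = ad.narrow(conv, 1, 0, t_pool * _POOL_WINDOW)
        stacked = ad.reshape(
            trimmed, (tokens.shape[0], t_pool, _POOL_WINDOW, self.cfg.conv_filters)
        )
        return ad.tmax(stacked, axis=2)  # (B, T_pool, f)


class LSTMModel(_TokenFrontEnd):
    architecture = "lstm"

    def __init__(self, cfg: ClassifierConfig, rng: np.random.Generator):
        super().__init__(cfg, rng)
        f, u = cfg.conv_filters, cfg.recurrent_units
        self._param("Wx", (f, 4 * u), rng, f)
        self._param("Wh", (u, 4 * u), rng, u)
        self.params["b"] = ad.parameter(np.zeros(4 * u))
        self._param("Wd", (u, 1), rng, u)
        self.params["bd"] = ad.parameter(np.zeros(1))

    def forward(self, tokens: np.ndarray) -> ad.Tensor:
        pooled = self._front(tokens)
        B, T_pool = pooled.shape[0], pooled.shape[1]
        u = self.cfg.recurrent_units
        h = ad.constant(np.zeros((B, u)))
        c = ad.constant(np.zeros((B, u)))
        for t in range(T_pool):
            x_t = ad.take(pooled, np.asarray(t), axis=1)  # (B, f)
            gates = ad.add(
                ad.add(ad.matmul(x_t, self.params["Wx"]),
                       ad.matmul(h, self.params["Wh"])),
                self.params["b"],
            )
            i = ad.sigmoid(ad.narrow(gates, 1, 0, u))
            f_g = ad.sigmoid(ad.narrow(gates, 1, u, u))
            o = ad.sigmoid(ad.narrow(gates, 1, 2 * u, u))
            c_tilde = ad.tanh(ad.narrow(gates, 1, 3 * u, u))
            c = ad.add(ad.mul(f_g, c), ad.mul(i, c_tilde))
            h = ad.mul(o, ad.tanh(c))
        return ad.sigmoid(ad.add(ad.matmul(h, self.params["Wd"]), self.params["bd"]))


class AttentionModel(_TokenFrontEnd):
    """The LSTM layer replaced by a single additive attention layer."""

    architecture = "attention"

    def __init__(self, cfg: ClassifierConfig, rng: np.random.Generator):
        super().__init__(cfg, rng)
        f, u = cfg.conv_filters, cfg.recurrent_units
        self._param("Wa", (f, u), rng, f)
        self.params["ba"] = ad.parameter(np.zeros(u))
        self._param("va", (u, 1), rng, u)
        self._param("Wd", (f, 1), rng, f)
        self.params["bd"] = ad.parameter(np.zeros(1))

    def forward(self, tokens: np.ndarray) -> ad.Tensor:
        pooled = self._front(tokens)  # (B, T_pool, f)
        scores = ad.matmul(
            ad.tanh(ad.add(ad.matmul(pooled, self.params["Wa"]), self.params["ba"])),
            self.params["va"],
        )  # (B, T_pool, 1)
        weights = ad.softmax(scores, axis=1)
        context = ad.tsum(ad.mul(weights, pooled), axis=1)  # (B, f)
        return ad.sigmoid(
            ad.add(ad.matmul(context, self.params["Wd"]), self.params["bd"])
        )


def build_model(cfg: ClassifierConfig, input_dim: int | None = None) -> _Model:
    """Construct a seeded, untrained model for ``cfg.architecture``.

    ``input_dim`` (the embedding dimension) is required for the MLP path.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.architecture == "mlp":
        if input_dim is None:
            raise ValueError("input_dim is required for the mlp architecture")
        return MLPModel(input_dim, cfg.hidden_size, rng)
    if cfg.architecture == "lstm":
        return LSTMModel(cfg, rng)
    return AttentionModel(cfg, rng)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = 0  # 0-based index into the loss lists

    @property
    def n_epochs(self) -> int:
        return len(self.val_loss)


def _bce_loss(prob: ad.Tensor, y: np.ndarray) -> ad.Tensor:
    yt = ad.constant(y.reshape(-1, 1))
    eps = ad.constant(1e-9)
    pos = ad.mul(yt, ad.log(ad.add(prob, eps)))
    neg = ad.mul(ad.sub(ad.constant(1.0), yt),
                 ad.log(ad.add(ad.sub(ad.constant(1.0), prob), eps)))
    total = ad.neg(ad.tsum(ad.add(pos, neg)))
    return ad.mul(total, ad.constant(1.0 / len(y)))


def _eval_loss(model: _Model, X: np.ndarray, y: np.ndarray) -> float:
    return float(_bce_loss(model.forward(X), y).data)


def train(
    model: _Model, X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig
) -> tuple[_Model, TrainingHistory]:
    """Train with BCE + Adam, early-stopping on a seeded validation split.

    Stops when validation loss has not improved for ``cfg.patience`` epochs
    (or at ``cfg.max_epochs``) and restores the best-on-validation snapshot.
    """
    X = np.asarray(X)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("degenerate labels: training data contains one class")
    if class_counts.min() < 2:
        raise ValueError("degenerate labels: need >= 2 examples per class")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(y))
    n_val = max(1, int(round(cfg.validation_fraction * len(y))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    optimizer = ad.Adam(model.params, lr=cfg.learning_rate)
    history = TrainingHistory()
    best_loss = np.inf
    best_snapshot = model.snapshot()
    epochs_without_improvement = 0

    for epoch in range(cfg.max_epochs):
        batch_order = rng.permutation(len(y_tr))
        epoch_losses = []
        for start in range(0, len(y_tr), cfg.batch_size):
            batch = batch_order[start : start + cfg.batch_size]
            optimizer.zero_grad()
            loss = _bce_loss(model.forward(X_tr[batch]), y_tr[batch])
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))
        val_loss = _eval_loss(model, X_val, y_val)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        logger.debug("epoch %d: train %.4f val %.4f", epoch + 1,
                     history.train_loss[-1], val_loss)
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_snapshot = model.snapshot()
            history.best_epoch = epoch
            epochs_without_improvement = 0
        else:
            epochs_without_improvement += 1
            if epochs_without_improvement >= cfg.patience:
                break

    model.restore(best_snapshot)
    logger.info("training stopped after %d epoch(s); best epoch %d (val loss %.4f)",
                history.n_epochs, history.best_epoch + 1, best_loss)
    return model, history


def predict_scores(model: _Model, X: np.ndarray) -> np.ndarray:
    """Batch of probabilities in [0, 1], one per input row."""
    return model.forward(np.asarray(X)).data.ravel()


def predict_ko(model: _Model, x: np.ndarray, threshold: float = 0.5
               ) -> tuple[float, bool]:
    """Score one embedding/encoding; KO iff score is strictly above threshold."""
    score = float(predict_scores(model, np.asarray(x)[None, :])[0])
    return score, score > threshold


@dataclass(frozen=True)
class ClassifierCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class ClassifierMetrics:
    precision_star: float
    recall_star: float
    f1_star: float


def classifier_metrics(counts: ClassifierCounts) -> ClassifierMetrics:
    """Precision*/recall*/F1* with KO as the positive class.

    An undefined metric (zero denominator) is reported as NaN and makes F1*
    NaN; precision* = recall* = 0 gives F1* = 0 (limit convention).
    """
    precision = counts.TP / (counts.TP + counts.FP) if counts.TP + counts.FP else np.nan
    recall = counts.TP / (counts.TP + counts.FN) if counts.TP + counts.FN else np.nan
    if np.isnan(precision) or np.isnan(recall):
        f1 = np.nan
    elif precision == 0.0 and recall == 0.0:
        f1 = 0.0
    else:
        f1 = 2.0 / (1.0 / recall + 1.0 / precision)
    return ClassifierMetrics(float(precision), float(recall), float(f1))


def counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ClassifierCounts:
    """Confusion counts from boolean/0-1 arrays (positive class = KO)."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have identical shape")
    return ClassifierCounts(
        TP=int(np.sum(y_true & y_pred)),
        FP=int(np.sum(~y_true & y_pred)),
        FN=int(np.sum(y_true & ~y_pred)),
        TN=int(np.sum(~y_true & ~y_pred)),
    )


def save_model(model: _Model, path: str | Path) -> None:
    """Persist parameters and architecture metadata as ``.npz``."""
    meta = {"architecture": model.architecture}
    if isinstance(model, MLPModel):
        meta.update(input_dim=model.input_dim, hidden_size=model.hidden_size)
    else:
        meta["config"] = asdict(model.cfg)
    arrays = {f"param_{k}": p.data for k, p in model.params.items()}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_model(path: str | Path) -> _Model:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        arrays = {k[6:]: np.asarray(data[k]) for k in data.files
                  if k.startswith("param_")}
    rng = np.random.default_rng(0)
    if meta["architecture"] == "mlp":
        model: _Model = MLPModel(meta["input_dim"], meta["hidden_size"], rng)
    else:
        cfg = ClassifierConfig(**meta["config"])
        model = LSTMModel(cfg, rng) if meta["architecture"] == "lstm" \
            else AttentionModel(cfg, rng)
    model.restore(arrays)
    return model
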