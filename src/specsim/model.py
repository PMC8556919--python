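"""Siamese dense network: binned spectrum -> embedding -> cosine similarity.

The base network is input -> dense(500, L1+L2) -> batch-norm -> ReLU ->
dense(500) -> batch-norm -> ReLU -> dropout(0.2) -> dense(200); the head is
the cosine of two embeddings, trained with Adam on the mean squared error
against the structural-similarity label. Implemented directly on numpy
(no GPU framework required) with full backpropagation, so training is
single-threaded and bit-reproducible under a fixed seed.

Choices the architecture description leaves open (hidden activation,
dropout placed after batch-norm, best-epoch weight restoration) are exposed
in :class:`ModelConfig`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from specsim.binning import BinnedSpectrum, BinningScheme
from specsim.labels import SimilarityLabelMatrix
from specsim.pairs import GeneratorConfig, PairGenerator, stack_batch

MODEL_FORMAT_VERSION = "specsim-model-1"


@dataclass
class ModelConfig:
    input_dim: int = 9948
    hidden_dims: list[int] = field(default_factory=lambda: [500, 500])
    embedding_dim: int = 200
    dropout_rate: float = 0.2
    l1_penalty: float = 1e-6
    l2_penalty: float = 1e-6
    learning_rate: float = 0.001
    batch_size: int = 32
    early_stop_patience: int = 5
    max_epochs: int = 100
    seed: int = 0
    activation: str = "relu"
    restore_best_weights: bool = True
    clip_predictions: bool = False

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.embedding_dim < 1 or any(h < 1 for h in self.hidden_dims):
            raise ValueError("all layer dimensions must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.l1_penalty < 0 or self.l2_penalty < 0:
            raise ValueError("penalties must be >= 0")


@dataclass
class SpectrumEmbedding:
    values: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding entries must be finite")


# ---------------------------------------------------------------------------
# layers


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, l1: float = 0.0, l2: float = 0.0):
        limit = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.l1 = l1
        self.l2 = l2
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, **_):
        return x @ self.W + self.b, x

    def backward(self, dy, cache):
        x = cache
        self.gW += x.T @ dy
        self.gb += dy.sum(axis=0)
        return dy @ self.W.T

    def reg_grad(self):
        if self.l1 or self.l2:
            self.gW += self.l1 * np.sign(self.W) + 2.0 * self.l2 * self.W

    def params(self):
        return [("W", self), ("b", self)]


class _BatchNorm:
    def __init__(self, n: int, momentum: float = 0.99, eps: float = 1e-3):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self.ggamma = np.zeros(n)
        self.gbeta = np.zeros(n)

    def forward(self, x, training=False, **_):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean) * inv_std
        return self.gamma * x_hat + self.beta, (x_hat, inv_std, training)

    def backward(self, dy, cache):
        x_hat, inv_std, training = cache
        self.ggamma += (dy * x_hat).sum(axis=0)
        self.gbeta += dy.sum(axis=0)
        if not training:
            return dy * self.gamma * inv_std
        m = dy.shape[0]
        dx_hat = dy * self.gamma
        return (
            inv_std / m * (m * dx_hat - dx_hat.sum(axis=0) - x_hat * (dx_hat * x_hat).sum(axis=0))
        )

    def params(self):
        return [("gamma", self), ("beta", self)]


class _ReLU:
    def forward(self, x, **_):
        return np.maximum(x, 0.0), x > 0

    def backward(self, dy, cache):
        return dy * cache

    def params(self):
        return []


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate

    def forward(self, x, dropout_active=False, rng=None, **_):
        if not dropout_active or self.rate <= 0.0:
            return x, None
        if rng is None:
            raise ValueError("dropout requires an rng when active")
        mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * mask, mask

    def backward(self, dy, cache):
        return dy if cache is None else dy * cache

    def params(self):
        return []


class BaseNetwork:
    """Shared encoder of the Siamese pair.

    L1/L2 regularization acts on the first dense layer only; dropout on the
    hidden layers after the first ("all but the first layer"); batch
    normalization after every dense layer except the embedding output.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.layers: list = []
        n_prev = cfg.input_dim
        for i, h in enumerate(cfg.hidden_dims):
            self.layers.append(
                _Dense(n_prev, h, rng, l1=cfg.l1_penalty if i == 0 else 0.0,
                       l2=cfg.l2_penalty if i == 0 else 0.0)
            )
            self.layers.append(_BatchNorm(h))
            self.layers.append(_ReLU())
            if i >= 1 and cfg.dropout_rate > 0:
                self.layers.append(_Dropout(cfg.dropout_rate))
            n_prev = h
        self.layers.append(_Dense(n_prev, cfg.embedding_dim, rng))

    def forward(self, x: np.ndarray, training: bool = False, dropout_active: bool = False,
                rng: np.random.Generator | None = None):
        caches = []
        out = x
        for layer in self.layers:
            out, cache = layer.forward(out, training=training,
                                       dropout_active=dropout_active or training, rng=rng)
            caches.append(cache)
        return out, caches

    def backward(self, d_out: np.ndarray, caches) -> np.ndarray:
        grad = d_out
        for layer, cache in zip(reversed(self.layers), reversed(caches)):
            grad = layer.backward(grad, cache)
        return grad

    def zero_grads(self) -> None:
        for layer in self.layers:
            for name, owner in layer.params():
                getattr(owner, "g" + name)[...] = 0.0

    def add_reg_grads(self) -> None:
        for layer in self.layers:
            if isinstance(layer, _Dense):
                layer.reg_grad()

    def param_list(self):
        out = []
        for layer in self.layers:
            for name, owner in layer.params():
                out.append((layer, name))
        return out

    def get_weights(self) -> list[np.ndarray]:
        weights = []
        for layer in self.layers:
            if isinstance(layer, _Dense):
                weights += [layer.W.copy(), layer.b.copy()]
            elif isinstance(layer, _BatchNorm):
                weights += [layer.gamma.copy(), layer.beta.copy(),
                            layer.running_mean.copy(), layer.running_var.copy()]
        return weights

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        it = iter(weights)
        for layer in self.layers:
            if isinstance(layer, _Dense):
                layer.W = np.asarray(next(it), dtype=float).copy()
                layer.b = np.asarray(next(it), dtype=float).copy()
                layer.gW = np.zeros_like(layer.W)
                layer.gb = np.zeros_like(layer.b)
            elif isinstance(layer, _BatchNorm):
                layer.gamma = np.asarray(next(it), dtype=float).copy()
                layer.beta = np.asarray(next(it), dtype=float).copy()
                layer.running_mean = np.asarray(next(it), dtype=float).copy()
                layer.running_var = np.asarray(next(it), dtype=float).copy()
                layer.ggamma = np.zeros_like(layer.gamma)
                layer.gbeta = np.zeros_like(layer.beta)


class _Adam:
    def __init__(self, net: BaseNetwork, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-7):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self) -> None:
        self.t += 1
        for layer, name in self.net.param_list():
            key = (id(layer), name)
            param = getattr(layer, name)
            grad = getattr(layer, "g" + name)
            if key not in self.m:
                self.m[key] = np.zeros_like(param)
                self.v[key] = np.zeros_like(param)
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * grad
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * grad * grad
            m_hat = self.m[key] / (1 - self.beta1 ** self.t)
            v_hat = self.v[key] / (1 - self.beta2 ** self.t)
            setattr(layer, name, param - self.lr * m_hat / (np.sqrt(v_hat) + self.eps))


# ---------------------------------------------------------------------------
# cosine head


def _cosine_forward(ea: np.ndarray, eb: np.ndarray):
    na = np.linalg.norm(ea, axis=1)
    nb = np.linalg.norm(eb, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("zero-norm embedding in cosine head")
    c = (ea * eb).sum(axis=1) / (na * nb)
    return c, (na, nb)


def _cosine_backward(dc: np.ndarray, ea, eb, na, nb, c):
    dea = dc[:, None] * (eb / (na * nb)[:, None] - (c / na**2)[:, None] * ea)
    deb = dc[:, None] * (ea / (na * nb)[:, None] - (c / nb**2)[:, None] * eb)
    return dea, deb


def score_pair(e1: SpectrumEmbedding | np.ndarray, e2: SpectrumEmbedding | np.ndarray) -> float:
    """Cosine similarity between two embeddings, reported raw in [-1, 1]."""
    a = e1.values if isinstance(e1, SpectrumEmbedding) else np.asarray(e1, dtype=float)
    b = e2.values if isinstance(e2, SpectrumEmbedding) else np.asarray(e2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("embedding length mismatch")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm embedding")
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# model


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without validation improvement."""

    def __init__(self, patience: int = 5):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = -1
        self.n_bad = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record an epoch's validation loss; returns True when training should stop."""
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
            self.n_bad = 0
        else:
            self.n_bad += 1
        return self.n_bad >= self.patience


class SiameseModel:
    """Trained (or trainable) model bundling weights, config and binning scheme."""

    def __init__(self, config: ModelConfig, binning: BinningScheme,
                 label_metadata: dict | None = None):
        if binning.n_known != config.input_dim:
            raise ValueError(
                f"binning has {binning.n_known} known bins but config.input_dim is {config.input_dim}"
            )
        self.config = config
        self.binning = binning
        self.label_metadata = label_metadata or {}
        self.training_history: list[dict] = []
        self.base = BaseNetwork(config, np.random.default_rng(config.seed))
        self.n_forward_passes = 0  # spectra pushed through the base network

    # -- inference ---------------------------------------------------------

    def _as_matrix(self, b) -> np.ndarray:
        x = b.values if isinstance(b, BinnedSpectrum) else np.asarray(b, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.config.input_dim:
            raise ValueError(f"expected input dim {self.config.input_dim}, got {x.shape[1]}")
        return x

    def embed(self, b: BinnedSpectrum | np.ndarray, dropout_active: bool = False,
              rng: np.random.Generator | None = None) -> SpectrumEmbedding:
        """Embed one binned spectrum (deterministic unless dropout_active)."""
        x = self._as_matrix(b)
        out, _ = self.base.forward(x, training=False, dropout_active=dropout_active, rng=rng)
        self.n_forward_passes += x.shape[0]
        source_id = b.source_id if isinstance(b, BinnedSpectrum) else ""
        return SpectrumEmbedding(out[0], source_id=source_id)

    def embed_many(self, binned: Sequence[BinnedSpectrum], dropout_active: bool = False,
                   rng: np.random.Generator | None = None) -> np.ndarray:
        x = np.stack([b.values for b in binned])
        out, _ = self.base.forward(self._as_matrix(x), training=False,
                                   dropout_active=dropout_active, rng=rng)
        self.n_forward_passes += x.shape[0]
        return out

    def predict_pair(self, a: BinnedSpectrum | np.ndarray, b: BinnedSpectrum | np.ndarray) -> float:
        """Full Siamese forward for one pair (both sides re-embedded)."""
        score = score_pair(self.embed(a), self.embed(b))
        if self.config.clip_predictions:
            score = min(max(score, 0.0), 1.0)
        return score


def build_model(cfg: ModelConfig, binning: BinningScheme,
                label_metadata: dict | None = None) -> SiameseModel:
    """Fresh model with seeded weight initialization."""
    return SiameseModel(cfg, binning, label_metadata)


def split_by_compound(compound_keys: Sequence[str], n_val: int, n_test: int,
                      seed: int = 0) -> tuple[list[str], list[str], list[str]]:
    """Uniform random disjoint (train, validation, test) compound-key sets."""
    keys = list(compound_keys)
    if n_val + n_test >= len(keys):
        raise ValueError("n_val + n_test must be smaller than the number of keys")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(keys))
    val = [keys[i] for i in order[:n_val]]
    test = [keys[i] for i in order[n_val:n_val + n_test]]
    train = [keys[i] for i in order[n_val + n_test:]]
    return train, val, test


def _epoch_pass(model: SiameseModel, generator: PairGenerator, optimizer: _Adam | None,
                epoch_index: int, rng: np.random.Generator | None) -> float:
    """One pass over a generator; trains when an optimizer is given. Returns MSE."""
    total_sq = 0.0
    n = 0
    training = optimizer is not None
    for batch in generator.epoch(epoch_index):
        xa, xb, y = stack_batch(batch)
        ea, ca = model.base.forward(xa, training=training, dropout_active=training, rng=rng)
        eb, cb = model.base.forward(xb, training=training, dropout_active=training, rng=rng)
        c, (na, nb) = _cosine_forward(ea, eb)
        err = c - y
        total_sq += float((err**2).sum())
        n += len(y)
        if training:
            dc = 2.0 * err / len(y)
            dea, deb = _cosine_backward(dc, ea, eb, na, nb, c)
            model.base.zero_grads()
            model.base.backward(dea, ca)
            model.base.backward(deb, cb)
            model.base.add_reg_grads()
            optimizer.step()
    return total_sq / n if n else np.nan


def train(
    model: SiameseModel,
    train_binned: Sequence[BinnedSpectrum],
    val_binned: Sequence[BinnedSpectrum],
    labels: SimilarityLabelMatrix,
    gen_cfg: GeneratorConfig | None = None,
    val_gen_cfg: GeneratorConfig | None = None,
    verbose: bool = False,
) -> SiameseModel:
    """Train with Adam on MSE; early stopping on the fixed-seed validation stream.

    Train and validation pools must not share compound keys (data-leakage
    guard). The best-validation weights are restored on stop when
    ``config.restore_best_weights`` is set.
    """
    cfg = model.config
    train_keys = {b.compound_key for b in train_binned}
    val_keys = {b.compound_key for b in val_binned}
    overlap = train_keys & val_keys
    if overlap:
        raise ValueError(f"compound keys shared between train and validation splits: {sorted(overlap)[:5]}")

    gen_cfg = gen_cfg or GeneratorConfig(batch_size=cfg.batch_size)
    if val_gen_cfg is None:
        val_gen_cfg = GeneratorConfig(
            batch_size=cfg.batch_size,
            cycles_per_epoch=10,
            augmentation_enabled=False,
            shuffle_seed=cfg.seed + 7919,
        )
    root = np.random.default_rng(cfg.seed)
    dropout_rng = np.random.default_rng(root.integers(2**63))
    train_gen_seed = int(root.integers(2**63))
    train_gen = PairGenerator(train_binned, labels, gen_cfg, seed=train_gen_seed)
    val_seed = val_gen_cfg.shuffle_seed if val_gen_cfg.shuffle_seed is not None else cfg.seed + 7919
    val_gen = PairGenerator(val_binned, labels, val_gen_cfg, seed=val_seed)

    optimizer = _Adam(model.base, cfg.learning_rate)
    stopper = EarlyStopper(cfg.early_stop_patience)
    best_weights = model.base.get_weights()
    model.training_history = []
    for epoch in range(cfg.max_epochs):
        train_loss = _epoch_pass(model, train_gen, optimizer, epoch, dropout_rng)
        # validation stream is identical every epoch (fixed seed, epoch 0)
        val_loss = _epoch_pass(model, val_gen, None, 0, None)
        model.training_history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        if verbose:
            print(f"epoch {epoch}: train MSE {train_loss:.5f}  val MSE {val_loss:.5f}")
        improved = val_loss < stopper.best_loss
        stop = stopper.update(val_loss, epoch)
        if improved:
            best_weights = model.base.get_weights()
        if stop:
            break
    if cfg.restore_best_weights:
        model.base.set_weights(best_weights)
    return model


# ---------------------------------------------------------------------------
# persistence (all-text archive: config.json, binning.json, weights.json, history.csv)


def save_model(model: SiameseModel, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = asdict(model.config)
    (path / "config.json").write_text(json.dumps(cfg, indent=1))
    model.binning.save(path / "binning.json")
    weights = [w.tolist() for w in model.base.get_weights()]
    (path / "weights.json").write_text(json.dumps(
        {"format_version": MODEL_FORMAT_VERSION, "weights": weights}
    ))
    (path / "metadata.json").write_text(json.dumps(
        {"format_version": MODEL_FORMAT_VERSION, "label_metadata": model.label_metadata}
    ))
    with open(path / "history.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["epoch", "train_loss", "val_loss"])
        writer.writeheader()
        for row in model.training_history:
            writer.writerow(row)


def load_model(path: str | Path) -> SiameseModel:
    path = Path(path)
    for required in ("config.json", "binning.json", "weights.json", "metadata.json"):
        if not (path / required).exists():
            raise FileNotFoundError(f"model archive incomplete: missing {required}")
    meta = json.loads((path / "metadata.json").read_text())
    version = meta.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model archive version {version!r} does not match supported {MODEL_FORMAT_VERSION!r}"
        )
    cfg = ModelConfig(**json.loads((path / "config.json").read_text()))
    binning = BinningScheme.load(path / "binning.json")
    model = SiameseModel(cfg, binning, meta.get("label_metadata"))
    payload = json.loads((path / "weights.json").read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("weights file version mismatch")
    model.base.set_weights([np.asarray(w, dtype=float) for w in payload["weights"]])
    history_path = path / "history.csv"
    if history_path.exists():
        with open(history_path) as fh:
            model.training_history = [
                {"epoch": int(r["epoch"]), "train_loss": float(r["train_loss"]),
                 "val_loss": float(r["val_loss"])}
                for r in csv.DictReader(fh)
            ]
    return model
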