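"""Block-structured convolutional network: build, train, predict.

The network stacks ``n_blocks`` convolutional blocks — conv (no padding),
batch-norm, ReLU; conv ('same' padding), batch-norm, ReLU; max-pool; dropout —
followed by a flattening layer and a dense head.  Filters start at
``base_filters`` in block 1 and double with every added block.  Training
minimizes cross-entropy with early stopping on validation loss: if the loss
does not reach a new minimum for ``patience`` consecutive epochs the run is
terminated and the best-epoch weights are restored.

Every internal layer that can serve as a feature-extraction point is listed
in a :class:`LayerCatalog` with 1-based contiguous indices: per block
``conv1``, ``conv2`` and ``pool``, then ``flatten`` and each dense layer, so
``|catalog| = 3 * n_blocks + 1 + len(dense)``.
"""

from __future__ import annotations

import copy
import io
import json
import logging
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from .containers import LabeledDataset
from .layers import (
    Adam,
    BatchNorm,
    Conv1D,
    Dense,
    Dropout,
    Embedding,
    Flatten,
    Layer,
    MaxPool1D,
    Optimizer,
    ReLU,
    RMSprop,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# math primitives
# ---------------------------------------------------------------------------

def relu(x):
    """Elementwise ``max(0, x)``."""
    return np.maximum(0, x)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax along ``axis`` (max-subtraction, shift-invariant)."""
    z = np.asarray(z, dtype=float)
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(y, p, eps: float = 1e-7):
    """Binary cross-entropy ``-(y log p + (1-y) log(1-p))`` with ``p`` clipped to [eps, 1-eps]."""
    p = np.clip(np.asarray(p, dtype=float), eps, 1 - eps)
    y = np.asarray(y, dtype=float)
    out = -(y * np.log(p) + (1 - y) * np.log1p(-p))
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# architecture specification and layer catalog
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """Hyperparameters defining one network.

    ``dense_sizes`` lists the dense head; the classifier output layer
    (``n_classes`` units for softmax, 1 for sigmoid) is appended at build time
    unless the last listed entry already equals it.
    """

    n_blocks: int = 1
    base_filters: int = 64
    kernel_size: int = 3
    pool_size: int = 2
    dropout_rate: float = 0.4
    dense_sizes: tuple[int, ...] = (64, 1)
    output_activation: str = "sigmoid"
    optimizer: str = "adam"
    learning_rate: float | None = None
    embedding: tuple[int, int] | None = None  # (vocab_size, embed_dim), text only
    input_shape: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if not self.dense_sizes:
            raise ValueError("dense_sizes must be non-empty")
        if self.output_activation not in ("softmax", "sigmoid"):
            raise ValueError("output_activation must be 'softmax' or 'sigmoid'")
        if self.optimizer not in ("adam", "rmsprop"):
            raise ValueError("optimizer must be 'adam' or 'rmsprop'")

    def filters_in_block(self, b: int) -> int:
        """Filter count of block ``b`` (1-based): doubles with each block."""
        return self.base_filters * 2 ** (b - 1)

    def resolved_dense_sizes(self, n_classes: int) -> list[int]:
        out_units = n_classes if self.output_activation == "softmax" else 1
        sizes = list(self.dense_sizes)
        if sizes[-1] != out_units:
            sizes.append(out_units)
        return sizes

    def with_blocks(self, n_blocks: int) -> "ArchitectureSpec":
        d = asdict(self)
        d["n_blocks"] = n_blocks
        d["dense_sizes"] = tuple(d["dense_sizes"])
        if d["embedding"] is not None:
            d["embedding"] = tuple(d["embedding"])
        if d["input_shape"] is not None:
            d["input_shape"] = tuple(d["input_shape"])
        return ArchitectureSpec(**d)


@dataclass(frozen=True)
class CatalogEntry:
    index: int          # 1-based, contiguous
    name: str
    kind: str           # conv | pool | flatten | dense
    output_shape: tuple[int, ...]


@dataclass
class LayerCatalog:
    entries: list[CatalogEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, index: int) -> CatalogEntry:
        """Look up by 1-based catalog index."""
        if not 1 <= index <= len(self.entries):
            raise IndexError(
                f"layer index {index} out of range; catalog has layers 1..{len(self.entries)}: "
                + ", ".join(f"{e.index}={e.name}" for e in self.entries)
            )
        return self.entries[index - 1]

    def describe(self) -> str:
        return "\n".join(
            f"{e.index:3d}  {e.name:16s} {e.kind:8s} {e.output_shape}" for e in self.entries
        )


class Network:
    """Ordered op list plus capture positions for the layer catalog."""

    def __init__(self, ops: list[Layer], capture_after: list[int],
                 output_activation: str, n_classes: int) -> None:
        self.ops = ops
        self.capture_after = capture_after  # op index after which catalog entry i is captured
        self.output_activation = output_activation
        self.n_classes = n_classes

    # -- weights ------------------------------------------------------------
    def get_weights(self) -> list[dict]:
        state = []
        for op in self.ops:
            s = {k: v.copy() for k, v in op.params.items()}
            if isinstance(op, BatchNorm):
                s["_running_mean"] = op.running_mean.copy()
                s["_running_var"] = op.running_var.copy()
            state.append(s)
        return state

    def set_weights(self, state: list[dict]) -> None:
        for op, s in zip(self.ops, state):
            for k in op.params:
                op.params[k] = s[k].copy()
            if isinstance(op, BatchNorm):
                op.running_mean = s["_running_mean"].copy()
                op.running_var = s["_running_var"].copy()

    @property
    def n_params(self) -> int:
        return sum(v.size for op in self.ops for v in op.params.values())

    # -- passes -------------------------------------------------------------
    def forward_logits(self, X: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        out = np.asarray(X)
        for op in self.ops:
            out = op.forward(out, training, rng)
        return out

    def forward_capture(self, X: np.ndarray, catalog_index: int,
                        rng: np.random.Generator | None = None) -> np.ndarray:
        """Inference-mode forward pass truncated after catalog layer ``catalog_index``."""
        rng = rng or np.random.default_rng(0)
        stop = self.capture_after[catalog_index - 1]
        out = np.asarray(X)
        for i, op in enumerate(self.ops):
            out = op.forward(out, False, rng)
            if i == stop:
                if i == len(self.ops) - 1:  # classifier layer: capture post-activation
                    out = self._activate(out)
                return out
        raise AssertionError("capture position beyond op list")

    def _activate(self, logits: np.ndarray) -> np.ndarray:
        return softmax(logits, axis=1) if self.output_activation == "softmax" else sigmoid(logits)

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for op in reversed(self.ops):
            d = op.backward(d)


@dataclass
class TrainedNetwork:
    """A fitted network with its spec, catalog, training history and stop epoch."""

    net: Network
    spec: ArchitectureSpec
    catalog: LayerCatalog
    history: dict[str, list[float]]
    stopped_epoch: int
    seed: int = 0

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.history["val_loss"])) + 1


def build_network(spec: ArchitectureSpec, n_classes: int, seed: int = 0) -> tuple[Network, LayerCatalog]:
    """Assemble an untrained network and its extraction-layer catalog.

    Raises ``ValueError`` (advising fewer blocks) if the spatial dimension
    would fall below the kernel size at any convolution.
    """
    if spec.input_shape is None:
        raise ValueError("spec.input_shape must be set before building")
    rng = np.random.default_rng(seed)
    ops: list[Layer] = []
    capture_after: list[int] = []
    entries: list[CatalogEntry] = []
    shape = tuple(spec.input_shape)

    if spec.embedding is not None:
        vocab, dim = spec.embedding
        emb = Embedding(vocab, dim, rng)
        shape = emb.output_shape(shape)
        ops.append(emb)
    if len(shape) != 2:
        raise ValueError(f"expected (length, channels) input after any embedding, got {shape}")

    def add_entry(name: str, kind: str) -> None:
        capture_after.append(len(ops) - 1)
        entries.append(CatalogEntry(len(entries) + 1, name, kind, shape))

    in_ch = shape[1]
    for b in range(1, spec.n_blocks + 1):
        F = spec.filters_in_block(b)
        for half, padding in ((1, "valid"), (2, "same")):
            conv = Conv1D(in_ch, F, spec.kernel_size, padding, rng)
            try:
                shape = conv.output_shape(shape)
            except ValueError as exc:
                raise ValueError(f"block {b}: {exc}") from None
            ops.extend([conv, BatchNorm(F), ReLU()])
            add_entry(f"block{b}_conv{half}", "conv")
            in_ch = F
        pool = MaxPool1D(spec.pool_size)
        try:
            shape = pool.output_shape(shape)
        except ValueError as exc:
            raise ValueError(f"block {b}: {exc}; use fewer blocks") from None
        ops.append(pool)
        add_entry(f"block{b}_pool", "pool")
        ops.append(Dropout(spec.dropout_rate))

    flat = Flatten()
    shape = flat.output_shape(shape)
    ops.append(flat)
    add_entry("flatten", "flatten")

    sizes = spec.resolved_dense_sizes(n_classes)
    for i, units in enumerate(sizes):
        dense = Dense(shape[0], units, rng)
        shape = dense.output_shape(shape)
        ops.append(dense)
        if i < len(sizes) - 1:
            ops.append(ReLU())
            add_entry(f"dense{i + 1}", "dense")
        else:
            add_entry("classifier", "dense")

    net = Network(ops, capture_after, spec.output_activation, n_classes)
    catalog = LayerCatalog(entries)
    logger.info(
        "built %d-block network: %d catalog layers, %d trainable parameters",
        spec.n_blocks, len(catalog), net.n_params,
    )
    return net, catalog


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _loss_and_grad(net: Network, logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    n = logits.shape[0]
    if net.output_activation == "softmax":
        shifted = logits - logits.max(axis=1, keepdims=True)
        logp = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        loss = -logp[np.arange(n), y].mean()
        grad = np.exp(logp)
        grad[np.arange(n), y] -= 1.0
        return float(loss), grad / n
    # sigmoid + BCE with logits (stable):  max(z,0) - z*y + log(1+exp(-|z|))
    z = logits[:, 0]
    yf = y.astype(float)
    loss = float(np.mean(np.maximum(z, 0) - z * yf + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - yf) / n)[:, None]
    return loss, grad


def _batched_eval(net: Network, X: np.ndarray, y: np.ndarray, batch_size: int = 512) -> tuple[float, float]:
    rng = np.random.default_rng(0)
    losses, correct = [], 0
    for s in range(0, X.shape[0], batch_size):
        xb, yb = X[s : s + batch_size], y[s : s + batch_size]
        logits = net.forward_logits(xb, False, rng)
        loss, _ = _loss_and_grad(net, logits, yb)
        losses.append(loss * xb.shape[0])
        probs = net._activate(logits)
        pred = probs.argmax(axis=1) if net.output_activation == "softmax" else (probs[:, 0] > 0.5).astype(int)
        correct += int((pred == yb).sum())
    return sum(losses) / X.shape[0], correct / X.shape[0]


def make_optimizer(spec: ArchitectureSpec) -> Optimizer:
    lr = spec.learning_rate
    if spec.optimizer == "adam":
        return Adam(lr=lr if lr is not None else 1e-3)
    return RMSprop(lr=lr if lr is not None else 1e-3)


def train_network(
    net: Network,
    catalog: LayerCatalog,
    spec: ArchitectureSpec,
    train: LabeledDataset,
    val: LabeledDataset,
    max_epochs: int = 100,
    patience: int = 10,
    batch_size: int = 32,
    seed: int = 0,
) -> TrainedNetwork:
    """Mini-batch training with patience-based early stopping on validation loss.

    Stops once the validation loss has gone ``patience`` consecutive epochs
    without a new strict minimum, or at ``max_epochs``; the weights from the
    best-validation-loss epoch are restored before returning.
    """
    if train.n == 0 or val.n == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(seed)
    opt = make_optimizer(spec)
    history: dict[str, list[float]] = {k: [] for k in ("train_loss", "val_loss", "train_acc", "val_acc")}
    best_loss = np.inf
    best_weights = net.get_weights()
    since_best = 0
    stopped_epoch = max_epochs
    Xtr, ytr = train.X, train.y

    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(train.n)
        for s in range(0, train.n, batch_size):
            idx = order[s : s + batch_size]
            logits = net.forward_logits(Xtr[idx], True, rng)
            loss, dlogits = _loss_and_grad(net, logits, ytr[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; inspect the learning rate and input scaling"
                )
            net.backward(dlogits)
            opt.step(net.ops)
        tl, ta = _batched_eval(net, Xtr, ytr)
        vl, va = _batched_eval(net, val.X, val.y)
        if not (np.isfinite(tl) and np.isfinite(vl)):
            raise RuntimeError(f"non-finite loss at epoch {epoch}")
        history["train_loss"].append(tl)
        history["val_loss"].append(vl)
        history["train_acc"].append(ta)
        history["val_acc"].append(va)
        if vl < best_loss:
            best_loss = vl
            best_weights = net.get_weights()
            since_best = 0
        else:
            since_best += 1
        if since_best >= patience:
            stopped_epoch = epoch
            break
    net.set_weights(best_weights)
    logger.info(
        "training stopped at epoch %d (best val loss %.4f at epoch %d)",
        stopped_epoch, best_loss, int(np.argmin(history["val_loss"])) + 1,
    )
    return TrainedNetwork(net, spec, catalog, history, stopped_epoch, seed)


def predict(trained: TrainedNetwork, X: np.ndarray, batch_size: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels in inference mode (deterministic).

    Softmax heads return an ``(n, k)`` probability matrix; sigmoid heads a
    length-``n`` vector of positive-class probabilities.
    """
    net = trained.net
    rng = np.random.default_rng(0)
    chunks = []
    for s in range(0, np.asarray(X).shape[0], batch_size):
        logits = net.forward_logits(X[s : s + batch_size], False, rng)
        chunks.append(net._activate(logits))
    probs = np.vstack(chunks)
    if net.output_activation == "softmax":
        return probs, probs.argmax(axis=1)
    p = probs[:, 0]
    return p, (p > 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_network(trained: TrainedNetwork, path: str) -> None:
    """Serialize weights + spec + catalog + history into a single zip archive."""
    meta = {
        "spec": asdict(trained.spec),
        "catalog": [asdict(e) for e in trained.catalog.entries],
        "history": trained.history,
        "stopped_epoch": trained.stopped_epoch,
        "seed": trained.seed,
        "n_classes": trained.net.n_classes,
    }
    state = trained.net.get_weights()
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        buf = io.BytesIO()
        flat = {f"{i}/{k}": v for i, s in enumerate(state) for k, v in s.items()}
        np.savez(buf, **flat)
        zf.writestr("weights.npz", buf.getvalue())


def load_network(path: str) -> TrainedNetwork:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = np.load(io.BytesIO(zf.read("weights.npz")))
    d = meta["spec"]
    for key in ("dense_sizes", "embedding", "input_shape"):
        if d[key] is not None:
            d[key] = tuple(d[key])
    spec = ArchitectureSpec(**d)
    net, catalog = build_network(spec, meta["n_classes"], seed=meta["seed"])
    state = net.get_weights()
    for name in arrays.files:
        i, k = name.split("/", 1)
        state[int(i)][k] = arrays[name]
    net.set_weights(state)
    return TrainedNetwork(net, spec, catalog, meta["history"], meta["stopped_epoch"], meta["seed"])


def history_to_tsv(trained: TrainedNetwork, path: str) -> None:
    """Export per-epoch history as TSV (epoch, train_loss, val_loss, train_acc, val_acc)."""
    h = trained.history
    with open(path, "w") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\ttrain_acc\tval_acc\n")
        for i in range(len(h["train_loss"])):
            fh.write(
                f"{i + 1}\t{h['train_loss'][i]:.6f}\t{h['val_loss'][i]:.6f}"
                f"\t{h['train_acc'][i]:.6f}\t{h['val_acc'][i]:.6f}\n"
            )
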