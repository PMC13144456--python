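"""Training protocol: stratified split, SMOTE rebalancing, optimization with
early stopping and checkpointing, and the frozen-encoder transfer-learning
procedure.

The protocol is: split labeled windows 70/30 stratified by class, fit the
depth scaler on the training partition only, rebalance the training
partition with SMOTE (every class oversampled to the majority count), then
optimize with Adam (LR 0.001) under sparse categorical cross-entropy, early
stopping on validation loss (patience 10) and checkpointing at the minimum
validation loss. Fine-tuning freezes the convolutional encoder,
re-initializes the classification head (50% dropout on its dense layers) and
retrains it at LR 0.0002 with patience 5.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .model import ArchitectureSpec, ConvAttentionNet
from .nnet import Adam, softmax_xent
from .windows import DepthScaler, ExonWindow, encode_batch, fit_depth_scaler, labels_of


class SmoteError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    split_fraction: float = 0.70
    smote_enabled: bool = True
    smote_k_neighbors: int = 5
    smote_seed: int = 42
    learning_rate: float = 1e-3
    loss: str = "sparse_categorical_crossentropy"
    early_stopping_patience: int = 10
    max_epochs: int = 100
    batch_size: int = 256
    split_seed: int = 0
    shuffle_seed: int = 1
    dropout_seed: int = 2

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError(f"split_fraction must be in (0, 1), got {self.split_fraction}")
        if self.early_stopping_patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass(frozen=True)
class FineTuneConfig:
    head_units: tuple[int, ...] = (256, 128)
    head_dropout: float = 0.5
    learning_rate: float = 2e-4
    early_stopping_patience: int = 5
    max_epochs: int = 100
    batch_size: int = 256
    smote_enabled: bool = True
    smote_k_neighbors: int = 5
    smote_seed: int = 42
    head_init_seed: int = 3
    shuffle_seed: int = 4
    dropout_seed: int = 5


@dataclass
class EncodedDataset:
    """Model-ready arrays for a window collection."""

    channels: np.ndarray  # (n, seq_len, 3) float32
    chrom: np.ndarray     # (n, 24) float32
    y: np.ndarray         # (n,) int64

    def __len__(self) -> int:
        return len(self.y)

    @classmethod
    def from_windows(cls, windows: Sequence[ExonWindow], scaler: DepthScaler) -> "EncodedDataset":
        ch, k = encode_batch(windows, scaler)
        return cls(ch, k, labels_of(windows))

    def flat_features(self, idx: np.ndarray | None = None) -> np.ndarray:
        """Windows flattened to (n, seq_len*3 + 24) vectors (the SMOTE space)."""
        ch = self.channels if idx is None else self.channels[idx]
        k = self.chrom if idx is None else self.chrom[idx]
        return np.concatenate([ch.reshape(len(ch), -1), k], axis=1)


def stratified_split(
    windows: Sequence[ExonWindow], fraction: float = 0.70, seed: int = 0
) -> tuple[list[ExonWindow], list[ExonWindow]]:
    """Class-stratified partition into (train, validation).

    Per-class proportions in each partition match the input up to rounding;
    the partitions are disjoint and exhaustive and deterministic under seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"split fraction must be in (0, 1), got {fraction}")
    y = labels_of(windows)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if idx.size < 2:
            raise ValueError(f"class {c} has fewer than 2 members; cannot stratify")
        idx = rng.permutation(idx)
        k = int(round(fraction * idx.size))
        k = min(max(k, 1), idx.size - 1)
        train_idx.extend(idx[:k])
        val_idx.extend(idx[k:])
    train_idx.sort()
    val_idx.sort()
    return [windows[i] for i in train_idx], [windows[i] for i in val_idx]


def oversample_smote(
    features: np.ndarray,
    labels: np.ndarray,
    *,
    k_neighbors: int = 5,
    seed: int = 42,
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE with the "auto" strategy: every class grows to the majority count.

    Synthetic minority points are convex combinations x_i + u (x_j - x_i) of a
    class member and one of its k nearest same-class neighbors, u ~ U(0, 1).
    Apply to the training partition only. Deterministic under seed.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    target = counts.max()
    rng = np.random.default_rng(seed)
    out_x = [features]
    out_y = [labels]
    for c in np.flatnonzero(counts):
        need = target - counts[c]
        if need == 0:
            continue
        xc = features[labels == c]
        if len(xc) <= k_neighbors:
            raise SmoteError(
                f"class {c} has {len(xc)} members, not enough for k_neighbors="
                f"{k_neighbors}; lower k_neighbors"
            )
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(xc)
        _, neigh = nn.kneighbors(xc)  # column 0 is the point itself
        base = rng.integers(len(xc), size=need)
        pick = neigh[base, rng.integers(1, k_neighbors + 1, size=need)]
        u = rng.random(need)[:, None].astype(features.dtype)
        out_x.append(xc[base] + u * (xc[pick] - xc[base]))
        out_y.append(np.full(need, c, dtype=labels.dtype))
    return np.concatenate(out_x), np.concatenate(out_y)


def rebalance_dataset(ds: EncodedDataset, config: TrainConfig) -> EncodedDataset:
    """SMOTE in the flattened window space, reshaped back to model tensors."""
    flat = ds.flat_features()
    x, y = oversample_smote(flat, ds.y, k_neighbors=config.smote_k_neighbors,
                            seed=config.smote_seed)
    n, seq_len, c = ds.channels.shape
    return EncodedDataset(
        channels=x[:, : seq_len * c].reshape(-1, seq_len, c),
        chrom=x[:, seq_len * c:],
        y=y,
    )


def predict_proba(
    model: ConvAttentionNet, ds: EncodedDataset, batch_size: int = 512
) -> np.ndarray:
    """Deterministic inference probabilities for a dataset."""
    out = np.empty((len(ds), model.spec.n_classes), dtype=np.float64)
    for i in range(0, len(ds), batch_size):
        out[i:i + batch_size] = model.forward(
            ds.channels[i:i + batch_size], ds.chrom[i:i + batch_size])
    return out


def _dataset_loss(model: ConvAttentionNet, ds: EncodedDataset, batch_size: int) -> float:
    p = predict_proba(model, ds, batch_size)
    return float(-np.log(np.maximum(p[np.arange(len(ds)), ds.y], 1e-15)).mean())


def train_model(
    spec: ArchitectureSpec,
    train_ds: EncodedDataset,
    val_ds: EncodedDataset,
    config: TrainConfig = TrainConfig(),
    *,
    model: ConvAttentionNet | None = None,
    verbose: bool = False,
) -> tuple[ConvAttentionNet, list[dict]]:
    """Optimize the classifier; returns the minimum-validation-loss checkpoint.

    ``train_ds`` should already be rebalanced if SMOTE is enabled. Stops
    after ``early_stopping_patience`` epochs without validation improvement.
    """
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("empty train or validation partition")
    if model is None:
        model = ConvAttentionNet(spec)
    opt = Adam(model.parameters("all"), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.shuffle_seed)
    drop_rng = np.random.default_rng(config.dropout_seed)

    history: list[dict] = []
    best_state = model.state_dict()
    best_val = np.inf
    best_epoch = -1
    since_best = 0
    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(len(train_ds))
        tot_loss = 0.0
        for i in range(0, len(order), config.batch_size):
            b = order[i:i + config.batch_size]
            cache: dict = {}
            model.forward(train_ds.channels[b], train_ds.chrom[b],
                          rng=drop_rng, cache=cache)
            loss, _, dlog = softmax_xent(cache["logits"], train_ds.y[b])
            model.backward(dlog, cache)
            opt.step(model.gradients("all"))
            tot_loss += loss * len(b)
        train_loss = tot_loss / len(order)
        val_loss = _dataset_loss(model, val_ds, config.batch_size)
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss}
        )
        if verbose:
            print(f"epoch {epoch}: train_loss={train_loss:.4f} val_loss={val_loss:.4f}")
        if val_loss < best_val:
            best_val, best_epoch, since_best = val_loss, epoch, 0
            best_state = model.state_dict()
        else:
            since_best += 1
            if since_best >= config.early_stopping_patience:
                break
    model.load_state_dict(best_state)
    model.training_meta = {
        "epochs_run": len(history),
        "best_epoch": best_epoch,
        "best_val_loss": best_val,
    }
    return model, history


def fit_and_train(
    windows: Sequence[ExonWindow],
    spec: ArchitectureSpec = ArchitectureSpec(),
    config: TrainConfig = TrainConfig(),
    *,
    verbose: bool = False,
) -> tuple[ConvAttentionNet, DepthScaler, list[dict]]:
    """End-to-end protocol on labeled windows: split, fit scaler, SMOTE, train."""
    train_w, val_w = stratified_split(windows, config.split_fraction, config.split_seed)
    scaler = fit_depth_scaler(train_w)
    train_ds = EncodedDataset.from_windows(train_w, scaler)
    val_ds = EncodedDataset.from_windows(val_w, scaler)
    if config.smote_enabled:
        train_ds = rebalance_dataset(train_ds, config)
    model, history = train_model(spec, train_ds, val_ds, config, verbose=verbose)
    return model, scaler, history


def _head_loss(model: ConvAttentionNet, pooled: np.ndarray, y: np.ndarray,
               batch_size: int) -> float:
    tot = 0.0
    for i in range(0, len(y), batch_size):
        p = model.head_forward(pooled[i:i + batch_size])
        tot += -np.log(
            np.maximum(p[np.arange(len(p)), y[i:i + batch_size]], 1e-15)
        ).sum()
    return float(tot / len(y))


def fine_tune(
    model: ConvAttentionNet,
    train_ds: EncodedDataset,
    val_ds: EncodedDataset,
    config: FineTuneConfig = FineTuneConfig(),
    *,
    verbose: bool = False,
) -> tuple[ConvAttentionNet, list[dict]]:
    """Frozen-encoder transfer learning on an expert-labeled dataset.

    The convolutional encoder (chromosome embedding + both convolutions) is
    frozen — its parameters are bit-identical before and after — and a fresh
    classification head is trained on the cached pooled encoder features.
    Returns the minimum-validation-loss head checkpoint.
    """
    tuned = copy.deepcopy(model)
    tuned.reinitialize_head(config.head_init_seed, head_dropout=config.head_dropout,
                            head_units=config.head_units)

    def _pooled(ds: EncodedDataset) -> np.ndarray:
        chunks = [
            tuned.encoder_features(ds.channels[i:i + 512], ds.chrom[i:i + 512])
            for i in range(0, len(ds), 512)
        ]
        return np.concatenate(chunks).astype(np.float32)

    pooled_tr = _pooled(train_ds)
    pooled_va = _pooled(val_ds)
    y_tr, y_va = train_ds.y, val_ds.y
    if config.smote_enabled:
        pooled_tr, y_tr = oversample_smote(
            pooled_tr, y_tr, k_neighbors=config.smote_k_neighbors,
            seed=config.smote_seed)

    opt = Adam(tuned.parameters("head"), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.shuffle_seed)
    drop_rng = np.random.default_rng(config.dropout_seed)
    history: list[dict] = []
    best_state = tuned.state_dict()
    best_val = np.inf
    since_best = 0
    for epoch in range(config.max_epochs):
        order = shuffle_rng.permutation(len(y_tr))
        tot = 0.0
        for i in range(0, len(order), config.batch_size):
            b = order[i:i + config.batch_size]
            cache: dict = {}
            tuned.head_forward(pooled_tr[b], rng=drop_rng, cache=cache)
            loss, _, dlog = softmax_xent(cache["logits"], y_tr[b])
            tuned._head_backward(dlog, cache)
            opt.step(tuned.gradients("head"))
            tot += loss * len(b)
        val_loss = _head_loss(tuned, pooled_va, y_va, config.batch_size)
        history.append(
            {"epoch": epoch, "train_loss": tot / len(order), "val_loss": val_loss}
        )
        if verbose:
            print(f"fine-tune epoch {epoch}: val_loss={val_loss:.4f}")
        if val_loss < best_val:
            best_val, since_best = val_loss, 0
            best_state = tuned.state_dict()
        else:
            since_best += 1
            if since_best >= config.early_stopping_patience:
                break
    tuned.load_state_dict(best_state)
    tuned.training_meta = {
        "fine_tuned": True,
        "epochs_run": len(history),
        "best_val_loss": best_val,
    }
    return tuned, history
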