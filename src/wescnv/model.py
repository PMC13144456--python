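"""The convolutional attention classifier for exon-window CNV calling.

The network takes two inputs per window: the (1002, 3) depth/start/end
channel tensor and a 24-dim chromosome indicator. The chromosome vector is
embedded by a 24-unit ReLU dense layer and repeated along the sequence, then
concatenated with the channels into a (1002, 27) joint tensor. Two strided
same-padding 1-D convolutions (32 filters k=5 s=2, then 64 filters k=3 s=2)
extract local depth patterns; global average pooling, a 128-unit ReLU
projection with dropout, softmax feature attention, and a 256/128 ReLU head
with dropout feed a 3-way softmax over {no-call, deletion, duplication}.

The parameter store is partitioned into an *encoder* (chromosome embedding +
both convolutions) and a *head* (latent projection, attention, fully
connected stack, output); transfer learning freezes the encoder and retrains
the head only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nnet
from .nnet import Conv1D, Dense, Dropout, FeatureAttention, F32


@dataclass(frozen=True)
class ArchitectureSpec:
    """Every layer hyperparameter of the classifier; serializes to JSON."""

    seq_len: int = 1002
    depth_channels: int = 3
    chrom_dims: int = 24
    chrom_embed_units: int = 24
    conv1_filters: int = 32
    conv1_kernel: int = 5
    conv1_stride: int = 2
    conv2_filters: int = 64
    conv2_kernel: int = 3
    conv2_stride: int = 2
    latent_units: int = 128
    latent_dropout: float = 0.3
    attention_units: int = 128
    head_units: tuple[int, ...] = (256, 128)
    head_dropout: float = 0.3
    n_classes: int = 3
    init_seed: int = 0

    def __post_init__(self):
        for name in ("seq_len", "depth_channels", "chrom_dims", "chrom_embed_units",
                     "conv1_filters", "conv2_filters", "latent_units",
                     "attention_units", "n_classes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.attention_units != self.latent_units:
            raise ValueError("attention operates on the latent; units must match")

    @property
    def joint_features(self) -> int:
        """Feature width of the assembled input tensor (3 + 24 = 27)."""
        return self.depth_channels + self.chrom_embed_units

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["head_units"] = list(d["head_units"])
        Path(path).write_text(json.dumps(d, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ArchitectureSpec":
        d = json.loads(Path(path).read_text())
        d["head_units"] = tuple(d["head_units"])
        return cls(**d)


class StateError(RuntimeError):
    pass


class ConvAttentionNet:
    """The classifier graph: parameter store, forward pass, and gradients."""

    def __init__(self, spec: ArchitectureSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.init_seed)
        self._build_encoder(rng)
        self._build_head(rng)
        self.training_meta: dict = {}

    # -- construction -------------------------------------------------------

    def _build_encoder(self, rng) -> None:
        s = self.spec
        self.embed = Dense(rng, s.chrom_dims, s.chrom_embed_units, "relu")
        self.conv1 = Conv1D(rng, s.joint_features, s.conv1_filters,
                            s.conv1_kernel, s.conv1_stride)
        self.conv2 = Conv1D(rng, s.conv1_filters, s.conv2_filters,
                            s.conv2_kernel, s.conv2_stride)

    def _build_head(self, rng, head_dropout: float | None = None,
                    head_units: tuple[int, ...] | None = None) -> None:
        s = self.spec
        self.latent = Dense(rng, s.conv2_filters, s.latent_units, "relu")
        self.latent_drop = Dropout(s.latent_dropout)
        self.attention = FeatureAttention(rng, s.attention_units)
        self.head: list[Dense] = []
        n_in = s.attention_units
        for units in (s.head_units if head_units is None else head_units):
            self.head.append(Dense(rng, n_in, units, "relu"))
            n_in = units
        self.head_drop = Dropout(s.head_dropout if head_dropout is None else head_dropout)
        self.out = Dense(rng, n_in, s.n_classes, "linear")

    def reinitialize_head(self, seed: int, head_dropout: float | None = None,
                          head_units: tuple[int, ...] | None = None) -> None:
        """Fresh head parameters (encoder untouched); used by transfer learning."""
        if head_units is not None and tuple(head_units) != tuple(self.spec.head_units):
            object.__setattr__(self.spec, "head_units", tuple(head_units))
        self._build_head(np.random.default_rng(seed), head_dropout, head_units)

    # -- parameter bookkeeping ----------------------------------------------

    def _layers(self, partition: str = "all") -> list:
        enc = [self.embed, self.conv1, self.conv2]
        head = [self.latent, self.attention, *self.head, self.out]
        return {"encoder": enc, "head": head, "all": enc + head}[partition]

    def parameters(self, partition: str = "all") -> list[np.ndarray]:
        return [p for layer in self._layers(partition) for _, p in layer.params()]

    def gradients(self, partition: str = "all") -> list[np.ndarray]:
        return [g for layer in self._layers(partition) for g in layer.grads()]

    def count_parameters(self, partition: str = "all") -> int:
        """Exact trainable-parameter count; encoder + head = all."""
        return int(sum(p.size for p in self.parameters(partition)))

    def parameter_hash(self, partition: str = "all") -> str:
        import hashlib

        h = hashlib.sha256()
        for p in self.parameters(partition):
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {}
        names = ["embed", "conv1", "conv2", "latent", "attention"] + \
            [f"head{i}" for i in range(len(self.head))] + ["out"]
        layers = [self.embed, self.conv1, self.conv2, self.latent, self.attention,
                  *self.head, self.out]
        for name, layer in zip(names, layers):
            for pname, p in layer.params():
                d[f"{name}.{pname}"] = p.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        names = ["embed", "conv1", "conv2", "latent", "attention"] + \
            [f"head{i}" for i in range(len(self.head))] + ["out"]
        layers = [self.embed, self.conv1, self.conv2, self.latent, self.attention,
                  *self.head, self.out]
        for name, layer in zip(names, layers):
            for pname, p in layer.params():
                p[...] = d[f"{name}.{pname}"]

    # -- forward / backward -------------------------------------------------

    def embed_and_broadcast(self, chrom_onehot: np.ndarray) -> np.ndarray:
        """Embed chromosome indicators and repeat along the sequence.

        (B, 24) -> (B, seq_len, 24); a single indicator may be passed as a
        24-vector and yields (seq_len, 24).
        """
        single = chrom_onehot.ndim == 1
        k = np.atleast_2d(chrom_onehot).astype(F32)
        if k.shape[1] != self.spec.chrom_dims:
            raise ValueError(
                f"chromosome indicator must have {self.spec.chrom_dims} dims, "
                f"got {k.shape[1]}"
            )
        e = self.embed.forward(k)
        out = np.repeat(e[:, None, :], self.spec.seq_len, axis=1)
        return out[0] if single else out

    def assemble_input(self, channels: np.ndarray, chrom_onehot: np.ndarray) -> np.ndarray:
        """Concatenate channel tensor and broadcast embedding: (B, seq_len, 27)."""
        single = channels.ndim == 2
        c = channels[None] if single else channels
        if c.shape[1:] != (self.spec.seq_len, self.spec.depth_channels):
            raise ValueError(
                f"channel tensor must be (n, {self.spec.seq_len}, "
                f"{self.spec.depth_channels}), got {c.shape}"
            )
        emb = self.embed_and_broadcast(np.atleast_2d(chrom_onehot))
        out = np.concatenate([c.astype(F32), emb], axis=2)
        return out[0] if single else out

    def forward(
        self,
        channels: np.ndarray,
        chrom_onehot: np.ndarray,
        *,
        rng: np.random.Generator | None = None,
        cache: dict | None = None,
    ) -> np.ndarray:
        """Class probabilities for a batch; pass ``rng`` to enable dropout.

        Inference (rng=None) is deterministic for fixed parameters.
        """
        if channels.ndim != 3 or len(channels) == 0:
            raise StateError("forward requires a non-empty (B, seq_len, C) batch")
        c = cache if cache is not None else None

        def sub(name):
            if c is None:
                return None
            c[name] = {}
            return c[name]

        k = chrom_onehot.astype(F32)
        e = self.embed.forward(k, sub("embed"))
        B = len(channels)
        x = np.empty((B, self.spec.seq_len, self.spec.joint_features), dtype=F32)
        x[:, :, : self.spec.depth_channels] = channels
        x[:, :, self.spec.depth_channels:] = e[:, None, :]
        a1 = self.conv1.forward(x, sub("conv1"))
        a2 = self.conv2.forward(a1, sub("conv2"))
        pooled = a2.mean(axis=1)
        if c is not None:
            c["pool_len"] = a2.shape[1]
        lat = self.latent.forward(pooled, sub("latent"))
        lat = self.latent_drop.forward(lat, rng=rng, cache=sub("ldrop"))
        att = self.attention.forward(lat, sub("attn"))
        h = att
        for i, layer in enumerate(self.head):
            h = layer.forward(h, sub(f"head{i}"))
            h = self.head_drop.forward(h, rng=rng, cache=sub(f"hdrop{i}"))
        logits = self.out.forward(h, sub("out"))
        if c is not None:
            c["logits"] = logits
        return nnet.softmax(logits, axis=1)

    def encoder_features(self, channels: np.ndarray, chrom_onehot: np.ndarray) -> np.ndarray:
        """Pooled convolutional features (B, conv2_filters); the frozen-encoder output."""
        e = self.embed.forward(chrom_onehot.astype(F32))
        x = np.concatenate(
            [channels.astype(F32),
             np.repeat(e[:, None, :], self.spec.seq_len, axis=1)], axis=2)
        return self.conv2.forward(self.conv1.forward(x)).mean(axis=1)

    def head_forward(
        self,
        pooled: np.ndarray,
        *,
        rng: np.random.Generator | None = None,
        cache: dict | None = None,
    ) -> np.ndarray:
        """Head-only forward from cached pooled features; returns probabilities."""
        c = cache

        def sub(name):
            if c is None:
                return None
            c[name] = {}
            return c[name]

        lat = self.latent.forward(pooled.astype(F32), sub("latent"))
        lat = self.latent_drop.forward(lat, rng=rng, cache=sub("ldrop"))
        att = self.attention.forward(lat, sub("attn"))
        h = att
        for i, layer in enumerate(self.head):
            h = layer.forward(h, sub(f"head{i}"))
            h = self.head_drop.forward(h, rng=rng, cache=sub(f"hdrop{i}"))
        logits = self.out.forward(h, sub("out"))
        if c is not None:
            c["logits"] = logits
        return nnet.softmax(logits, axis=1)

    def _head_backward(self, d_logits: np.ndarray, cache: dict) -> np.ndarray:
        d = self.out.backward(d_logits, cache["out"])
        for i in reversed(range(len(self.head))):
            d = self.head_drop.backward(d, cache[f"hdrop{i}"])
            d = self.head[i].backward(d, cache[f"head{i}"])
        d = self.attention.backward(d, cache["attn"])
        d = self.latent_drop.backward(d, cache["ldrop"])
        return self.latent.backward(d, cache["latent"])

    def backward(self, d_logits: np.ndarray, cache: dict, *, encoder: bool = True) -> None:
        """Accumulate gradients from d(loss)/d(logits); head-only when encoder=False."""
        d_pool = self._head_backward(d_logits, cache)
        if not encoder:
            return
        d_a2 = np.broadcast_to(d_pool[:, None, :] / cache["pool_len"],
                               (len(d_pool), cache["pool_len"], d_pool.shape[1]))
        d_a1 = self.conv2.backward(d_a2, cache["conv2"])
        # the channel input needs no gradient; only the broadcast embedding does
        self.conv1.backward(d_a1, cache["conv1"], need_input_grad=False)
        d_e = self.conv1.input_grad_channel_sum(
            cache["conv1"], self.spec.depth_channels)
        self.embed.backward(d_e, cache["embed"])

    # -- serialization ------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Checkpoint: architecture JSON + parameter arrays in one .npz."""
        spec = asdict(self.spec)
        spec["head_units"] = list(spec["head_units"])
        np.savez(
            path,
            __spec__=np.frombuffer(json.dumps(spec, sort_keys=True).encode(), dtype=np.uint8),
            __meta__=np.frombuffer(json.dumps(self.training_meta, sort_keys=True, default=float).encode(), dtype=np.uint8),
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ConvAttentionNet":
        with np.load(path) as z:
            spec_d = json.loads(bytes(z["__spec__"]).decode())
            spec_d["head_units"] = tuple(spec_d["head_units"])
            model = cls(ArchitectureSpec(**spec_d))
            model.training_meta = json.loads(bytes(z["__meta__"]).decode())
            model.load_state_dict({k: z[k] for k in z.files if not k.startswith("__")})
        return model
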