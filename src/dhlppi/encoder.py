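"""The deep-hash encoder: a Siamese CNN producing relaxed binary codes.

Architecture (one shared trunk, two frozen heads):

1. **Embedding** — each integer token (0 = padding, 1..20 = residues) is
   mapped to a learned ``embed_dim``-vector, giving an ``L x dim`` matrix
   per protein.
2. **Four convolution blocks** — each block is 1-D convolution -> ReLU ->
   batch normalization -> pooling. Blocks 1–3 use window-2 average
   pooling; block 4 uses global average pooling, collapsing the sequence
   to a fixed-width feature vector.
3. **Two frozen random projections** — fully connected layers with
   ``code_dim`` outputs, one producing the *ontic* code (the database
   side) and one the *query* code (the probe side). Their weights are
   drawn from two distinct seeds at construction and never trained.
4. **Range control** — a sigmoid squashes each output into (0, 1); the
   relaxed code is binarized at threshold 0.5 to yield the hash code.

The trunk (embedding, convolutions, batch norms) is shared between the
ontic and query branches — the Siamese property — so only the frozen
heads distinguish the two roles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import _nn
from .seqio import TokenSequence

CHECKPOINT_FORMAT = "dhlppi-checkpoint-1"

ONTIC = "ontic"
QUERY = "query"

#: (n_kernels, kernel_size, pooling_kind, stride) per block.
DEFAULT_CONV_BLOCKS: tuple[tuple[int, int, str, int], ...] = (
    (64, 5, "avg", 1),
    (128, 7, "avg", 1),
    (256, 9, "avg", 1),
    (512, 15, "global_avg", 1),
)

# Scaled-down blocks keep the kernel sizes but narrow the trunk. The final
# width stays above 2 * code_dim: the trunk's feature vector must satisfy
# sign constraints through BOTH frozen projections (~2N half-space
# constraints), which is infeasible when the feature dimension is below 2N.
DESK_CONV_BLOCKS: tuple[tuple[int, int, str, int], ...] = (
    (16, 5, "avg", 1),
    (32, 7, "avg", 1),
    (64, 9, "avg", 1),
    (160, 15, "global_avg", 1),
)


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the hashing encoder.

    Defaults follow the full-scale profile (5000-residue inputs, 64-bit
    codes); :meth:`desk_profile` gives a scaled-down profile suitable for
    quick experiments and tests.
    """

    L: int = 5000
    embed_dim: int = 128
    conv_blocks: tuple[tuple[int, int, str, int], ...] = DEFAULT_CONV_BLOCKS
    code_dim: int = 64
    projection_seed_ontic: int = 101
    projection_seed_query: int = 202
    rng_seed: int = 0
    vocab_size: int = 21
    pool_window: int = 2

    def __post_init__(self) -> None:
        if self.L < 1 or self.code_dim < 1:
            raise ValueError("L and code_dim must be positive")
        if len(self.conv_blocks) != 4:
            raise ValueError("expected exactly 4 convolution blocks")
        if self.projection_seed_ontic == self.projection_seed_query:
            raise ValueError(
                "ontic and query projection seeds must differ; equal seeds would "
                "make the two roles identical"
            )
        kinds = [blk[2] for blk in self.conv_blocks]
        if kinds[-1] != "global_avg" or any(k != "avg" for k in kinds[:-1]):
            raise ValueError("blocks 1-3 must use 'avg' pooling, block 4 'global_avg'")

    def validate_for_search(self, d: int) -> None:
        """Check the code width supports Hamming-radius-``d`` indexing."""
        if self.code_dim % (2 * d) != 0:
            raise ValueError(
                f"search threshold d={d} requires 2d={2 * d} to divide "
                f"code_dim={self.code_dim}"
            )

    @classmethod
    def desk_profile(cls, **overrides) -> "EncoderConfig":
        """Scaled-down profile: 256-token inputs, narrow blocks, 64-bit codes.

        Uses window-4 average pooling so the trunk contracts quickly at
        short input lengths; the full-scale profile keeps window 2.
        """
        cfg = cls(L=256, embed_dim=16, conv_blocks=DESK_CONV_BLOCKS, pool_window=4)
        return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class RelaxedCode:
    """Pre-binarization code: sigmoid outputs, each strictly in (0, 1)."""

    values: np.ndarray
    role: str

    def __post_init__(self) -> None:
        if self.role not in (ONTIC, QUERY):
            raise ValueError(f"role must be 'ontic' or 'query', got {self.role!r}")


@dataclass(frozen=True)
class HashCode:
    """An N-bit binary code; bit 0 is the first network output.

    The integer form is big-endian over bits 0..N-1, so bit 0 is the most
    significant bit — the convention the fragment index relies on.
    """

    bits: np.ndarray
    role: str

    def __post_init__(self) -> None:
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("hash code bits must be 0 or 1")

    @property
    def width(self) -> int:
        return len(self.bits)

    def as_int(self) -> int:
        value = 0
        for b in self.bits:
            value = (value << 1) | int(b)
        return value

    @classmethod
    def from_int(cls, value: int, width: int, role: str) -> "HashCode":
        bits = np.array([(value >> (width - 1 - i)) & 1 for i in range(width)], dtype=np.uint8)
        return cls(bits=bits, role=role)

    def as_hex(self) -> str:
        return format(self.as_int(), f"0{(self.width + 3) // 4}x")


def binarize(code: RelaxedCode | np.ndarray, role: str | None = None) -> HashCode:
    """Threshold a relaxed code at 0.5 (inclusive: 0.5 -> 1)."""
    if isinstance(code, RelaxedCode):
        values, role = code.values, code.role
    else:
        values = np.asarray(code)
        if role is None:
            raise ValueError("role required when binarizing a bare array")
    bits = (values >= 0.5).astype(np.uint8)
    return HashCode(bits=bits, role=role)


class EncoderState:
    """Parameterized encoder: shared trainable trunk + two frozen heads.

    Construct via :func:`build_encoder`. The trainable parameters are the
    embedding table, convolution weights/biases and batch-norm affine
    parameters; the two projection matrices are frozen at initialization.
    """

    def __init__(self, config: EncoderConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.rng_seed)
        self.layers: list[_nn.Layer] = [
            _nn.Embedding(config.vocab_size, config.embed_dim, rng)
        ]
        in_ch = config.embed_dim
        for n_kernels, kernel, pooling, stride in config.conv_blocks:
            if stride != 1:
                raise ValueError("only stride-1 convolutions are supported")
            self.layers.append(_nn.Conv1d(in_ch, n_kernels, kernel, rng))
            self.layers.append(_nn.ReLU())
            self.layers.append(_nn.BatchNorm1d(n_kernels))
            if pooling == "avg":
                self.layers.append(_nn.AvgPool1d(config.pool_window))
            else:
                self.layers.append(_nn.GlobalAvgPool())
            in_ch = n_kernels
        self.feature_dim = in_ch
        # Frozen heads: symmetric-uniform init from the role seeds, no bias.
        bound = 1.0 / np.sqrt(self.feature_dim)
        self.projection = {
            ONTIC: np.random.default_rng(config.projection_seed_ontic).uniform(
                -bound, bound, size=(config.code_dim, self.feature_dim)
            ),
            QUERY: np.random.default_rng(config.projection_seed_query).uniform(
                -bound, bound, size=(config.code_dim, self.feature_dim)
            ),
        }

    # -- parameter access -------------------------------------------------

    def trainable_params(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of every trainable parameter."""
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params.items():
                out[f"layer{i}.{name}"] = arr
        return out

    def frozen_params(self) -> dict[str, np.ndarray]:
        return {f"projection.{role}": w for role, w in self.projection.items()}

    # -- forward / backward ----------------------------------------------

    def forward_batch(
        self, tokens: np.ndarray, role: str, train: bool = False
    ) -> tuple[np.ndarray, list]:
        """Relaxed codes for a (B, L) batch of token rows.

        Returns ``(codes (B, N), caches)``; the caches are consumed by
        :meth:`backward_batch` during training.
        """
        if role not in (ONTIC, QUERY):
            raise ValueError(f"unknown role {role!r}")
        if tokens.ndim != 2 or tokens.shape[1] != self.config.L:
            raise ValueError(
                f"expected token batch of shape (B, {self.config.L}), got {tokens.shape}"
            )
        caches = []
        x = tokens
        for layer in self.layers:
            x, cache = layer.forward(x, train)
            caches.append(cache)
        z = x @ self.projection[role].T
        out = _nn.sigmoid(z)
        caches.append((out, role))
        return out, caches

    def backward_batch(
        self, caches: list, grad_codes: np.ndarray, grads: dict[str, np.ndarray]
    ) -> None:
        """Backpropagate loss gradients wrt the relaxed codes into ``grads``.

        The frozen projections receive no gradient.
        """
        out, role = caches[-1]
        gz = grad_codes * out * (1.0 - out)
        g = gz @ self.projection[role]
        for i in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[i]
            layer_grads: dict[str, np.ndarray] = {}
            g = layer.backward(caches[i], g, layer_grads)
            for name, arr in layer_grads.items():
                key = f"layer{i}.{name}"
                if key in grads:
                    grads[key] += arr
                else:
                    grads[key] = arr

    # -- public encoding API ----------------------------------------------

    def encode(self, seq: TokenSequence, role: str) -> RelaxedCode:
        """Encode one token sequence into its relaxed code for ``role``."""
        if seq.padded_length != self.config.L:
            raise ValueError(
                f"token sequence has padded length {seq.padded_length}, "
                f"encoder expects {self.config.L}"
            )
        out, _ = self.forward_batch(seq.tokens[None, :], role, train=False)
        return RelaxedCode(values=out[0], role=role)

    def encode_batch(self, tokens: np.ndarray, role: str) -> np.ndarray:
        """Relaxed codes for many sequences at once (inference mode)."""
        return self.forward_batch(tokens, role, train=False)[0]

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist parameters, batch-norm statistics and config to ``path``."""
        arrays: dict[str, np.ndarray] = dict(self.trainable_params())
        arrays.update(self.frozen_params())
        for i, layer in enumerate(self.layers):
            if isinstance(layer, _nn.BatchNorm1d):
                arrays[f"layer{i}.running_mean"] = layer.running_mean
                arrays[f"layer{i}.running_var"] = layer.running_var
        cfg = {
            "format": CHECKPOINT_FORMAT,
            "config": {
                "L": self.config.L,
                "embed_dim": self.config.embed_dim,
                "conv_blocks": [list(b) for b in self.config.conv_blocks],
                "code_dim": self.config.code_dim,
                "projection_seed_ontic": self.config.projection_seed_ontic,
                "projection_seed_query": self.config.projection_seed_query,
                "rng_seed": self.config.rng_seed,
                "vocab_size": self.config.vocab_size,
                "pool_window": self.config.pool_window,
            },
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EncoderState":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("format") != CHECKPOINT_FORMAT:
                raise ValueError(f"unrecognized checkpoint format: {meta.get('format')!r}")
            c = meta["config"]
            c["conv_blocks"] = tuple(tuple(b) for b in c["conv_blocks"])
            state = cls(EncoderConfig(**c))
            params = state.trainable_params()
            for name, arr in params.items():
                arr[...] = data[name]
            for role in (ONTIC, QUERY):
                state.projection[role][...] = data[f"projection.{role}"]
            for i, layer in enumerate(state.layers):
                if isinstance(layer, _nn.BatchNorm1d):
                    layer.running_mean[...] = data[f"layer{i}.running_mean"]
                    layer.running_var[...] = data[f"layer{i}.running_var"]
        return state


def build_encoder(config: EncoderConfig) -> EncoderState:
    """Construct an encoder; identical configs yield identical parameters."""
    return EncoderState(config)
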