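"""Pair construction, cross-validation splitting and the training loop.

Each labeled pair is used twice — once with protein A as ontic and B as
query, once reversed — doubling the training samples (role reversal).
Cross-validation splits at the level of *undirected pairs* before
doubling, so a pair and its reversal never straddle the train/test
boundary; with the default 10 folds this realizes the 9:1 split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import losses as losses_mod
from ._nn import Adam
from .encoder import ONTIC, QUERY, EncoderState
from .losses import LossConfig
from .seqio import LabeledPair, TokenSequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DirectedSample:
    """A training sample: encode query_id as probe, ontic_id as database side."""

    query_id: str
    ontic_id: str
    label: int


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 5e-3
    optimizer: str = "adam"
    cv_folds: int = 10
    split_ratio: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split_ratio must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


def double_pairs(pairs: Sequence[LabeledPair]) -> list[DirectedSample]:
    """Role-reversal doubling: each pair yields (B->A) then (A->B)."""
    samples: list[DirectedSample] = []
    for p in pairs:
        samples.append(DirectedSample(query_id=p.id_b, ontic_id=p.id_a, label=p.label))
        samples.append(DirectedSample(query_id=p.id_a, ontic_id=p.id_b, label=p.label))
    return samples


def cv_split(
    pairs: Sequence[LabeledPair], fold: int, cfg: TrainConfig
) -> tuple[list[DirectedSample], list[DirectedSample]]:
    """Train/test doubled samples for one cross-validation fold.

    Pairs are shuffled once (by ``rng_seed``), partitioned into
    ``cv_folds`` disjoint test blocks covering all pairs, and doubled
    after splitting. Deterministic for a given seed.
    """
    if not (0 <= fold < cfg.cv_folds):
        raise ValueError(f"fold must be in [0, {cfg.cv_folds}), got {fold}")
    rng = np.random.default_rng(cfg.rng_seed)
    order = rng.permutation(len(pairs))
    bounds = np.linspace(0, len(pairs), cfg.cv_folds + 1).astype(int)
    test_idx = set(order[bounds[fold]: bounds[fold + 1]].tolist())
    train_pairs = [pairs[i] for i in order if i not in test_idx]
    test_pairs = [pairs[i] for i in order if i in test_idx]
    return double_pairs(train_pairs), double_pairs(test_pairs)


@dataclass
class LossTrace:
    """Per-epoch mean losses recorded during training."""

    ld: list[float] = field(default_factory=list)
    lh: list[float] = field(default_factory=list)
    lb: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)

    def append(self, means: Mapping[str, float]) -> None:
        self.ld.append(means["ld"])
        self.lh.append(means["lh"])
        self.lb.append(means["lb"])
        self.total.append(means["total"])

    def __len__(self) -> int:
        return len(self.total)


def _token_matrix(
    ids: Sequence[str], sequences: Mapping[str, TokenSequence]
) -> np.ndarray:
    rows = []
    for pid in ids:
        if pid not in sequences:
            raise KeyError(f"no sequence for protein id {pid!r}")
        rows.append(sequences[pid].tokens)
    return np.stack(rows)


def train(
    encoder_state: EncoderState,
    samples: Sequence[DirectedSample],
    sequences: Mapping[str, TokenSequence],
    loss_cfg: LossConfig,
    train_cfg: TrainConfig,
) -> tuple[EncoderState, LossTrace]:
    """Minimize the total loss over the directed samples (in place).

    The trunk parameters are updated by Adam; the frozen projections are
    untouched. Returns the same state object and the per-epoch loss
    trace. Fully reproducible given ``train_cfg.rng_seed``.
    """
    for s in samples:
        if s.query_id not in sequences or s.ontic_id not in sequences:
            missing = s.query_id if s.query_id not in sequences else s.ontic_id
            raise KeyError(f"no sequence for protein id {missing!r}")

    trace = LossTrace()
    if train_cfg.epochs == 0 or not samples:
        return encoder_state, trace

    params = encoder_state.trainable_params()
    opt = Adam(params, lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.rng_seed)
    labels_all = np.array([s.label for s in samples])
    ontic_tokens_all = _token_matrix([s.ontic_id for s in samples], sequences)
    query_tokens_all = _token_matrix([s.query_id for s in samples], sequences)

    n = len(samples)
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        epoch_losses = {"ld": 0.0, "lh": 0.0, "lb": 0.0, "total": 0.0}
        n_seen = 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start: start + train_cfg.batch_size]
            ont_out, ont_caches = encoder_state.forward_batch(
                ontic_tokens_all[idx], ONTIC, train=True
            )
            que_out, que_caches = encoder_state.forward_batch(
                query_tokens_all[idx], QUERY, train=True
            )
            batch_losses, g_ont, g_que = losses_mod.batch_losses_and_grads(
                ont_out, que_out, labels_all[idx], loss_cfg
            )
            if not np.isfinite(batch_losses["total"]):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}: "
                    f"{batch_losses}"
                )
            grads: dict[str, np.ndarray] = {}
            encoder_state.backward_batch(ont_caches, g_ont, grads)
            encoder_state.backward_batch(que_caches, g_que, grads)
            opt.step(grads)
            w = len(idx)
            for key in epoch_losses:
                epoch_losses[key] += batch_losses[key] * w
            n_seen += w
        trace.append({k: v / n_seen for k, v in epoch_losses.items()})
        logger.debug(
            "epoch %d: L=%.4f (Ld=%.4f Lh=%.4f Lb=%.4f)",
            epoch, trace.total[-1], trace.ld[-1], trace.lh[-1], trace.lb[-1],
        )
    return encoder_state, trace
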