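"""Loss functions for training the hashing encoder.

Three losses act on the relaxed (pre-binarization) codes:

* **Discrimination loss** — a contrastive hinge on the Manhattan distance
  between a pair's ontic and query codes: interacting pairs are pulled
  within ``in_dist`` (default 2), non-interacting pairs pushed beyond
  ``unin_dist`` (default 12).
* **Hash constraint loss** — a quantization penalty, largest when every
  component sits at the threshold 0.5 and zero once components reach
  {0, 1}; it drives the sigmoid outputs toward saturation so Manhattan
  distance converges to Hamming distance.
* **Bit balance loss** — the squared deviation of each code's mean from
  0.5, encouraging codes whose bits are 0 or 1 with equal probability.

The total is the weighted sum with default weights 1, 1 and 2/N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import RelaxedCode


def _values(code) -> np.ndarray:
    return code.values if isinstance(code, RelaxedCode) else np.asarray(code, dtype=float)


@dataclass(frozen=True)
class LossConfig:
    """Margins, quantization threshold and loss weights.

    ``lambda_b`` defaults to 2/N, compensating the bit-balance term's
    1/N^2 scale relative to the other losses.
    """

    N: int = 64
    in_dist: float = 2.0
    unin_dist: float = 12.0
    quan_thresh: float = 0.5
    lambda_d: float = 1.0
    lambda_h: float = 1.0
    lambda_b: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.in_dist < self.unin_dist <= self.N):
            raise ValueError(
                f"margins must satisfy 0 <= in_dist < unin_dist <= N, got "
                f"in_dist={self.in_dist}, unin_dist={self.unin_dist}, N={self.N}"
            )
        if not (0 < self.quan_thresh < 1):
            raise ValueError(f"quan_thresh must be in (0,1), got {self.quan_thresh}")
        if self.lambda_b is None:
            object.__setattr__(self, "lambda_b", 2.0 / self.N)
        if min(self.lambda_d, self.lambda_h, self.lambda_b) < 0:
            raise ValueError("loss weights must be non-negative")


def manhattan_dist(a, b) -> float:
    """Sum of absolute component differences; equals Hamming on binary codes."""
    va, vb = _values(a), _values(b)
    if va.shape != vb.shape:
        raise ValueError(f"length mismatch: {va.shape} vs {vb.shape}")
    return float(np.abs(va - vb).sum())


def discrimination_loss(dist: float, label: int, cfg: LossConfig) -> float:
    """Contrastive hinge: pull interacting pairs in, push others out."""
    if dist < 0:
        raise ValueError("distance must be non-negative")
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label!r}")
    return label * max(dist - cfg.in_dist, 0.0) + (1 - label) * max(cfg.unin_dist - dist, 0.0)


def _hash_term(values: np.ndarray, cfg: LossConfig) -> float:
    t = cfg.quan_thresh
    return max(t * t * len(values) - float(((values - t) ** 2).sum()), 0.0)


def hash_constraint_loss(ont, que, cfg: LossConfig) -> float:
    """Quantization penalty, summed over the ontic and query codes."""
    return _hash_term(_values(ont), cfg) + _hash_term(_values(que), cfg)


def bit_balance_loss(ont, que) -> float:
    """Squared deviation of each code's mean from 0.5, summed over roles."""
    vo, vq = _values(ont), _values(que)
    return float((vo.mean() - 0.5) ** 2 + (vq.mean() - 0.5) ** 2)


def total_loss(ld: float, lh: float, lb: float, cfg: LossConfig) -> float:
    """Weighted sum of the three losses."""
    return cfg.lambda_d * ld + cfg.lambda_h * lh + cfg.lambda_b * lb


def pair_losses(ont, que, label: int, cfg: LossConfig) -> dict[str, float]:
    """All four losses for one (ontic, query, label) pair."""
    ld = discrimination_loss(manhattan_dist(ont, que), label, cfg)
    lh = hash_constraint_loss(ont, que, cfg)
    lb = bit_balance_loss(ont, que)
    return {"ld": ld, "lh": lh, "lb": lb, "total": total_loss(ld, lh, lb, cfg)}


def batch_losses_and_grads(
    ont: np.ndarray, que: np.ndarray, labels: np.ndarray, cfg: LossConfig
) -> tuple[dict[str, float], np.ndarray, np.ndarray]:
    """Mean losses over a batch and gradients wrt the relaxed codes.

    ``ont`` and ``que`` are (B, N) relaxed-code matrices; ``labels`` is
    (B,) in {0,1}. Returns ``(losses, grad_ont, grad_que)`` where the
    losses dict holds the batch means of ld, lh, lb and the weighted
    total, and the gradients are of the mean total loss.
    """
    if ont.shape != que.shape:
        raise ValueError("ontic/query batch shape mismatch")
    B, N = ont.shape
    labels = labels.astype(float)
    diff = ont - que
    dist = np.abs(diff).sum(axis=1)                      # (B,)
    sgn = np.sign(diff)

    # discrimination hinge
    pos_active = (labels == 1) & (dist > cfg.in_dist)
    neg_active = (labels == 0) & (dist < cfg.unin_dist)
    ld = np.where(
        labels == 1,
        np.maximum(dist - cfg.in_dist, 0.0),
        np.maximum(cfg.unin_dist - dist, 0.0),
    )
    d_dist = np.zeros(B)
    d_dist[pos_active] = 1.0
    d_dist[neg_active] = -1.0
    g_ont_d = d_dist[:, None] * sgn
    g_que_d = -g_ont_d

    # hash constraint
    t = cfg.quan_thresh
    cap = t * t * N
    s_ont = ((ont - t) ** 2).sum(axis=1)
    s_que = ((que - t) ** 2).sum(axis=1)
    lh = np.maximum(cap - s_ont, 0.0) + np.maximum(cap - s_que, 0.0)
    g_ont_h = np.where((cap - s_ont > 0)[:, None], -2.0 * (ont - t), 0.0)
    g_que_h = np.where((cap - s_que > 0)[:, None], -2.0 * (que - t), 0.0)

    # bit balance
    mo = ont.mean(axis=1)
    mq = que.mean(axis=1)
    lb = (mo - 0.5) ** 2 + (mq - 0.5) ** 2
    g_ont_b = (2.0 * (mo - 0.5) / N)[:, None] * np.ones_like(ont)
    g_que_b = (2.0 * (mq - 0.5) / N)[:, None] * np.ones_like(que)

    losses = {
        "ld": float(ld.mean()),
        "lh": float(lh.mean()),
        "lb": float(lb.mean()),
    }
    losses["total"] = total_loss(losses["ld"], losses["lh"], losses["lb"], cfg)

    scale = 1.0 / B  # mean reduction over the batch
    grad_ont = scale * (cfg.lambda_d * g_ont_d + cfg.lambda_h * g_ont_h + cfg.lambda_b * g_ont_b)
    grad_que = scale * (cfg.lambda_d * g_que_d + cfg.lambda_h * g_que_h + cfg.lambda_b * g_que_b)
    return losses, grad_ont, grad_que
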