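"""Model/Results front-end tying the pipeline together.

:class:`DHLPPIModel` bundles the data (protein records + labeled pairs)
with the encoder, loss, training and search configurations;
:meth:`DHLPPIModel.fit` trains the Siamese hashing encoder and returns a
:class:`DHLPPIResults` carrying the trained state, the loss trace and
the prediction/evaluation methods (hash-code databases, all-against-all
search, confusion-matrix metrics, ``summary()``).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import hashsearch, training
from .metrics import ConfusionCounts, metrics as compute_metrics
from .encoder import (
    ONTIC,
    QUERY,
    EncoderConfig,
    EncoderState,
    build_encoder,
)
from .hashsearch import CodeDatabase, PPISet, SearchConfig
from .losses import LossConfig
from .seqio import LabeledPair, ProteinRecord, TokenSequence, read_fasta, read_pairs, tokenize
from .training import DirectedSample, LossTrace, TrainConfig

_ENCODE_CHUNK = 128


def _pack_codes(bits: np.ndarray) -> np.ndarray:
    """(B, N) {0,1} rows -> uint64 integers, bit 0 most significant."""
    N = bits.shape[1]
    weights = np.uint64(1) << np.uint64(N - 1 - np.arange(N))
    return (bits.astype(np.uint64) * weights[None, :]).sum(axis=1, dtype=np.uint64)


class DHLPPIModel:
    """Deep-hash interaction model over a set of proteins and labeled pairs.

    Parameters
    ----------
    records
        Protein sequences; every id referenced by ``pairs`` must appear.
    pairs
        Labeled protein pairs (1 = interacting, 0 = non-interacting).
    encoder_config, loss_config, train_config, search_config
        Component configurations; widths are cross-validated (the loss
        and search code width must equal the encoder's, and 2d must
        divide N for the fragment index).
    """

    def __init__(
        self,
        records: Sequence[ProteinRecord],
        pairs: Sequence[LabeledPair],
        encoder_config: EncoderConfig | None = None,
        loss_config: LossConfig | None = None,
        train_config: TrainConfig | None = None,
        search_config: SearchConfig | None = None,
    ) -> None:
        self.encoder_config = encoder_config or EncoderConfig.desk_profile()
        N = self.encoder_config.code_dim
        self.loss_config = loss_config or LossConfig(N=N)
        self.train_config = train_config or TrainConfig()
        self.search_config = search_config or SearchConfig(N=N)
        if self.loss_config.N != N:
            raise ValueError(
                f"loss config N={self.loss_config.N} != encoder code_dim={N}"
            )
        if self.search_config.N != N:
            raise ValueError(
                f"search config N={self.search_config.N} != encoder code_dim={N}"
            )
        self.encoder_config.validate_for_search(self.search_config.d)

        self.records = list(records)
        self.pairs = list(pairs)
        known = {r.id for r in self.records}
        for p in self.pairs:
            if p.id_a not in known or p.id_b not in known:
                missing = p.id_a if p.id_a not in known else p.id_b
                raise KeyError(f"pair references unknown protein id {missing!r}")
        self.sequences: dict[str, TokenSequence] = {
            r.id: tokenize(r, L=self.encoder_config.L) for r in self.records
        }

    @classmethod
    def from_files(cls, fasta_path, pairs_path, **kwargs) -> "DHLPPIModel":
        """Build a model from a FASTA file and a 3-column pair TSV."""
        return cls(read_fasta(fasta_path), read_pairs(pairs_path), **kwargs)

    def fit(self, fold: int | None = None) -> "DHLPPIResults":
        """Train the encoder; with ``fold`` set, hold that CV fold out.

        ``fold=None`` trains on all pairs (no held-out set); otherwise
        pairs are split 9:1 at pair level (fold ``fold`` of
        ``train_config.cv_folds``) before role-reversal doubling.
        """
        if fold is None:
            train_samples = training.double_pairs(self.pairs)
            test_samples: list[DirectedSample] = []
        else:
            train_samples, test_samples = training.cv_split(
                self.pairs, fold, self.train_config
            )
        state = build_encoder(self.encoder_config)
        state, trace = training.train(
            state, train_samples, self.sequences, self.loss_config, self.train_config
        )
        return DHLPPIResults(self, state, trace, train_samples, test_samples, fold)


class DHLPPIResults:
    """Fitted encoder plus prediction, search and evaluation methods."""

    def __init__(
        self,
        model: DHLPPIModel,
        encoder_state: EncoderState,
        loss_trace: LossTrace,
        train_samples: list[DirectedSample],
        test_samples: list[DirectedSample],
        fold: int | None,
    ) -> None:
        self.model = model
        self.encoder_state = encoder_state
        self._trace = loss_trace
        self.train_samples = train_samples
        self.test_samples = test_samples
        self.fold = fold

    @property
    def loss_trace(self) -> pd.DataFrame:
        """Per-epoch mean losses (ld, lh, lb, total)."""
        return pd.DataFrame(
            {"ld": self._trace.ld, "lh": self._trace.lh,
             "lb": self._trace.lb, "total": self._trace.total}
        )

    # -- encoding ----------------------------------------------------------

    def hash_codes(self, ids: Sequence[str], role: str) -> np.ndarray:
        """Binarized codes (uint64) for the given protein ids."""
        seqs = self.model.sequences
        tokens = np.stack([seqs[pid].tokens for pid in ids])
        out_bits = []
        for start in range(0, len(ids), _ENCODE_CHUNK):
            relaxed = self.encoder_state.encode_batch(
                tokens[start: start + _ENCODE_CHUNK], role
            )
            out_bits.append(relaxed >= 0.5)
        return _pack_codes(np.concatenate(out_bits))

    def build_database(self, ids: Sequence[str] | None = None) -> CodeDatabase:
        """Fragment-indexed database over the proteins' ontic codes."""
        ids = list(ids) if ids is not None else [r.id for r in self.model.records]
        codes = self.hash_codes(ids, ONTIC)
        return hashsearch.build_index(ids, codes, self.model.search_config)

    def predict_all(
        self,
        db: CodeDatabase | None = None,
        include_self: bool = False,
        symmetrize: bool = False,
    ) -> PPISet:
        """All-against-all predicted interactions at the Hamming threshold."""
        db = db or self.build_database()
        qcodes = self.hash_codes(db.ids, QUERY)
        return hashsearch.predict_all(
            db.ids, qcodes, db, self.model.search_config,
            include_self=include_self, symmetrize=symmetrize,
        )

    # -- evaluation --------------------------------------------------------

    def evaluate(
        self, samples: Sequence[DirectedSample] | None = None
    ) -> dict[str, float]:
        """Confusion-matrix metrics under the Hamming-threshold decision rule.

        A directed sample is predicted interacting when the Hamming
        distance between its query and ontic codes is at most ``d``.
        Defaults to the held-out samples of the fitted fold (training
        samples if the model was fitted without a held-out fold).
        """
        if samples is None:
            samples = self.test_samples or self.train_samples
        if not samples:
            raise ValueError("no samples to evaluate")
        q_codes = self.hash_codes([s.query_id for s in samples], QUERY)
        o_codes = self.hash_codes([s.ontic_id for s in samples], ONTIC)
        dists = np.bitwise_count(q_codes ^ o_codes)
        predicted = dists <= self.model.search_config.d
        labels = np.array([s.label for s in samples], dtype=bool)
        counts = ConfusionCounts(
            TP=int((predicted & labels).sum()),
            FP=int((predicted & ~labels).sum()),
            FN=int((~predicted & labels).sum()),
            TN=int((~predicted & ~labels).sum()),
        )
        result = compute_metrics(counts)
        result.update(TP=counts.TP, FP=counts.FP, FN=counts.FN, TN=counts.TN)
        return result

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary (architecture, losses, evaluation)."""
        cfg = self.model.encoder_config
        lines = [
            "DHL-PPI model fit",
            "=" * 60,
            f"proteins:            {len(self.model.records)}",
            f"labeled pairs:       {len(self.model.pairs)}"
            f"  (train samples: {len(self.train_samples)},"
            f" test samples: {len(self.test_samples)})",
            f"cv fold:             {'none (fit on all pairs)' if self.fold is None else self.fold}",
            f"input length L:      {cfg.L}",
            f"embedding dim:       {cfg.embed_dim}",
            f"conv blocks:         {[b[0] for b in cfg.conv_blocks]}"
            f" kernels {[b[1] for b in cfg.conv_blocks]}",
            f"code width N:        {cfg.code_dim} bits",
            f"Hamming threshold d: {self.model.search_config.d}",
            f"epochs trained:      {len(self._trace)}",
        ]
        if len(self._trace):
            lines.append(
                f"total loss:          {self._trace.total[0]:.4f} (epoch 1)"
                f" -> {self._trace.total[-1]:.4f} (final)"
            )
        try:
            ev = self.evaluate()
        except ValueError:
            ev = None
        if ev is not None:
            which = "held-out" if self.test_samples else "training"
            lines.append(f"evaluation ({which} samples, d <= {self.model.search_config.d}):")
            for name in ("precision", "recall", "f1", "specificity", "accuracy", "mcc"):
                lines.append(f"  {name:<12} {ev[name]:.3f}")
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Plot the per-epoch loss components; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.loss_trace
        for col in df.columns:
            ax.plot(np.arange(1, len(df) + 1), df[col], label=col)
        ax.set_xlabel("epoch")
        ax.set_ylabel("mean loss")
        ax.legend()
        return ax
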