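"""Synthetic data generation and brute-force oracles.

Two generators make the pipeline testable without any external data:

* :func:`gen_codes` — uniform random fixed-width binary codes with
  *planted* near-neighbors at exactly controlled Hamming distances, for
  exercising the index and search machinery against ground truth.
* :func:`gen_interactome` — a small artificial interactome in which
  proteins belong to motif families; proteins sharing a family motif may
  interact, cross-family pairs never do. The motif is a detectable
  sequence signal a convolutional encoder can learn, standing in for
  the sequence determinants of real interactomes.

:func:`brute_force_search` is the linear-scan Hamming oracle used to
cross-check the indexed search.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .seqio import AA_CODES, LabeledPair, ProteinRecord

_ALPHABET = "".join(sorted(AA_CODES, key=AA_CODES.get))  # A, G, V, ... C


@dataclass(frozen=True)
class PlantedNeighbor:
    """Ground-truth record: ``clone`` differs from ``base`` in exactly k bits."""

    base: int
    clone: int
    distance: int


@dataclass(frozen=True)
class PlantSpec:
    """Random code database with planted neighbors.

    ``planted`` lists (distance k, count) specs; each planted code is a
    copy of a uniformly chosen base code with exactly k distinct bits
    flipped, appended after the M uniform codes.
    """

    M: int
    N: int = 64
    planted: tuple[tuple[int, int], ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 0 or self.N < 1:
            raise ValueError("M must be >= 0 and N >= 1")
        for k, count in self.planted:
            if not (0 <= k <= self.N):
                raise ValueError(f"planted distance {k} outside [0, N={self.N}]")
            if count < 0:
                raise ValueError("planted count must be non-negative")


def gen_codes(spec: PlantSpec) -> tuple[np.ndarray, list[PlantedNeighbor]]:
    """Generate the code database and its planted-neighbor ground truth.

    Returns ``(codes, ground_truth)``: a uint64 array of M uniform codes
    followed by the planted clones, and one :class:`PlantedNeighbor` per
    clone. Reproducible from ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if spec.N == 64:
        base = rng.integers(0, 2**63, size=spec.M, dtype=np.uint64)
        base |= rng.integers(0, 2, size=spec.M).astype(np.uint64) << np.uint64(63)
    else:
        base = rng.integers(0, 2**spec.N, size=spec.M, dtype=np.uint64)
    codes = list(base)
    truth: list[PlantedNeighbor] = []
    for k, count in spec.planted:
        for _ in range(count):
            b = int(rng.integers(0, spec.M)) if spec.M else 0
            if not codes:
                codes.append(np.uint64(rng.integers(0, 2**spec.N)))
                b = 0
            value = int(codes[b])
            flip_positions = rng.choice(spec.N, size=k, replace=False)
            for pos in flip_positions:
                value ^= 1 << (spec.N - 1 - int(pos))
            codes.append(np.uint64(value))
            truth.append(PlantedNeighbor(base=b, clone=len(codes) - 1, distance=k))
    return np.array(codes, dtype=np.uint64), truth


def brute_force_search(q, codes: np.ndarray, d: int) -> set[int]:
    """Linear-scan oracle: all ordinals with Hamming distance <= d from q."""
    qint = np.uint64(int(q) if not hasattr(q, "as_int") else q.as_int())
    dists = np.bitwise_count(np.asarray(codes, dtype=np.uint64) ^ qint)
    return set(np.flatnonzero(dists <= d).tolist())


@dataclass(frozen=True)
class InteractomeSpec:
    """Motif-family interactome emulating a small labeled PPI dataset.

    Proteins are split evenly across ``n_motif_families``; each carries
    its family's motif (a fixed random ``motif_len``-mer) inserted at a
    random position in an otherwise background-random sequence. Pairs
    within a family interact with probability
    ``p_interact_within_family``; cross-family pairs are the negatives.
    ``n_pairs_per_class`` caps each class (None keeps everything);
    classes are balanced to the smaller class when capped.
    """

    n_proteins: int = 200
    seq_len: int = 200
    motif_len: int = 20
    n_motif_families: int = 4
    p_interact_within_family: float = 0.25
    background_freqs: tuple[float, ...] | None = None
    n_pairs_per_class: int | None = 300
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.motif_len >= self.seq_len:
            raise ValueError("motif_len must be smaller than seq_len")
        if not (0.0 <= self.p_interact_within_family <= 1.0):
            raise ValueError("p_interact_within_family must be a probability")
        if self.background_freqs is not None:
            freqs = np.asarray(self.background_freqs)
            if len(freqs) != 20 or freqs.min() < 0 or not np.isclose(freqs.sum(), 1.0):
                raise ValueError("background_freqs must be 20 non-negative values summing to 1")


def _random_seq(rng: np.random.Generator, length: int, freqs: np.ndarray) -> str:
    idx = rng.choice(20, size=length, p=freqs)
    return "".join(_ALPHABET[i] for i in idx)


def gen_interactome(
    spec: InteractomeSpec,
) -> tuple[list[ProteinRecord], list[LabeledPair]]:
    """Generate proteins and disjoint positive/negative labeled pairs."""
    rng = np.random.default_rng(spec.rng_seed)
    freqs = (
        np.asarray(spec.background_freqs)
        if spec.background_freqs is not None
        else np.full(20, 1 / 20)
    )
    n_fam = spec.n_motif_families
    motifs = [_random_seq(rng, spec.motif_len, freqs) for _ in range(n_fam)]

    records: list[ProteinRecord] = []
    family_of: dict[str, int] = {}
    for i in range(spec.n_proteins):
        seq = _random_seq(rng, spec.seq_len, freqs)
        pid = f"prot{i:04d}"
        fam = i % n_fam if n_fam > 0 else -1
        if fam >= 0:
            pos = int(rng.integers(0, spec.seq_len - spec.motif_len + 1))
            seq = seq[:pos] + motifs[fam] + seq[pos + spec.motif_len:]
        records.append(ProteinRecord(id=pid, sequence=seq))
        family_of[pid] = fam

    positives: list[tuple[str, str]] = []
    negatives: list[tuple[str, str]] = []
    ids = [r.id for r in records]
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            same_family = family_of[a] >= 0 and family_of[a] == family_of[b]
            if same_family:
                if rng.random() < spec.p_interact_within_family:
                    positives.append((a, b))
            else:
                negatives.append((a, b))

    cap = spec.n_pairs_per_class
    if cap is not None:
        n_per_class = min(cap, len(positives), len(negatives))
        if len(positives) > n_per_class:
            keep = rng.choice(len(positives), size=n_per_class, replace=False)
            positives = [positives[i] for i in sorted(keep)]
        if len(negatives) > n_per_class:
            keep = rng.choice(len(negatives), size=n_per_class, replace=False)
            negatives = [negatives[i] for i in sorted(keep)]
    else:
        # keep classes balanced: negatives vastly outnumber positives
        if len(negatives) > len(positives) > 0:
            keep = rng.choice(len(negatives), size=len(positives), replace=False)
            negatives = [negatives[i] for i in sorted(keep)]

    pairs = [LabeledPair(a, b, 1) for a, b in positives]
    pairs += [LabeledPair(a, b, 0) for a, b in negatives]
    return records, pairs
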