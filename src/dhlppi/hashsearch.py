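"""Pigeonhole-indexed Hamming-radius search over binary hash codes.

Predicting interactions reduces to finding, for each query code, every
ontic code within Hamming distance ``d``. Instead of scanning all ``M``
database codes per query (O(M^2) all-against-all), the codes are split
into ``2d`` equal fragments. If two N-bit codes differ in at most ``d``
bits then, by the pigeonhole principle, at least ``d`` of their ``2d``
fragments are bitwise identical. Concatenating each of the C(2d, d)
possible d-subsets of fragments yields an (N/2)-bit *index value*; one
sorted table per subset supports exact-match lookup by binary search.

Search (BCSA) is two-stage: **pre-screening** collects every database
ordinal whose index value matches the query's in at least one table
(guaranteed to contain every true neighbor), then **verification**
filters the candidate set by exact Hamming distance. With balanced
codes the expected number of spurious candidates per query is about
C(2d,d) * M / 2^(N/2) — vanishingly small for M up to tens of
thousands — giving O(M log M) all-against-all prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoder import HashCode

CODEDB_FORMAT = "dhlppi-codedb-1"


@dataclass(frozen=True)
class SearchConfig:
    """Hamming threshold ``d`` and code width ``N`` (2d must divide N)."""

    d: int = 4
    N: int = 64

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError(f"distance threshold d must be >= 1, got {self.d}")
        if self.N % (2 * self.d) != 0:
            raise ValueError(
                f"2d={2 * self.d} must divide the code width N={self.N} "
                "so fragments have integral width"
            )

    @property
    def n_fragments(self) -> int:
        return 2 * self.d

    @property
    def fragment_width(self) -> int:
        return self.N // (2 * self.d)

    @property
    def n_tables(self) -> int:
        return comb(2 * self.d, self.d)

    @property
    def index_bits(self) -> int:
        return self.d * self.fragment_width

    def fragment_combinations(self) -> list[tuple[int, ...]]:
        """d-subsets of fragment positions, in lexicographic order."""
        return list(combinations(range(self.n_fragments), self.d))


def _as_int(code) -> int:
    if isinstance(code, HashCode):
        return code.as_int()
    return int(code)


def hamming(a, b) -> int:
    """Number of differing bit positions between two equal-width codes."""
    if isinstance(a, HashCode) and isinstance(b, HashCode):
        if a.width != b.width:
            raise ValueError(f"width mismatch: {a.width} vs {b.width}")
    return int(_as_int(a) ^ _as_int(b)).bit_count()


def fragments(code, cfg: SearchConfig) -> np.ndarray:
    """Split a code into its 2d contiguous fragments, in bit order.

    Fragment 0 holds bits 0..w-1 (the most significant bits of the
    integer form); concatenating all fragments reconstructs the code.
    """
    value = _as_int(code)
    w = cfg.fragment_width
    mask = (1 << w) - 1
    return np.array(
        [(value >> (cfg.N - (f + 1) * w)) & mask for f in range(cfg.n_fragments)],
        dtype=np.uint64,
    )


def _fragment_matrix(codes: np.ndarray, cfg: SearchConfig) -> np.ndarray:
    """(M, 2d) fragment values for a uint64 code array."""
    w = cfg.fragment_width
    mask = np.uint64((1 << w) - 1)
    cols = [
        (codes >> np.uint64(cfg.N - (f + 1) * w)) & mask
        for f in range(cfg.n_fragments)
    ]
    return np.stack(cols, axis=1)


def _index_values(frag: np.ndarray, combo: tuple[int, ...], cfg: SearchConfig) -> np.ndarray:
    """Concatenate the selected fragments (position order, MSB first)."""
    w = cfg.fragment_width
    d = len(combo)
    vals = np.zeros(frag.shape[0], dtype=np.uint64)
    for j, pos in enumerate(combo):
        vals |= frag[:, pos] << np.uint64(w * (d - 1 - j))
    return vals


def _coerce_codes(codes) -> np.ndarray:
    if isinstance(codes, np.ndarray) and codes.dtype == np.uint64:
        return codes
    return np.array([_as_int(c) for c in codes], dtype=np.uint64)


@dataclass
class CodeDatabase:
    """M ontic codes plus the C(2d,d) sorted fragment-combination tables."""

    ids: list[str]
    codes: np.ndarray                     # (M,) uint64, bit 0 = MSB
    cfg: SearchConfig
    combos: list[tuple[int, ...]] = field(repr=False)
    tables: list[tuple[np.ndarray, np.ndarray]] = field(repr=False)  # (sorted vals, ordinals)

    def __len__(self) -> int:
        return len(self.ids)

    def save(self, path: str | Path) -> None:
        """Persist ids, raw codes and config as TSV; indexes rebuild on load."""
        with open(path, "w") as fh:
            fh.write(f"#{CODEDB_FORMAT}\tN={self.cfg.N}\td={self.cfg.d}\n")
            width = (self.cfg.N + 3) // 4
            for pid, code in zip(self.ids, self.codes):
                fh.write(f"{pid}\t{int(code):0{width}x}\n")

    @classmethod
    def load(cls, path: str | Path) -> "CodeDatabase":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if not header.startswith(f"#{CODEDB_FORMAT}"):
                raise ValueError(f"unrecognized code-database header: {header!r}")
            meta = dict(tok.split("=") for tok in header.split("\t")[1:])
            cfg = SearchConfig(d=int(meta["d"]), N=int(meta["N"]))
            ids, codes = [], []
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                pid, hexcode = line.split("\t")
                ids.append(pid)
                codes.append(int(hexcode, 16))
        return build_index(ids, np.array(codes, dtype=np.uint64), cfg)


@dataclass(frozen=True)
class PPISet:
    """Predicted interaction relations as directed (query, target) pairs."""

    relations: frozenset[tuple[str, str]]
    distances: dict[tuple[str, str], int] = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.relations)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.relations

    def symmetrized(self) -> frozenset[frozenset[str]]:
        """Undirected view: {a, b} present if either direction was predicted."""
        return frozenset(frozenset(p) for p in self.relations)

    def contains_undirected(self, a: str, b: str) -> bool:
        return (a, b) in self.relations or (b, a) in self.relations


def build_index(
    ids: Sequence[str], ontic_codes, cfg: SearchConfig
) -> CodeDatabase:
    """Build the C(2d,d) sorted index tables over the ontic codes.

    Each table corresponds to one d-subset of fragment positions
    (lexicographic enumeration) and holds every protein's concatenated
    index value, sorted with ties broken by ordinal.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in database")
    codes = _coerce_codes(ontic_codes)
    if len(codes) != len(ids):
        raise ValueError("ids and codes length mismatch")
    frag = (
        _fragment_matrix(codes, cfg)
        if len(codes)
        else np.zeros((0, cfg.n_fragments), dtype=np.uint64)
    )
    combos = cfg.fragment_combinations()
    tables = []
    for combo in combos:
        vals = _index_values(frag, combo, cfg)
        order = np.argsort(vals, kind="stable")
        tables.append((vals[order], order))
    return CodeDatabase(ids=ids, codes=codes, cfg=cfg, combos=combos, tables=tables)


def bcsa_candidates(q, db: CodeDatabase, cfg: SearchConfig | None = None) -> set[int]:
    """Pre-screening stage: ordinals matching the query in >= 1 index table."""
    cfg = cfg or db.cfg
    if cfg != db.cfg:
        raise ValueError(f"search config {cfg} does not match database config {db.cfg}")
    qcode = np.array([_as_int(q)], dtype=np.uint64)
    qfrag = _fragment_matrix(qcode, cfg)
    candidates: set[int] = set()
    for combo, (sorted_vals, order) in zip(db.combos, db.tables):
        qv = _index_values(qfrag, combo, cfg)[0]
        lo = np.searchsorted(sorted_vals, qv, side="left")
        hi = np.searchsorted(sorted_vals, qv, side="right")
        if hi > lo:
            candidates.update(order[lo:hi].tolist())
    return candidates


def bcsa(
    q, db: CodeDatabase, cfg: SearchConfig | None = None, return_candidates: bool = False
):
    """Radius search: all database ids within Hamming distance d of ``q``.

    Stage 1 collects candidates by exact index-value match (binary
    search in each sorted table); stage 2 verifies candidates by exact
    Hamming distance. The result equals a brute-force linear scan.
    """
    cfg = cfg or db.cfg
    candidates = bcsa_candidates(q, db, cfg)
    qint = _as_int(q)
    hits: set[str] = set()
    for ordinal in candidates:
        if (qint ^ int(db.codes[ordinal])).bit_count() <= cfg.d:
            hits.add(db.ids[ordinal])
    if return_candidates:
        return hits, {db.ids[o] for o in candidates}
    return hits


def predict_all(
    query_ids: Sequence[str],
    query_codes,
    db: CodeDatabase,
    cfg: SearchConfig | None = None,
    include_self: bool = False,
    symmetrize: bool = False,
) -> PPISet:
    """All-against-all prediction: union of BCSA results over all queries.

    Self-pairs (query id equals target id) are dropped unless
    ``include_self``; with ``symmetrize`` the directed set is replaced by
    one canonical direction per unordered pair.
    """
    cfg = cfg or db.cfg
    qcodes = _coerce_codes(query_codes)
    relations: set[tuple[str, str]] = set()
    distances: dict[tuple[str, str], int] = {}
    for qid, qcode in zip(query_ids, qcodes):
        qint = int(qcode)
        for tid in bcsa(qcode, db, cfg):
            if tid == qid and not include_self:
                continue
            relations.add((qid, tid))
    # recompute distances for the retained relations
    code_of = dict(zip(db.ids, (int(c) for c in db.codes)))
    qcode_of = dict(zip(query_ids, (int(c) for c in qcodes)))
    for qid, tid in relations:
        distances[(qid, tid)] = (qcode_of[qid] ^ code_of[tid]).bit_count()
    if symmetrize:
        undirected: dict[tuple[str, str], int] = {}
        for (qid, tid), dist in distances.items():
            key = (qid, tid) if qid <= tid else (tid, qid)
            undirected[key] = min(dist, undirected.get(key, cfg.N))
        relations = set(undirected)
        distances = undirected
    return PPISet(relations=frozenset(relations), distances=distances)
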