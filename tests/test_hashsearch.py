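"""Fragment index and BCSA radius search against brute-force oracles."""

import numpy as np
import pytest

from dhlppi.encoder import HashCode
from dhlppi.hashsearch import (
    CodeDatabase,
    PPISet,
    SearchConfig,
    bcsa,
    bcsa_candidates,
    build_index,
    fragments,
    hamming,
    predict_all,
)
from dhlppi.synth import PlantSpec, brute_force_search, gen_codes

CFG64 = SearchConfig(d=4, N=64)
CFG8 = SearchConfig(d=2, N=8)


class TestHamming:
    def test_identical_codes(self):
        assert hamming(0xDEADBEEF, 0xDEADBEEF) == 0

    def test_complement_is_full_width(self):
        a = 0x0123456789ABCDEF
        assert hamming(a, a ^ (2**64 - 1)) == 64

    def test_popcount_of_xor(self):
        assert hamming(0b1010, 0b0011) == 2

    def test_symmetry_and_triangle(self):
        rng = np.random.default_rng(0)
        a, b, c = (int(x) for x in rng.integers(0, 2**32, size=3))
        assert hamming(a, b) == hamming(b, a)
        assert hamming(a, c) <= hamming(a, b) + hamming(b, c)

    def test_width_mismatch_rejected(self):
        h1 = HashCode(bits=np.array([1, 0], dtype=np.uint8), role="ontic")
        h2 = HashCode(bits=np.array([1, 0, 1], dtype=np.uint8), role="query")
        with pytest.raises(ValueError):
            hamming(h1, h2)


class TestFragments:
    def test_eight_fragments_of_eight_bits_at_default(self):
        assert CFG64.n_fragments == 8
        assert CFG64.fragment_width == 8
        frags = fragments(0, CFG64)
        assert len(frags) == 8

    def test_concatenation_reconstructs_code(self):
        rng = np.random.default_rng(1)
        for cfg in (CFG64, CFG8, SearchConfig(d=2, N=16)):
            value = int(rng.integers(0, 2 ** min(cfg.N, 62)))
            frags = fragments(value, cfg)
            w = cfg.fragment_width
            rebuilt = 0
            for f in frags:
                rebuilt = (rebuilt << w) | int(f)
            assert rebuilt == value

    def test_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divide"):
            SearchConfig(d=5, N=64)


class TestBuildIndex:
    def test_seventy_tables_of_32_bit_values(self):
        assert CFG64.n_tables == 70
        assert CFG64.index_bits == 32
        codes, _ = gen_codes(PlantSpec(M=20, rng_seed=0))
        db = build_index([f"c{i}" for i in range(20)], codes, CFG64)
        assert len(db.tables) == 70
        for sorted_vals, order in db.tables:
            assert len(sorted_vals) == 20
            assert (sorted_vals < 2**32).all()
            assert (np.diff(sorted_vals.astype(np.int64)) >= 0).all()

    def test_empty_database(self):
        db = build_index([], np.array([], dtype=np.uint64), CFG64)
        assert len(db.tables) == 70
        assert all(len(t[0]) == 0 for t in db.tables)
        assert bcsa(12345, db) == set()

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_index(["a", "a"], np.array([1, 2], dtype=np.uint64), CFG64)

    def test_index_soundness_values_recompute_from_fragments(self):
        codes, _ = gen_codes(PlantSpec(M=50, rng_seed=3))
        db = build_index([f"c{i}" for i in range(50)], codes, CFG64)
        w = CFG64.fragment_width
        for combo, (sorted_vals, order) in zip(db.combos, db.tables):
            for val, ordinal in zip(sorted_vals[:5], order[:5]):
                frags = fragments(int(db.codes[ordinal]), CFG64)
                expected = 0
                for pos in combo:
                    expected = (expected << w) | int(frags[pos])
                assert int(val) == expected

    def test_save_load_round_trip(self, tmp_path):
        codes, _ = gen_codes(PlantSpec(M=30, rng_seed=4))
        db = build_index([f"c{i}" for i in range(30)], codes, CFG64)
        path = tmp_path / "db.tsv"
        db.save(path)
        loaded = CodeDatabase.load(path)
        assert loaded.ids == db.ids
        assert (loaded.codes == db.codes).all()
        assert loaded.cfg == db.cfg


class TestBCSA:
    def test_exact_duplicate_is_found(self):
        codes, _ = gen_codes(PlantSpec(M=100, rng_seed=5))
        db = build_index([f"c{i}" for i in range(100)], codes, CFG64)
        assert "c7" in bcsa(codes[7], db)

    def test_all_far_codes_give_empty_result(self):
        # codes pairwise far apart: complement blocks
        codes = np.array([0, 2**64 - 1], dtype=np.uint64)
        db = build_index(["a", "b"], codes, CFG64)
        q = 0x00000000FFFFFFFF  # 32 bits away from both
        assert bcsa(q, db) == set()

    def test_matches_linear_scan_oracle_on_random_database(self):
        codes, _ = gen_codes(PlantSpec(M=1000, rng_seed=6))
        ids = [f"c{i}" for i in range(len(codes))]
        db = build_index(ids, codes, CFG64)
        rng = np.random.default_rng(7)
        queries = rng.integers(0, 2**63, size=50, dtype=np.uint64)
        # include near-duplicates so the hit set is non-trivial
        queries[:10] = codes[:10] ^ np.uint64(0b101)
        for q in queries:
            expected = {ids[i] for i in brute_force_search(q, codes, CFG64.d)}
            assert bcsa(q, db) == expected

    def test_config_mismatch_rejected(self):
        codes, _ = gen_codes(PlantSpec(M=10, rng_seed=8))
        db = build_index([f"c{i}" for i in range(10)], codes, CFG64)
        with pytest.raises(ValueError, match="config"):
            bcsa(codes[0], db, SearchConfig(d=2, N=64))

    def test_pigeonhole_no_false_negatives_exhaustive_small_width(self):
        # all 256 codes at N=8, d=2: every code within distance d of the
        # query must appear in the pre-screening candidate set
        codes = np.arange(256, dtype=np.uint64)
        ids = [f"c{i}" for i in range(256)]
        db = build_index(ids, codes, CFG8)
        for q in range(256):
            hits, candidates = bcsa(q, db, return_candidates=True)
            expected = {ids[i] for i in brute_force_search(q, codes, CFG8.d)}
            assert hits == expected
            assert expected <= candidates


class TestPredictAll:
    def test_empty_query_set(self):
        codes, _ = gen_codes(PlantSpec(M=10, rng_seed=9))
        db = build_index([f"c{i}" for i in range(10)], codes, CFG64)
        assert len(predict_all([], np.array([], dtype=np.uint64), db)) == 0

    def test_union_of_independent_bcsa_calls(self):
        codes, _ = gen_codes(PlantSpec(M=200, planted=((2, 10),), rng_seed=10))
        ids = [f"c{i}" for i in range(len(codes))]
        db = build_index(ids, codes, CFG64)
        ppi = predict_all(ids, codes, db)
        expected = set()
        for qid, q in zip(ids, codes):
            for tid in bcsa(q, db):
                if tid != qid:
                    expected.add((qid, tid))
        assert set(ppi.relations) == expected

    def test_planted_neighbors_recovered_directed_both_ways(self):
        codes, truth = gen_codes(PlantSpec(M=100, planted=((3, 5), (20, 5)), rng_seed=11))
        ids = [f"c{i}" for i in range(len(codes))]
        db = build_index(ids, codes, CFG64)
        ppi = predict_all(ids, codes, db)
        for t in truth:
            a, b = ids[t.base], ids[t.clone]
            if t.distance <= CFG64.d:
                assert (a, b) in ppi and (b, a) in ppi
            else:
                # distance-20 plants: only reachable if some other random
                # code happens to be close, which brute force confirms
                direct = hamming(int(codes[t.base]), int(codes[t.clone]))
                assert direct > CFG64.d

    def test_self_pairs_excluded_by_default_and_includable(self):
        codes, _ = gen_codes(PlantSpec(M=20, rng_seed=12))
        ids = [f"c{i}" for i in range(20)]
        db = build_index(ids, codes, CFG64)
        default = predict_all(ids, codes, db)
        assert all(q != t for q, t in default.relations)
        with_self = predict_all(ids, codes, db, include_self=True)
        assert all((i, i) in with_self for i in ids)

    def test_database_order_invariance(self):
        codes, _ = gen_codes(PlantSpec(M=150, planted=((1, 8),), rng_seed=13))
        ids = [f"c{i}" for i in range(len(codes))]
        perm = np.random.default_rng(14).permutation(len(ids))
        db1 = build_index(ids, codes, CFG64)
        db2 = build_index([ids[i] for i in perm], codes[perm], CFG64)
        p1 = predict_all(ids, codes, db1)
        p2 = predict_all(ids, codes, db2)
        assert set(p1.relations) == set(p2.relations)

    def test_symmetrize_collapses_directions(self):
        codes, _ = gen_codes(PlantSpec(M=50, planted=((2, 5),), rng_seed=15))
        ids = [f"c{i}" for i in range(len(codes))]
        db = build_index(ids, codes, CFG64)
        sym = predict_all(ids, codes, db, symmetrize=True)
        assert all(q <= t for q, t in sym.relations)
        directed = predict_all(ids, codes, db)
        assert sym.symmetrized() == directed.symmetrized()


class TestCandidateSetScaling:
    def test_mean_candidate_set_is_tiny_for_uniform_codes(self):
        # expectation argument: ~C(2d,d) * M / 2^(N/2) spurious candidates
        M = 5000
        codes, _ = gen_codes(PlantSpec(M=M, rng_seed=16))
        db = build_index([f"c{i}" for i in range(M)], codes, SearchConfig())
        rng = np.random.default_rng(17)
        queries = rng.integers(0, 2**63, size=100, dtype=np.uint64)
        sizes = [len(bcsa_candidates(q, db)) for q in queries]
        assert np.mean(sizes) < 0.01 * M
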