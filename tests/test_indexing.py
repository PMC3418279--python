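"""Indexer tests against the brute-force matching oracle (reduced scale)."""

import numpy as np
import pytest

import motifindexer as mi
from motifindexer.indexing import concrete_window_codes, window_digits

from conftest import brute_force_presence_counts


class TestIndexPromoters:
    def test_single_homopolymer_promoter(self):
        # one all-A promoter: exactly the expansions of "AAA" get count 1
        pset = mi.PromoterSet(["g"], ["A" * 30], window_length=30)
        idx = mi.index_promoters(pset, mi.ALPHA11, 3)
        expected = {
            mi.encode(w, mi.ALPHA11)
            for w in mi.degenerate_expansions("AAA", mi.ALPHA11)
        }
        nonzero = set(np.flatnonzero(idx.counts).tolist())
        assert nonzero == expected
        assert len(nonzero) == 5**3
        assert np.all(idx.counts[sorted(nonzero)] == 1)

    def test_identical_promoters_count_presence_not_multiplicity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30))
        pset = mi.PromoterSet(["a", "b"], [seq, seq], window_length=30)
        idx = mi.index_promoters(pset, mi.ALPHA11, 3)
        assert set(np.unique(idx.counts)) <= {0, 2}

    def test_matches_brute_force_oracle_all_codes(self, random_promoters):
        idx = mi.index_promoters(random_promoters, mi.ALPHA11, 3)
        oracle = brute_force_presence_counts(random_promoters, mi.ALPHA11, 3)
        assert np.array_equal(idx.counts, oracle)

    def test_alpha5_matches_brute_force(self, random_promoters):
        idx = mi.index_promoters(random_promoters, mi.ALPHA5, 3)
        oracle = brute_force_presence_counts(random_promoters, mi.ALPHA5, 3)
        assert np.array_equal(idx.counts, oracle)

    def test_union_additivity_and_permutation_invariance(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=25)) for _ in range(12)]
        ids = [f"g{i}" for i in range(12)]
        full = mi.PromoterSet(ids, seqs, window_length=25)
        part1 = mi.PromoterSet(ids[:5], seqs[:5], window_length=25)
        part2 = mi.PromoterSet(ids[5:], seqs[5:], window_length=25)
        perm = rng.permutation(12)
        shuffled = mi.PromoterSet(
            [ids[i] for i in perm], [seqs[i] for i in perm], window_length=25
        )
        c_full = mi.index_promoters(full, mi.ALPHA11, 3).counts
        c_sum = (
            mi.index_promoters(part1, mi.ALPHA11, 3).counts
            + mi.index_promoters(part2, mi.ALPHA11, 3).counts
        )
        c_perm = mi.index_promoters(shuffled, mi.ALPHA11, 3).counts
        assert np.array_equal(c_full, c_sum)
        assert np.array_equal(c_full, c_perm)

    def test_more_than_64_promoters_batches_correctly(self, rng):
        # the packed transform runs in batches of 64; check a 70-promoter set
        seqs = ["".join(rng.choice(list("ACGT"), size=25)) for _ in range(70)]
        pset = mi.PromoterSet([f"g{i}" for i in range(70)], seqs, window_length=25)
        idx = mi.index_promoters(pset, mi.ALPHA11, 3)
        oracle = brute_force_presence_counts(pset, mi.ALPHA11, 3)
        assert np.array_equal(idx.counts, oracle)

    def test_full_wildcard_counts_clean_promoters(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(5)]
        seqs.append("N" * 30)  # no clean window at all
        pset = mi.PromoterSet([f"g{i}" for i in range(6)], seqs, window_length=30)
        idx = mi.index_promoters(pset, mi.ALPHA11, 3)
        assert idx.counts[-1] == 5  # "nnn" counts promoters with >=1 clean window
        assert int(idx.counts.max()) <= len(pset)

    def test_windows_spanning_n_are_skipped(self):
        pset = mi.PromoterSet(["g"], ["ACGTNACGTACGTACGTACGT"[:20]], window_length=20)
        win, starts = window_digits(pset.sequences[0], 3)
        # windows at starts 3,4,5 overlap the N at position 5
        assert set(starts.tolist()) == set(range(1, 19)) - {3, 4, 5}
        idx = mi.index_promoters(pset, mi.ALPHA11, 3)
        oracle = brute_force_presence_counts(pset, mi.ALPHA11, 3)
        assert np.array_equal(idx.counts, oracle)


class TestOccurrenceIndex:
    def test_occurrences_and_position_sums_match_collect_positions(self, random_promoters, rng):
        occ = mi.occurrence_index(random_promoters, mi.ALPHA11, 3)
        for code in rng.integers(0, 11**3, size=60):
            word = mi.decode(int(code), 3, mi.ALPHA11)
            positions = mi.collect_positions(random_promoters, word, mi.ALPHA11)
            flat = [p for ps in positions.values() for p in ps]
            assert occ.occurrences[code] == len(flat)
            assert occ.pos_sum[code] == sum(flat)

    def test_total_windows(self, random_promoters):
        occ = mi.occurrence_index(random_promoters, mi.ALPHA11, 3)
        assert occ.total_windows == 20 * 28


class TestCollectPositions:
    def test_universal_wildcard_hits_every_start(self):
        pset = mi.PromoterSet(["g"], ["ACGT" * 10], window_length=40)
        pos = mi.collect_positions(pset, "nnn", mi.ALPHA11)
        assert pos == {"g": list(range(1, 39))}

    def test_absent_oligo_gives_empty_map(self):
        pset = mi.PromoterSet(["g"], ["A" * 30], window_length=30)
        assert mi.collect_positions(pset, "CCC", mi.ALPHA11) == {}

    def test_presence_consistency_with_index(self, random_promoters):
        idx = mi.index_promoters(random_promoters, mi.ALPHA11, 3)
        for code in range(0, 11**3, 97):
            word = mi.decode(code, 3, mi.ALPHA11)
            genes = mi.collect_positions(random_promoters, word, mi.ALPHA11)
            assert len(genes) == idx.counts[code]


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path, random_promoters):
        idx = mi.index_promoters(random_promoters, mi.ALPHA11, 3)
        mi.save_index(idx, tmp_path / "genome")
        loaded = mi.load_index(tmp_path / "genome")
        assert np.array_equal(loaded.counts, idx.counts)
        assert loaded.n_promoters == idx.n_promoters
        assert loaded.alphabet is mi.ALPHA11
        assert loaded.word_length == 3

    def test_checksum_detects_corruption(self, tmp_path, random_promoters):
        idx = mi.index_promoters(random_promoters, mi.ALPHA11, 3)
        mi.save_index(idx, tmp_path / "genome")
        raw = (tmp_path / "genome.counts").read_bytes()
        (tmp_path / "genome.counts").write_bytes(raw[:-1] + bytes([raw[-1] ^ 1]))
        with pytest.raises(IOError):
            mi.load_index(tmp_path / "genome")


def test_window_codes_match_manual_encoding():
    seq = "ACGTAC"
    codes, starts = concrete_window_codes(seq, 3, mi.ALPHA11)
    words = [seq[i : i + 3] for i in range(4)]
    assert codes.tolist() == [mi.encode(w, mi.ALPHA11) for w in words]
    assert starts.tolist() == [1, 2, 3, 4]


def test_numpy_fallback_matches_compiled_path(monkeypatch, rng):
    """The pure-numpy transform path computes identical counts and sums."""
    import motifindexer.indexing as ix

    seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(30)]
    pset = mi.PromoterSet([f"g{i}" for i in range(30)], seqs, window_length=40)
    fast = mi.index_promoters(pset, mi.ALPHA11, 4).counts
    occ_fast = mi.occurrence_index(pset, mi.ALPHA11, 4)
    monkeypatch.setattr(ix, "_HAVE_NUMBA", False)
    slow = mi.index_promoters(pset, mi.ALPHA11, 4).counts
    occ_slow = mi.occurrence_index(pset, mi.ALPHA11, 4)
    assert np.array_equal(fast, slow)
    assert np.array_equal(occ_fast.occurrences, occ_slow.occurrences)
    assert np.array_equal(occ_fast.pos_sum, occ_slow.pos_sum)
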