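"""Conserved p-values, ortholog maps, and the genome-wide bias scan."""

from math import comb

import numpy as np
import pytest

import motifindexer as mi
from motifindexer.comparative import restricted_degenerate_codes


class TestConservedPvalue:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (1.64e-38, 2.91e-35, 2.91e-35),  # second species is the worse one
            (6.57e-06, 2.61e-06, 6.57e-06),  # first species is the worse one
            (1e-6, 1e-6, 1e-6),              # idempotent
        ],
    )
    def test_larger_of_the_two(self, p1, p2, expected):
        assert mi.conserved_pvalue(p1, p2) == expected

    def test_symmetric_and_bounding(self):
        assert mi.conserved_pvalue(0.1, 0.9) == mi.conserved_pvalue(0.9, 0.1)
        assert mi.conserved_pvalue(0.1, 0.9) >= 0.1

    def test_rejects_non_probabilities(self):
        with pytest.raises(ValueError):
            mi.conserved_pvalue(-0.1, 0.5)


class TestOrthologMap:
    def test_one_to_one_enforced(self):
        with pytest.raises(ValueError):
            mi.OrthologMap([("a", "x"), ("a", "y")])
        with pytest.raises(ValueError):
            mi.OrthologMap([("a", "x"), ("b", "x")])

    def test_tsv_round_trip(self, tmp_path):
        m = mi.OrthologMap([("a", "x"), ("b", "y")])
        path = tmp_path / "orthologs.tsv"
        m.write_tsv(path)
        again = mi.OrthologMap.read_tsv(path)
        assert again.pairs == m.pairs
        assert again.ortholog_of("a") == "x"


@pytest.fixture(scope="module")
def ortho_fixture():
    """Two diverged species sharing a protected TSS-proximal planted motif."""
    spec = mi.FixtureSpec(
        n_genome_promoters=90,
        window_length=60,
        cluster_size=25,
        seed=5,
        substitution_rate=0.15,
        plants=(
            mi.PlantedMotif(
                "rGTCw", 0.8, 0.02, positions=("tss_biased", 40, 56, 1.0)
            ),
        ),
    )
    return mi.generate_ortholog_fixture(spec, protect_plants=True)


class TestConservedMotifAnalysis:
    def test_protected_plant_survives_conserved_analysis(self, ortho_fixture):
        fx = ortho_fixture
        gi1 = mi.index_promoters(fx.species1, mi.ALPHA11, 5)
        gi2 = mi.index_promoters(fx.species2, mi.ALPHA11, 5)
        table = mi.conserved_motif_analysis(
            fx.cluster_ids, fx.orthologs, fx.species1, fx.species2,
            gi1, gi2, cutoff=1e-3,
        )
        assert len(table)
        top = table.iloc[0]
        planted = mi.canonical_word("rGTCw", mi.ALPHA11)
        assert top["motif"] == planted
        assert top["conserved_pvalue"] == max(top["pvalue_1"], top["pvalue_2"])
        assert np.all(
            table["conserved_pvalue"]
            >= np.maximum(0, table[["pvalue_1", "pvalue_2"]].max(axis=1) - 1e-18)
        )

    def test_unprotected_plant_is_dropped_by_max_rule(self):
        # plant diverges like background in species 2 -> conserved p is large
        spec = mi.FixtureSpec(
            n_genome_promoters=90,
            window_length=60,
            cluster_size=25,
            seed=5,
            substitution_rate=0.35,
            plants=(
                mi.PlantedMotif(
                    "rGTCw", 0.8, 0.02, positions=("tss_biased", 40, 56, 1.0)
                ),
            ),
        )
        fx = mi.generate_ortholog_fixture(spec, protect_plants=False)
        gi1 = mi.index_promoters(fx.species1, mi.ALPHA11, 5)
        gi2 = mi.index_promoters(fx.species2, mi.ALPHA11, 5)
        table = mi.conserved_motif_analysis(
            fx.cluster_ids, fx.orthologs, fx.species1, fx.species2,
            gi1, gi2, cutoff=1e-5,
        )
        planted = mi.canonical_word("rGTCw", mi.ALPHA11)
        assert planted not in set(table["motif"])

    def test_zero_divergence_gives_identical_species(self):
        spec = mi.FixtureSpec(
            n_genome_promoters=30, window_length=40, cluster_size=10,
            seed=9, substitution_rate=0.0,
        )
        fx = mi.generate_ortholog_fixture(spec)
        assert fx.species1.sequences == fx.species2.sequences

    def test_no_shared_orthologs_is_an_error(self, ortho_fixture):
        fx = ortho_fixture
        gi1 = mi.index_promoters(fx.species1, mi.ALPHA11, 5)
        with pytest.raises(ValueError):
            mi.conserved_motif_analysis(
                ["not_a_gene"], fx.orthologs, fx.species1, fx.species2,
                gi1, gi1, cutoff=1e-3,
            )


class TestRestrictedEnumeration:
    def test_enumeration_size_matches_combinatorics_at_l8(self):
        codes = restricted_degenerate_codes(mi.ALPHA11, 8, 2, "ryswn")
        expected = (
            comb(8, 0) * 4**8
            + comb(8, 1) * 5 * 4**7
            + comb(8, 2) * 25 * 4**6
        )
        assert codes.size == expected == 3_588_096
        assert np.unique(codes).size == codes.size

    def test_no_excluded_letters_and_degeneracy_bound(self):
        codes = restricted_degenerate_codes(mi.ALPHA11, 4, 2, "ryswn")
        banned = set("mk")
        for code in np.random.default_rng(0).choice(codes, 200, replace=False):
            word = mi.decode(int(code), 4, mi.ALPHA11)
            wobbles = [c for c in word if c not in "ACGT"]
            assert len(wobbles) <= 2
            assert not banned & set(wobbles)

    def test_three_wobble_words_never_enumerated(self):
        codes = set(restricted_degenerate_codes(mi.ALPHA11, 4, 2, "ryswn").tolist())
        assert mi.encode("rrrA", mi.ALPHA11) not in codes
        assert mi.encode("rrAA", mi.ALPHA11) in codes


@pytest.fixture(scope="module")
def biased_genome():
    spec = mi.FixtureSpec(
        n_genome_promoters=150,
        window_length=60,
        cluster_size=150,
        seed=13,
        plants=(
            mi.PlantedMotif(
                "GGCC", cluster_fraction=0.6, positions=("tss_biased", 45, 57, 1.0)
            ),
        ),
    )
    genome, _, _ = mi.generate_fixture(spec)
    return genome


class TestGenomeBiasScan:
    def test_planted_tss_proximal_family_tops_ranking(self, biased_genome):
        scan = mi.genome_bias_scan(
            biased_genome, z_cutoff=3.0, word_length=4, max_degenerate=2
        )
        assert len(scan)
        top = scan.iloc[0]["motif"]
        # the top-ranked biased word must match the planted element (GGCC is
        # palindromic, so orientation does not matter)
        assert mi.matches(top, "GGCC", mi.ALPHA11) or mi.matches(
            mi.reverse_complement(top), "GGCC", mi.ALPHA11
        )

    def test_null_genome_survivors_near_gaussian_tail(self):
        spec = mi.FixtureSpec(
            n_genome_promoters=150, window_length=60, cluster_size=10, seed=21
        )
        null_genome, _, _ = mi.generate_fixture(spec)
        scan = mi.genome_bias_scan(
            null_genome, z_cutoff=3.0, word_length=4, max_degenerate=2
        )
        n_enumerated = restricted_degenerate_codes(mi.ALPHA11, 4, 2, "ryswn").size
        # ~0.00135 of words (before RC dedup) clear z>3 under the null
        assert len(scan) < 0.00135 * n_enumerated * 4 + 10

    def test_intersect_partitions_scans(self, biased_genome):
        scan1 = mi.genome_bias_scan(biased_genome, 2.0, word_length=4)
        shared, only1, only2 = mi.intersect_biased(scan1, scan1.copy())
        assert len(shared) == len(scan1)
        assert not len(only1) and not len(only2)

        spec = mi.FixtureSpec(
            n_genome_promoters=100, window_length=60, cluster_size=10, seed=77
        )
        other, _, _ = mi.generate_fixture(spec)
        scan2 = mi.genome_bias_scan(other, 2.0, word_length=4)
        shared, only1, only2 = mi.intersect_biased(scan1, scan2)
        assert len(shared) + len(only1) == len(scan1)
        assert len(shared) + len(only2) == len(scan2)

    def test_mismatched_parameters_rejected(self, biased_genome):
        scan1 = mi.genome_bias_scan(biased_genome, 2.0, word_length=4)
        scan2 = mi.genome_bias_scan(biased_genome, 2.0, word_length=4, max_degenerate=1)
        with pytest.raises(ValueError):
            mi.intersect_biased(scan1, scan2)
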