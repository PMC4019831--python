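"""In silico PCR-RFLP: amplification, digestion, gel typing, genotypes."""

import numpy as np
import pytest

from rhizotax.io import DEFAULT_ENZYMES, FD1_RD1, RunConfig, read_pattern_table, table3_path
from rhizotax.phenotype import UndefinedSimilarityError, cut_at_similarity, node_height
from rhizotax.rflp import (
    AmbiguousAmpliconError,
    Amplicon,
    AmpliconError,
    BandMatrix,
    DigestProfile,
    GenotypeTable,
    assign_pattern_letters,
    band_matrix,
    combine_genotypes,
    digest,
    extract_amplicon,
    GelPattern,
    genotype_amplicons,
    nei_li_similarity,
    rflp_dendrogram,
    roman,
    to_gel,
)

from _oracles import naive_digest_oracle

REV_RC = "GGCTGGATCACCTCCTT"  # reverse complement of rD1


def _template(insert: str) -> str:
    return FD1_RD1.forward + insert + REV_RC


class TestExtractAmplicon:
    def test_constructed_template_length(self, rng):
        insert = "".join(rng.choice(list("ACGT"), size=1000))
        amp = extract_amplicon(_template(insert), FD1_RD1)
        assert len(amp) == 20 + 1000 + 17
        assert amp.sequence == _template(insert)

    def test_missing_reverse_site(self):
        with pytest.raises(AmpliconError, match="reverse"):
            extract_amplicon(FD1_RD1.forward + "A" * 300, FD1_RD1)

    def test_exact_match_returns_insert_plus_primers(self):
        insert = "ACGT" * 50
        amp = extract_amplicon("TTTT" + _template(insert) + "GGGG", FD1_RD1, max_mismatches=0)
        assert amp.sequence == _template(insert)
        assert (amp.start, amp.end) == (4, 4 + len(_template(insert)))

    def test_ambiguous_products_listed(self):
        t = _template("A" * 50) + "C" * 10 + REV_RC
        with pytest.raises(AmbiguousAmpliconError, match="coordinates"):
            extract_amplicon(t, FD1_RD1)


class TestDigest:
    def test_mboi_example(self, enzymes):
        assert digest("AAGATCTTGATCAA", enzymes["MboI"]).fragments == (2, 6, 6)

    def test_no_site_single_fragment(self, enzymes):
        assert digest("A" * 73, enzymes["MboI"]).fragments == (73,)

    def test_hinfi_degenerate_site(self, enzymes):
        assert digest("GACTC", enzymes["HinfI"]).fragments == (1, 4)

    def test_ambiguous_base_rejected_with_position(self, enzymes):
        with pytest.raises(ValueError, match="position 2"):
            digest("ACNGT", enzymes["MboI"])

    def test_naive_scan_oracle_on_random_sequences(self, rng, enzymes):
        for _ in range(60):
            n = int(rng.integers(200, 2001))
            seq = "".join(rng.choice(list("ACGT"), size=n))
            for e in enzymes.values():
                assert digest(seq, e).fragments == naive_digest_oracle(
                    seq, e.recognition, e.cut_offset
                ), f"enzyme {e.name}"

    def test_fragment_length_conservation(self, rng, enzymes):
        seq = "".join(rng.choice(list("ACGT"), size=1500))
        for e in enzymes.values():
            assert digest(seq, e).total == 1500

    def test_agrees_with_biopython_restriction(self, rng):
        from Bio.Restriction import AluI, HinfI, MboI, MspI, RsaI, TaqI
        from Bio.Seq import Seq

        panel = {"AluI": AluI, "MboI": MboI, "RsaI": RsaI,
                 "TaqI": TaqI, "MspI": MspI, "HinfI": HinfI}
        mine = {e.name: e for e in DEFAULT_ENZYMES}
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        for name, bio_enzyme in panel.items():
            cuts = bio_enzyme.search(Seq(seq))  # 1-based positions after which... cut before
            bounds = [0] + sorted(c - 1 for c in cuts) + [len(seq)]
            expected = tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))
            assert digest(seq, mine[name]).fragments == expected, name

    def test_non_palindromic_pattern_scans_both_strands(self):
        from rhizotax.io import EnzymeDef

        e = EnzymeDef("FakeI", "GGGA", 1)  # non-palindromic
        # site on the reverse strand only: revcomp(GGGA)=TCCC present
        assert digest("AATCCCAA", e).fragments != (8,)
        assert digest("AATCCCAA", e, both_strands=False).fragments == (8,)


class TestGelModel:
    def test_all_fragments_below_detection(self):
        p = DigestProfile("s", "MboI", (2, 6, 6))
        assert to_gel(p, min_size=50).bands == ()

    def test_co_migration_merge(self):
        p = DigestProfile("s", "E", (200, 500, 505))
        assert to_gel(p, min_size=50, tolerance=0.05).bands == (502.5, 200.0)

    def test_zero_tolerance_keeps_distinct_sizes(self):
        p = DigestProfile("s", "E", (60, 60, 61, 40))
        assert to_gel(p, min_size=50, tolerance=0.0).bands == (61.0, 60.0)

    def test_bands_strictly_decreasing_and_separated(self, rng):
        frags = tuple(int(x) for x in rng.integers(30, 1500, size=12))
        gel = to_gel(DigestProfile("s", "E", frags), min_size=50, tolerance=0.05)
        for hi, lo in zip(gel.bands, gel.bands[1:]):
            assert hi - lo > 0.05 * hi - 1e-9


class TestPatternLetters:
    def test_identical_patterns_share_a_letter(self):
        pats = [GelPattern(f"s{i}", "E", (500.0, 200.0)) for i in range(3)]
        assert assign_pattern_letters(pats) == ["A", "A", "A"]

    def test_first_appearance_order(self):
        x = (500.0, 200.0)
        y = (900.0,)
        pats = [GelPattern("a", "E", x), GelPattern("b", "E", y), GelPattern("c", "E", x)]
        assert assign_pattern_letters(pats) == ["A", "B", "A"]

    def test_partition_invariant_under_reordering(self, rng):
        bands = [(100.0,), (200.0,), (100.0,), (300.0,), (200.0,), (100.0,)]
        pats = [GelPattern(f"s{i}", "E", b) for i, b in enumerate(bands)]
        base = assign_pattern_letters(pats)
        order = rng.permutation(len(pats))
        perm = assign_pattern_letters([pats[i] for i in order])
        # co-membership is preserved even though letters relabel
        for a in range(len(pats)):
            for b in range(len(pats)):
                ia, ib = list(order).index(a), list(order).index(b)
                assert (base[a] == base[b]) == (perm[ia] == perm[ib])

    def test_mixed_enzymes_rejected(self):
        with pytest.raises(ValueError):
            assign_pattern_letters(
                [GelPattern("a", "E1", (1.0,)), GelPattern("b", "E2", (1.0,))]
            )


@pytest.fixture(scope="module")
def table3():
    return read_pattern_table(table3_path())


class TestCombineGenotypes:
    def test_strains_share_label_iff_tuples_identical(self, table3):
        labelled, _ = combine_genotypes(table3)
        by_strain = dict(zip(labelled.strains, zip(labelled.letters, labelled.genotypes)))
        for s1, (t1, g1) in by_strain.items():
            for s2, (t2, g2) in by_strain.items():
                assert (t1 == t2) == (g1 == g2), (s1, s2)

    def test_isolate_genotypes_matching_references(self, table3):
        labelled, _ = combine_genotypes(table3)
        by_strain = dict(zip(labelled.strains, labelled.genotypes))
        assert by_strain["AG17"] == by_strain["Mesorhizobium septentrionale SDW018"]
        assert by_strain["AG20"] == by_strain["Mesorhizobium tianshanense USDA3592"]

    def test_roman_labels_in_first_appearance_order(self):
        table = GenotypeTable(
            strains=["a", "b", "c"], enzymes=["E"], letters=[("A",), ("B",), ("A",)]
        )
        labelled, _ = combine_genotypes(table)
        assert labelled.genotypes == ["I", "II", "I"]

    def test_missing_letter_names_strain_and_enzyme(self):
        table = GenotypeTable(
            strains=["a"], enzymes=["E1", "E2"], letters=[("A", "")]
        )
        with pytest.raises(ValueError, match="'a' x 'E2'"):
            combine_genotypes(table)

    def test_combined_partition_refines_each_enzyme_partition(self, table3):
        labelled, _ = combine_genotypes(table3)
        for col in range(len(table3.enzymes)):
            for i in range(len(table3.strains)):
                for j in range(len(table3.strains)):
                    if labelled.genotypes[i] == labelled.genotypes[j]:
                        assert table3.letters[i][col] == table3.letters[j][col]

    def test_adding_an_enzyme_never_decreases_genotypes(self, rng):
        n = 12
        letters3 = [tuple(rng.choice(list("AB"), size=3)) for _ in range(n)]
        letters4 = [t + (rng.choice(list("AB")),) for t in letters3]
        strains = [f"s{i}" for i in range(n)]
        _, c3 = combine_genotypes(GenotypeTable(strains, ["E1", "E2", "E3"], letters3))
        _, c4 = combine_genotypes(GenotypeTable(strains, ["E1", "E2", "E3", "E4"], letters4))
        assert c4.n_genotypes >= c3.n_genotypes

    def test_roman_numerals(self):
        assert [roman(i) for i in (1, 4, 9, 12, 25)] == ["I", "IV", "IX", "XII", "XXV"]


class TestBandMatrix:
    def _patterns(self):
        return [
            GelPattern("s1", "E1", (500.0, 200.0)),
            GelPattern("s2", "E1", (500.0, 200.0)),
            GelPattern("s3", "E1", (500.0, 90.0)),
            GelPattern("s1", "E2", (800.0,)),
            GelPattern("s2", "E2", (800.0,)),
            GelPattern("s3", "E2", (800.0,)),
        ]

    def test_identical_patterns_identical_rows(self):
        bm = band_matrix(self._patterns(), tolerance=0.0)
        i1, i2 = bm.strains.index("s1"), bm.strains.index("s2")
        np.testing.assert_array_equal(bm.values[i1], bm.values[i2])

    def test_unique_band_yields_singleton_column(self):
        bm = band_matrix(self._patterns(), tolerance=0.0)
        col = bm.bands.index(("E1", 90.0))
        assert bm.values[:, col].sum() == 1

    def test_column_count_equals_band_set_union(self):
        pats = self._patterns()
        bm = band_matrix(pats, tolerance=0.0)
        union = {(p.enzyme, b) for p in pats for b in p.bands}
        assert len(bm.bands) == len(union)

    def test_cross_strain_binning_collapses_near_identical_sizes(self):
        pats = [GelPattern("s1", "E", (500.0,)), GelPattern("s2", "E", (505.0,))]
        bm = band_matrix(pats, tolerance=0.05)
        assert len(bm.bands) == 1
        assert bm.values.sum() == 2


class TestNeiLi:
    def test_identical_band_sets(self):
        assert nei_li_similarity({1, 2, 3}, {1, 2, 3}) == 1.0

    def test_disjoint_band_sets(self):
        assert nei_li_similarity({1, 2}, {3, 4}) == 0.0

    def test_shared_and_unique_counts(self):
        x = {1, 2, 3, 4, 5, 6}
        y = {1, 2, 3, 4, 7, 8}
        assert nei_li_similarity(x, y) == pytest.approx(8 / 12)

    def test_binary_vector_input(self):
        assert nei_li_similarity([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(0.5)

    def test_both_empty_rejected(self):
        with pytest.raises(UndefinedSimilarityError):
            nei_li_similarity(set(), set())


class TestRflpDendrogram:
    def test_identical_genotypes_merge_at_zero(self):
        values = np.array([[1, 1, 0], [1, 1, 0], [0, 1, 1]])
        bm = BandMatrix(["a", "b", "c"], [("E", 1.0), ("E", 2.0), ("E", 3.0)], values)
        tree = rflp_dendrogram(bm)
        ab = tree.find("a").distance(tree.find("b"))
        assert ab == pytest.approx(0.0, abs=1e-12)

    def test_planted_groups_split_first(self):
        values = np.array(
            [
                [1, 1, 1, 0, 0, 0],
                [1, 1, 1, 0, 0, 0],
                [1, 1, 0, 0, 0, 1],
                [0, 0, 0, 1, 1, 1],
                [0, 0, 1, 1, 1, 0],
                [0, 0, 0, 1, 1, 1],
            ]
        )
        bands = [("E", float(i)) for i in range(6)]
        bm = BandMatrix([f"s{i}" for i in range(6)], bands, values)
        tree = rflp_dendrogram(bm)
        top = {frozenset(t.name for t in child.tips()) or frozenset({child.name})
               for child in tree.children}
        assert top == {frozenset({"s0", "s1", "s2"}), frozenset({"s3", "s4", "s5"})}

    def test_deterministic_across_strain_orderings(self, rng):
        values = rng.integers(0, 2, size=(7, 15))
        values[:, 0] = 1  # no empty band rows
        bands = [("E", float(i)) for i in range(15)]
        ids = [f"s{i}" for i in range(7)]
        t1 = rflp_dendrogram(BandMatrix(ids, bands, values))
        perm = rng.permutation(7)
        t2 = rflp_dendrogram(BandMatrix([ids[i] for i in perm], bands, values[perm]))
        c1 = {frozenset(c) for c in cut_at_similarity(t1, 0.6)}
        c2 = {frozenset(c) for c in cut_at_similarity(t2, 0.6)}
        assert c1 == c2


class TestEndToEndGenotyping:
    def test_single_sequence_round_trip(self, rng):
        from rhizotax.simulate import random_amplicon

        amp = random_amplicon(seed=11)
        table, patterns = genotype_amplicons([amp, amp], RunConfig())
        assert table.letters[0] == table.letters[1]
        assert all(l == "A" for l in table.letters[0])
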