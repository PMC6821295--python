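"""Codon-table data model: enumeration, translation, mutations, round trips."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fscodes.codes import (
    GeneticCode,
    MutationClass,
    NullCodonError,
    all_codons,
    builtin_code,
    classify_mutation,
    hamming,
    mutation_neighbors,
    normalize_codon,
)

codon_strategy = st.text(alphabet="ACGU", min_size=3, max_size=3)


class TestAllCodons:
    def test_counts(self):
        assert len(all_codons(3)) == 64
        assert len(all_codons(4)) == 256

    def test_order_is_classic_table_order(self):
        codons = all_codons(3)
        assert codons[:4] == ("UUU", "UUC", "UUA", "UUG")
        assert codons[-1] == "GGG"
        assert len(set(codons)) == 64

    def test_unsupported_length(self):
        with pytest.raises(ValueError):
            all_codons(2)


class TestNeighbors:
    @pytest.mark.parametrize("codon,expected", [("UUU", 9), ("AAAA", 12)])
    def test_neighbor_count(self, codon, expected):
        nbrs = mutation_neighbors(codon)
        assert len(nbrs) == expected
        assert len(set(nbrs)) == expected
        assert all(hamming(codon, n) == 1 for n in nbrs)

    @given(codon_strategy)
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, codon):
        for nbr in mutation_neighbors(codon):
            assert codon in mutation_neighbors(nbr)

    def test_dna_input_normalized(self):
        assert normalize_codon("ttt") == "UUU"
        with pytest.raises(ValueError):
            normalize_codon("UXN")


class TestBuiltins:
    @pytest.mark.parametrize(
        "name,counts",
        [
            ("standard", (61, 3, 0)),
            ("colorado", (63, 1, 0)),
            ("fs20", (20, 1, 43)),
            ("red20", (20, 3, 41)),
            ("fs16", (16, 1, 47)),
            ("red15", (15, 3, 46)),
            ("fsquad", (20, 1, 235)),
        ],
    )
    def test_sense_stop_null_counts(self, name, counts):
        assert builtin_code(name).counts() == counts

    def test_standard_is_canonical(self, standard):
        assert standard.label("AUG") == "M"
        assert standard.label("UAA") == "*"
        assert standard.label("UGG") == "W"
        assert set(standard.stop_codons) == {"UAA", "UAG", "UGA"}

    def test_reduced_codes_one_codon_per_amino_acid(self, red20, red15):
        for code in (red20, red15):
            for aa in code.amino_acids:
                assert len(code.codons_for(aa)) == 1

    def test_red_codes_keep_standard_assignments(self, standard, red20, red15):
        # natural tRNAs are charged with their natural amino acid
        for code in (red20, red15):
            for codon in code.sense_codons:
                assert code.label(codon) == standard.label(codon)
            assert set(code.stop_codons) == {"UAA", "UAG", "UGA"}

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            builtin_code("nonsense20")

    def test_assignment_total_over_all_codons(self):
        for name in ("standard", "red20", "fsquad"):
            code = builtin_code(name)
            for codon in all_codons(code.codon_length):
                assert codon in code.assignment


class TestTranslate:
    def test_canonical(self, standard):
        assert standard.translate("AUGUUU") == "MF"
        assert standard.translate("atgtttTAA") == "MF"  # DNA input, stop

    def test_empty(self, standard):
        assert standard.translate("") == ""

    def test_null_codon_reports_position(self, red20):
        null = red20.null_codons[0]
        cds = red20.sense_codons[0] + null
        with pytest.raises(NullCodonError) as err:
            red20.translate(cds)
        assert err.value.position == 1
        assert err.value.codon == null

    def test_length_violation(self, standard):
        with pytest.raises(ValueError):
            standard.translate("AUGU")


class TestClassify:
    @pytest.mark.parametrize(
        "c1,c2,expected",
        [
            ("UUU", "UUC", MutationClass.SYNONYMOUS),
            ("UAU", "UAA", MutationClass.NONSENSE),
            ("UUU", "UUA", MutationClass.MISSENSE),
            ("UAA", "UAU", MutationClass.FROM_NONSENSE),
        ],
    )
    def test_standard_examples(self, standard, c1, c2, expected):
        assert classify_mutation(standard, c1, c2) == expected

    def test_red15_every_sense_mutation_truncates(self, red15):
        for c1 in red15.sense_codons:
            for c2 in mutation_neighbors(c1):
                assert classify_mutation(red15, c1, c2) in (
                    MutationClass.TO_NULL,
                    MutationClass.NONSENSE,
                )

    def test_distance_must_be_one(self, standard):
        with pytest.raises(ValueError):
            classify_mutation(standard, "UUU", "UUU")
        with pytest.raises(ValueError):
            classify_mutation(standard, "UUU", "AAU")


class TestSerialization:
    @pytest.mark.parametrize("name", ["standard", "red20", "fsquad"])
    def test_json_round_trip(self, name, tmp_path):
        code = builtin_code(name)
        path = tmp_path / f"{name}.json"
        code.to_json(path)
        loaded = GeneticCode.from_json(path)
        assert loaded.assignment == code.assignment
        assert loaded.codon_length == code.codon_length

    def test_tsv_round_trip(self, red15, tmp_path):
        path = tmp_path / "red15.tsv"
        red15.to_tsv(path)
        loaded = GeneticCode.from_tsv(path, name="red15")
        assert loaded.assignment == red15.assignment

    def test_json_label_conventions(self, red20):
        data = json.loads(red20.to_json())
        assert data["assignments"]["UAA"] == "*"
        assert "-" in data["assignments"].values()

    def test_partial_map_fills_null(self):
        code = GeneticCode.from_partial({"UUU": "F", "UUA": "L"})
        assert code.counts() == (2, 0, 62)

    def test_invalid_assignments_rejected(self):
        with pytest.raises(ValueError):
            GeneticCode(name="bad", codon_length=3, assignment={"UUU": "F"})
        bad = {c: "F" for c in all_codons(3)}
        bad["UUU"] = "?"
        with pytest.raises(ValueError):
            GeneticCode(name="bad", codon_length=3, assignment=bad)
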