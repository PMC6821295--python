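"""Code statistics: f_s, hydropathy change, null fraction, phi, ensembles."""

import itertools

import numpy as np
import pytest

from fscodes.codes import (
    NULL,
    STOP,
    GeneticCode,
    all_codons,
    hamming,
)
from fscodes.fixtures import toy_code
from fscodes.metrics import (
    KYTE_DOOLITTLE,
    ensemble_metrics,
    mean_delta_kd,
    missense_fraction,
    mutation_counts,
    null_mutation_fraction,
    phi,
    random_code,
    synonymous_fraction,
)


def brute_force_counts(code):
    """Independent oracle: enumerate ordered codon pairs at distance 1."""
    syn = mis = non = null = 0
    for c1, c2 in itertools.product(all_codons(code.codon_length), repeat=2):
        if hamming(c1, c2) != 1:
            continue
        a1, a2 = code.assignment[c1], code.assignment[c2]
        if a1 in (STOP, NULL):
            continue
        if a2 == NULL:
            null += 1
        elif a2 == STOP:
            non += 1
        elif a1 == a2:
            syn += 1
        else:
            mis += 1
    return syn, mis, non, null


class TestSynonymousFraction:
    def test_standard_is_24_percent(self, standard):
        assert round(synonymous_fraction(standard), 2) == 0.24

    def test_monochrome_code_is_one(self):
        code = GeneticCode(
            name="allF", codon_length=3, assignment={c: "F" for c in all_codons(3)}
        )
        assert synonymous_fraction(code) == 1.0

    def test_red20_has_no_synonyms(self, red20):
        assert synonymous_fraction(red20) == 0.0

    def test_no_sense_codons_error(self):
        with pytest.raises(ValueError):
            synonymous_fraction(toy_code({}))


class TestMeanDeltaKD:
    def test_single_missense_pair(self):
        code = toy_code({"UUU": "I", "UUA": "R"})
        assert mean_delta_kd(code) == pytest.approx(9.0)

    def test_undefined_without_missense(self):
        code = toy_code({"UUU": "I", "UUA": "I"})
        with pytest.raises(ValueError):
            mean_delta_kd(code)

    def test_scale_extremes(self):
        assert max(KYTE_DOOLITTLE, key=KYTE_DOOLITTLE.get) == "I"
        assert min(KYTE_DOOLITTLE, key=KYTE_DOOLITTLE.get) == "R"

    def test_standard_below_random_ensemble_mean(self, standard, rng):
        df = ensemble_metrics(300, rng)
        assert mean_delta_kd(standard) < df.attrs["mean_dkd"]


class TestNullFraction:
    def test_standard_has_none(self, standard):
        assert null_mutation_fraction(standard) == 0.0

    def test_ideal_codes_truncate_everything(self, red15, fs16):
        # every sense-origin mutation lands on null or stop: zero missense,
        # zero synonymous (stop adjacency is unavoidable for these families)
        for code in (red15, fs16):
            counts = mutation_counts(code)
            assert counts.missense == 0
            assert counts.synonymous == 0
            assert counts.to_null + counts.nonsense == counts.total
            assert null_mutation_fraction(code) > 0.9

    def test_fsquad_strictly_null(self, fsquad):
        assert null_mutation_fraction(fsquad) == 1.0


class TestPhi:
    def test_normalization(self, standard):
        assert phi(standard, standard) == 1.0

    def test_ideal_codes_are_zero(self, red15, fs16, standard):
        assert phi(red15, standard) == 0.0
        assert phi(fs16, standard) == 0.0

    def test_fs20_positive(self, fs20, standard):
        assert phi(fs20, standard) > 0.0

    def test_scale_free(self, fs20, standard, colorado):
        assert phi(fs20, standard) * missense_fraction(standard) == pytest.approx(
            missense_fraction(fs20)
        )
        assert phi(colorado, standard) > 1.0

    def test_zero_missense_reference_rejected(self, red15, standard):
        with pytest.raises(ValueError):
            phi(standard, reference=red15)

    def test_truncating_denominator_variant(self, red15, fs20, standard):
        assert phi(red15, standard, truncating_denominator=True) == 0.0
        assert phi(fs20, standard, truncating_denominator=True) > 0.0


class TestOracleAndInvariants:
    @pytest.mark.parametrize("name", ["standard", "colorado", "fs20", "red20", "red15"])
    def test_counts_match_brute_force(self, name):
        from fscodes.codes import builtin_code

        code = builtin_code(name)
        counts = mutation_counts(code)
        assert brute_force_counts(code) == (
            counts.synonymous,
            counts.missense,
            counts.nonsense,
            counts.to_null,
        )

    def test_class_fractions_sum_to_one(self, rng):
        for _ in range(5):
            code = random_code(rng)
            counts = mutation_counts(code)
            assert counts.total == len(code.sense_codons) * 9

    def test_nucleotide_relabeling_symmetry(self, rng):
        code = random_code(rng)
        perm = {"U": "G", "C": "A", "A": "U", "G": "C"}
        relabeled = GeneticCode(
            name="perm",
            codon_length=3,
            assignment={
                "".join(perm[x] for x in c): a for c, a in code.assignment.items()
            },
        )
        assert synonymous_fraction(relabeled) == synonymous_fraction(code)
        assert null_mutation_fraction(relabeled) == null_mutation_fraction(code)


class TestRandomEnsemble:
    def test_determinism(self):
        c1 = random_code(np.random.default_rng(7))
        c2 = random_code(np.random.default_rng(7))
        assert c1.assignment == c2.assignment

    def test_all_labels_present(self, rng):
        for _ in range(10):
            code = random_code(rng)
            assert len(code.amino_acids) == 20
            assert len(code.stop_codons) >= 1
            assert len(code.null_codons) == 0

    def test_ensemble_matches_per_code_path(self):
        df = ensemble_metrics(40, np.random.default_rng(99))
        rng2 = np.random.default_rng(99)
        direct = []
        for _ in range(40):
            code = random_code(rng2)
            direct.append(synonymous_fraction(code))
        assert np.allclose(df["fs"].to_numpy(), direct)

    def test_mean_fs_self_consistent(self):
        small = ensemble_metrics(2000, np.random.default_rng(1))
        large = ensemble_metrics(20000, np.random.default_rng(2))
        se = small["fs"].std() / np.sqrt(len(small))
        assert abs(small.attrs["mean_fs"] - large.attrs["mean_fs"]) < 3 * se

    def test_standard_fs_exceeds_ensemble_mean(self, standard):
        df = ensemble_metrics(2000, np.random.default_rng(3))
        assert synonymous_fraction(standard) > df.attrs["mean_fs"]
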