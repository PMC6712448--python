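import pytest
from hypothesis import given
from hypothesis import strategies as st

from poleclass.classify import (
    COMMON_HYPERMUTATOR,
    NONHYPERMUTATOR,
    POLE_CATEGORY,
    MutationSpectrum,
    annotate_pole,
    build_profile,
    classify_tumor,
    compute_spectrum,
    mutations_per_mb,
    parse_protein_change,
    substitution_class,
)
from poleclass.datasets import load_pole_case_table
from poleclass.io_formats import COMPLEMENT, SUBSTITUTION_CLASSES


class TestSubstitutionClass:
    @pytest.mark.parametrize("ref,alt,expected", [
        ("C", "A", "C>A"), ("C", "G", "C>G"), ("C", "T", "C>T"),
        ("T", "A", "T>A"), ("T", "C", "T>C"), ("T", "G", "T>G"),
        ("G", "T", "C>A"), ("G", "C", "C>G"), ("G", "A", "C>T"),
        ("A", "T", "T>A"), ("A", "G", "T>C"), ("A", "C", "T>G"),
    ])
    def test_all_twelve_substitutions(self, ref, alt, expected):
        assert substitution_class(ref, alt) == expected

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            substitution_class("N", "A")
        with pytest.raises(ValueError):
            substitution_class("C", "C")


class TestSpectrum:
    def test_both_strands_of_one_process_collapse(self, make_variant):
        variants = [make_variant(pos=i + 1, ref="C", alt="A") for i in range(5)]
        variants += [make_variant(pos=i + 50, ref="G", alt="T") for i in range(5)]
        spec = compute_spectrum(variants)
        assert spec.counts["C>A"] == 10 and spec.total == 10
        assert spec.fraction("C>A") == 1.0

    def test_fraction_arithmetic(self, make_variant):
        variants = (
            [make_variant(pos=i + 1, ref="C", alt="A") for i in range(25)]
            + [make_variant(pos=i + 100, ref="C", alt="G") for i in range(2)]
            + [make_variant(pos=i + 200, ref="C", alt="T") for i in range(73)]
        )
        fr = compute_spectrum(variants).fractions
        assert (fr["C>A"], fr["C>G"], fr["C>T"]) == (0.25, 0.02, 0.73)

    def test_empty_input_all_zero_undefined_fractions(self):
        spec = compute_spectrum([])
        assert spec.total == 0 and spec.fractions is None
        with pytest.raises(ValueError):
            spec.fraction("C>A")

    def test_non_snvs_ignored_and_counted(self, make_variant):
        variants = [make_variant(), make_variant(pos=2, ref="CT", alt="C")]
        spec = compute_spectrum(variants)
        assert spec.total == 1 and spec.n_ignored == 1

    @given(st.lists(st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT")),
                    min_size=1, max_size=50))
    def test_strand_complement_invariance(self, make_variant, pairs):
        pairs = [(r, a) for r, a in pairs if r != a]
        if not pairs:
            return
        fwd = [make_variant(pos=i + 1, ref=r, alt=a) for i, (r, a) in enumerate(pairs)]
        rev = [make_variant(pos=i + 1, ref=COMPLEMENT[r], alt=COMPLEMENT[a])
               for i, (r, a) in enumerate(pairs)]
        assert compute_spectrum(fwd).counts == compute_spectrum(rev).counts


def spectrum_from_fractions(ca: int, cg: int, ct: int) -> MutationSpectrum:
    return MutationSpectrum(counts={"C>A": ca, "C>G": cg, "C>T": ct})


class TestClassification:
    def test_ultramutated_case(self):
        spec = spectrum_from_fractions(45, 1, 54)  # C>A 0.45, C>G 0.01
        assert classify_tumor(9515, spec) == POLE_CATEGORY

    def test_count_boundary_is_strict(self):
        spec = spectrum_from_fractions(45, 1, 54)
        assert classify_tumor(500, spec) == NONHYPERMUTATOR
        assert classify_tumor(501, spec) == POLE_CATEGORY

    def test_c_to_g_boundary_is_strict(self):
        # C>G exactly 3% disqualifies from the POLE category
        spec = spectrum_from_fractions(25, 3, 72)
        assert classify_tumor(501, spec) == COMMON_HYPERMUTATOR

    def test_c_to_a_boundary_is_strict(self):
        # C>A exactly 20% is not enough
        spec = spectrum_from_fractions(20, 2, 78)
        assert classify_tumor(501, spec) == COMMON_HYPERMUTATOR

    def test_hypermutator_without_pole_spectrum(self):
        spec = spectrum_from_fractions(10, 5, 85)
        assert classify_tumor(1041, spec) == COMMON_HYPERMUTATOR

    def test_empty_spectrum_hypermutator_is_common(self):
        assert classify_tumor(501, MutationSpectrum(counts={})) == COMMON_HYPERMUTATOR

    def test_negative_count_errors(self):
        with pytest.raises(ValueError):
            classify_tumor(-1, MutationSpectrum(counts={}))

    @given(st.integers(501, 10000), st.integers(0, 100))
    def test_c_to_g_axis_never_reaches_nonhypermutator(self, count, cg):
        # moving only the C>G fraction across 3% toggles PC <-> CH, never NH
        spec = MutationSpectrum(counts={"C>A": 30, "C>G": cg, "C>T": 70})
        assert classify_tumor(count, spec) in (POLE_CATEGORY, COMMON_HYPERMUTATOR)


class TestMutationsPerMb:
    def test_arithmetic(self):
        assert mutations_per_mb(500, 50.0) == 10.0
        assert mutations_per_mb(0, 45.0) == 0.0
        assert mutations_per_mb(1050, 50.0) == 21.0

    def test_footprint_must_be_positive(self):
        with pytest.raises(ValueError):
            mutations_per_mb(10, 0.0)


class TestProteinChange:
    @pytest.mark.parametrize("text,expected", [
        ("P286R", ("P", 286, "R", "missense")),
        ("Q196*", ("Q", 196, "*", "nonsense")),
        ("p.V411L", ("V", 411, "L", "missense")),
    ])
    def test_parse(self, text, expected):
        assert parse_protein_change(text) == expected

    @pytest.mark.parametrize("bad", ["", "286R", "P286", "B286R", "P-3R"])
    def test_parse_errors_state_grammar(self, bad):
        with pytest.raises(ValueError, match="expected"):
            parse_protein_change(bad)

    def test_compound_entries_split(self):
        anns = annotate_pole(["P1207S, V1218I"])
        assert [a.protein_change for a in anns] == ["P1207S", "V1218I"]

    @pytest.mark.parametrize("change,in_domain,hotspot", [
        ("P286R", True, True),
        ("S297Y", True, True),
        ("F367C", True, True),
        ("V411L", True, True),
        ("R47W", False, False),
        ("Q196*", True, False),
        ("A427G", True, False),   # domain upper boundary inclusive
        ("A428G", False, False),
        ("A86G", True, False),    # domain lower boundary inclusive
        ("A85G", False, False),
    ])
    def test_domain_and_hotspot_flags(self, change, in_domain, hotspot):
        (ann,) = annotate_pole([change])
        assert ann.in_exonuclease_domain is in_domain
        assert ann.is_hotspot is hotspot


class TestReportedPoleCases:
    """The 27 independently reported POLE-mutant tumors must be reproduced."""

    def test_hypermutator_status_matches_for_all_27(self):
        df = load_pole_case_table()
        assert len(df) == 27
        for row in df.itertuples():
            is_hyper = row.nonsyn_snv_count > 500
            assert is_hyper == (row.classification != NONHYPERMUTATOR), row

    def test_exonuclease_domain_flag_matches_for_all_27(self):
        df = load_pole_case_table()
        for row in df.itertuples():
            anns = annotate_pole([row.protein_change])
            assert any(a.in_exonuclease_domain for a in anns) == row.exonuclease_domain, row


class TestBuildProfile:
    def test_profile_extracts_pole_and_labels(self, make_variant):
        variants = [make_variant(pos=i + 1, ref="C", alt="T") for i in range(10)]
        variants[0].gene = "POLE"
        variants[0].protein_change = "P286R"
        p = build_profile("T1", variants, footprint_mb=50.0)
        assert p.label == NONHYPERMUTATOR
        assert p.nonsyn_snv_count == 10 and p.total_snv_count == 10
        assert p.mutations_per_mb == 0.2
        assert p.pole_mutations[0].is_hotspot

    def test_spectrum_set_switch(self, make_variant):
        nonsyn = [make_variant(pos=i + 1, ref="C", alt="A") for i in range(4)]
        syn = [make_variant(pos=i + 50, ref="C", alt="T",
                            consequence="synonymous_SNV") for i in range(6)]
        all_set = build_profile("T1", nonsyn + syn, spectrum_set="all")
        ns_set = build_profile("T1", nonsyn + syn, spectrum_set="nonsynonymous")
        assert all_set.spectrum.fraction("C>A") == 0.4
        assert ns_set.spectrum.fraction("C>A") == 1.0
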