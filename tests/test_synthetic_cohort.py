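import filecmp

import numpy as np
import pytest

from poleclass.classify import (
    COMMON_HYPERMUTATOR,
    NONHYPERMUTATOR,
    POLE_CATEGORY,
    build_profile,
    compute_spectrum,
)
from poleclass.cohort_stats import compare_expression_by_group, expression_records_from_frame
from poleclass.qc_filter import apply_fp_filters, filter_summary, kept_variants
from poleclass.synthetic_cohort import (
    CohortSpec,
    _GenomeIndex,
    simulate_cohort,
    simulate_expression,
    simulate_genome,
    simulate_tumor_variants,
)


@pytest.fixture(scope="module")
def genome_index():
    rng = np.random.default_rng(42)
    return _GenomeIndex(simulate_genome(rng, 2, 20000))


def default_spec(**kw):
    return CohortSpec(**kw)


class TestSpecValidation:
    def test_prevalence_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(prevalence={NONHYPERMUTATOR: 0.9, COMMON_HYPERMUTATOR: 0.2,
                                   POLE_CATEGORY: 0.1})

    def test_background_spectrum_must_violate_pole_rule(self):
        bad = {"C>A": 0.30, "C>G": 0.01, "C>T": 0.39, "T>A": 0.07,
               "T>C": 0.16, "T>G": 0.07}
        with pytest.raises(ValueError, match="POLE spectrum rule"):
            CohortSpec(nh_spectrum=bad)

    def test_pole_band_must_satisfy_rule(self):
        with pytest.raises(ValueError):
            CohortSpec(pc_c_to_a=(0.15, 0.45))
        with pytest.raises(ValueError):
            CohortSpec(pc_c_to_g=0.05)


class TestTumorVariants:
    def test_zero_snvs_gives_empty_list(self, genome_index):
        rng = np.random.default_rng(0)
        spec = default_spec()
        assert simulate_tumor_variants("T1", NONHYPERMUTATOR, 0, spec.nh_spectrum,
                                       rng, genome_index, spec) == []

    def test_exact_count_and_spectrum_concentration(self, genome_index):
        rng = np.random.default_rng(1)
        spec = default_spec()
        target = {"C>A": 0.35, "C>G": 0.01, "C>T": 0.40, "T>A": 0.08,
                  "T>C": 0.12, "T>G": 0.04}
        calls = simulate_tumor_variants("T1", POLE_CATEGORY, 5000, target, rng,
                                        genome_index, spec)
        assert len(calls) == 5000
        observed = compute_spectrum(calls)
        assert abs(observed.fraction("C>A") - 0.35) < 0.02
        assert observed.fraction("C>G") < 0.03

    def test_both_strands_represented(self, genome_index):
        rng = np.random.default_rng(2)
        spec = default_spec()
        calls = simulate_tumor_variants("T1", NONHYPERMUTATOR, 500,
                                        spec.nh_spectrum, rng, genome_index, spec)
        refs = {v.ref for v in calls}
        assert refs >= {"C", "G"}  # pyrimidine and purine reference strands

    def test_qc_noise_fraction_discarded(self, genome_index):
        rng = np.random.default_rng(3)
        spec = default_spec()
        calls = simulate_tumor_variants("T1", NONHYPERMUTATOR, 20000,
                                        spec.nh_spectrum, rng, genome_index, spec)
        s = filter_summary(apply_fp_filters(calls))
        # five independent 1% failure modes -> ~4.9% discarded
        assert 0.03 < s.discarded / s.total < 0.07

    def test_nonhypermutator_classification_follows_counts(self, genome_index):
        rng = np.random.default_rng(4)
        spec = default_spec()
        calls = simulate_tumor_variants("T1", NONHYPERMUTATOR, 100,
                                        spec.nh_spectrum, rng, genome_index, spec)
        profile = build_profile("T1", calls)
        if profile.nonsyn_snv_count <= 500:
            assert profile.label == NONHYPERMUTATOR


class TestCohort:
    def test_same_seed_is_byte_identical(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_cohort(CohortSpec(n_tumors=8, seed=9)).write(a)
        simulate_cohort(CohortSpec(n_tumors=8, seed=9)).write(b)
        assert not filecmp.dircmp(a, b).diff_files
        assert not filecmp.dircmp(a / "variants", b / "variants").diff_files

    def test_pure_pole_cohort_satisfies_spectrum_rule(self):
        spec = CohortSpec(
            n_tumors=5, seed=5,
            prevalence={NONHYPERMUTATOR: 0.0, COMMON_HYPERMUTATOR: 0.0,
                        POLE_CATEGORY: 1.0},
        )
        cohort = simulate_cohort(spec)
        for calls in cohort.variants.values():
            observed = compute_spectrum(calls)
            assert observed.fraction("C>A") > 0.20
            assert observed.fraction("C>G") < 0.03

    def test_truth_labels_recovered_end_to_end(self):
        cohort = simulate_cohort(CohortSpec(n_tumors=250, seed=6))
        truth = cohort.truth_labels()
        hits = 0
        for tid, calls in cohort.variants.items():
            kept = kept_variants(apply_fp_filters(calls, cohort.blacklist))
            hits += build_profile(tid, kept).label == truth[tid]
        assert hits / 250 >= 0.99

    def test_pole_tumors_carry_hotspot_changes(self):
        spec = CohortSpec(
            n_tumors=6, seed=7,
            prevalence={NONHYPERMUTATOR: 0.0, COMMON_HYPERMUTATOR: 0.0,
                        POLE_CATEGORY: 1.0},
        )
        cohort = simulate_cohort(spec)
        changes = set(cohort.truth["pole_change"])
        assert changes <= {"P286R", "S297Y", "F367C", "V411L"}
        for tid, calls in cohort.variants.items():
            profile = build_profile(tid, calls)
            assert any(m.is_hotspot for m in profile.pole_mutations)

    def test_blacklist_noise_feeds_criterion_six(self):
        spec = CohortSpec(n_tumors=3, seed=8)
        spec.qc_noise["blacklist"] = 0.5
        cohort = simulate_cohort(spec)
        assert len(cohort.blacklist) > 0
        calls = next(iter(cohort.variants.values()))
        verdicts = apply_fp_filters(calls, cohort.blacklist)
        assert any(6 in vd.failed_criteria for vd in verdicts)

    def test_clinical_age_structure(self):
        spec = CohortSpec(
            n_tumors=300, seed=10,
            group_sizes={NONHYPERMUTATOR: 200, COMMON_HYPERMUTATOR: 50,
                         POLE_CATEGORY: 50},
            # keep runtime small: scale down counts, structure unchanged
            pc_count={"low": 600, "high": 900},
            ch_count={"offset": 650.0, "median": 100.0, "sigma": 0.3},
        )
        cohort = simulate_cohort(spec)
        truth = cohort.truth_labels()
        ages = {g: [] for g in (NONHYPERMUTATOR, POLE_CATEGORY)}
        for rec in cohort.clinical:
            if truth[rec.tumor_id] in ages:
                ages[truth[rec.tumor_id]].append(rec.age)
        assert np.median(ages[POLE_CATEGORY]) < np.median(ages[NONHYPERMUTATOR])


class TestExpression:
    def test_figure_pattern_for_one_seed(self):
        labels = {f"T{i:04d}": g for i, g in enumerate(
            [NONHYPERMUTATOR] * 400 + [COMMON_HYPERMUTATOR] * 40
            + [POLE_CATEGORY] * 10)}
        spec = CohortSpec(n_tumors=450, gep_missing_rate=0.0)
        df = simulate_expression(labels, spec, np.random.default_rng(20))
        records = expression_records_from_frame(df)
        pdl1 = compare_expression_by_group(records, labels, "PD-L1")
        assert pdl1["NH_vs_CH"] < 0.05 and pdl1["NH_vs_PC"] < 0.05
        cd8a = compare_expression_by_group(records, labels, "CD8A")
        assert cd8a["NH_vs_PC"] < 0.05
        ctla4 = compare_expression_by_group(records, labels, "CTLA-4")
        assert ctla4["NH_vs_PC"] >= 0.05

    def test_fold_change_consistency(self):
        labels = {"T0001": NONHYPERMUTATOR}
        spec = CohortSpec(n_tumors=1, gep_missing_rate=0.0)
        df = simulate_expression(labels, spec, np.random.default_rng(21))
        assert np.allclose(df["tumor_value"] - df["normal_value"],
                           df["fold_change"], atol=1e-3)
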