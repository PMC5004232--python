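"""Somatic filters, mutation matrix, group-specific rule, burden, cohort table."""

import itertools

import numpy as np
import pytest

from metadriver import (
    CohortLabels,
    VariantRecord,
    build_mutation_matrix,
    cohort_table,
    cohort_table_from_counts,
    filter_somatic_variants,
    find_group_specific_mutations,
    summarize_burden,
)
from metadriver.filtering import MutationMatrix


def v(sample, gene, pchg="p.A1T", cls="missense", region="exon", af=None):
    return VariantRecord(sample, gene, pchg, cls, region, af)


class TestSomaticFilters:
    def test_matched_normal_variant_removed(self):
        tumor = [v("s1", "G1"), v("s1", "G2")]
        normal = [v("s1", "G1")]
        assert filter_somatic_variants(tumor, normal) == [v("s1", "G2")]

    def test_normal_match_is_per_sample(self):
        tumor = [v("s1", "G1"), v("s2", "G1")]
        normal = [v("s1", "G1")]
        assert filter_somatic_variants(tumor, normal) == [v("s2", "G1")]

    def test_population_af_boundary_is_strict(self):
        tumor = [v("s1", "G1", af=0.1), v("s1", "G2", af=0.10001)]
        assert filter_somatic_variants(tumor, []) == [v("s1", "G1", af=0.1)]

    def test_synonymous_and_unknown_removed(self):
        tumor = [v("s1", "G1", cls="synonymous"), v("s1", "G2", cls="unknown"), v("s1", "G3")]
        assert filter_somatic_variants(tumor, []) == [v("s1", "G3")]

    def test_region_restriction(self):
        tumor = [v("s1", "G1", region="other"), v("s1", "G2", region="splice_site")]
        assert filter_somatic_variants(tumor, []) == [v("s1", "G2", region="splice_site")]

    def test_unknown_normal_sample_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            filter_somatic_variants([v("s1", "G1")], [v("s9", "G1")])

    def test_filters_commute(self):
        """Subsetting the tumor list first in any order yields the same survivors."""
        tumor = [
            v("s1", "G1"),
            v("s1", "G2", af=0.5),
            v("s1", "G3", cls="synonymous"),
            v("s1", "G4", region="other"),
            v("s1", "G5"),
        ]
        normal = [v("s1", "G5")]
        expected = filter_somatic_variants(tumor, normal)
        for perm in itertools.permutations(range(len(tumor))):
            shuffled = [tumor[i] for i in perm]
            assert set(filter_somatic_variants(shuffled, normal)) == set(expected)


class TestMutationMatrix:
    def test_distinct_mutations_give_identity(self, small_labels):
        variants = [v("h1", "G1"), v("h2", "G2")]
        mm = build_mutation_matrix(variants, small_labels)
        sub = mm.restrict(samples=["h1", "h2"])
        assert np.array_equal(sub.values, np.eye(2, dtype=int))

    def test_shared_mutation_single_column(self, small_labels):
        mm = build_mutation_matrix([v("h1", "G1"), v("h2", "G1")], small_labels)
        assert mm.shape[1] == 1
        assert mm.column_sums().tolist() == [2]

    def test_empty_variant_list_errors(self, small_labels):
        with pytest.raises(ValueError):
            build_mutation_matrix([], small_labels)

    def test_unknown_sample_errors(self, small_labels):
        with pytest.raises(ValueError, match="absent"):
            build_mutation_matrix([v("zz", "G1")], small_labels)

    def test_column_sums_match_naive_recount(self, small_labels):
        rng = np.random.default_rng(3)
        samples = small_labels.samples
        variants = []
        for _ in range(40):
            s = samples[rng.integers(len(samples))]
            g = f"G{rng.integers(6)}"
            variants.append(v(s, g))
        mm = build_mutation_matrix(variants, small_labels)
        for j, key in enumerate(mm.mutations):
            carriers = {x.sample_id for x in variants if x.key == key}
            assert mm.column_sums()[j] == len(carriers)

    def test_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            MutationMatrix(["s1"], [("G", "p")], np.array([[2]]))


class TestGroupSpecific:
    @pytest.fixture
    def cohort_22_56(self):
        labels = {f"H{i:02d}": "HRM" for i in range(22)}
        labels.update({f"L{i:02d}": "LRM" for i in range(56)})
        return CohortLabels(labels)

    def test_two_of_22_hrm_kept(self, cohort_22_56):
        variants = [v("H00", "G1"), v("H01", "G1")]
        mm = build_mutation_matrix(variants, cohort_22_56)
        assert find_group_specific_mutations(mm, cohort_22_56) == [("G1", "p.A1T")]

    def test_single_lrm_carrier_excludes(self, cohort_22_56):
        variants = [v("H00", "G1"), v("H01", "G1"), v("H02", "G1"), v("L00", "G1")]
        mm = build_mutation_matrix(variants, cohort_22_56)
        assert find_group_specific_mutations(mm, cohort_22_56) == []

    def test_one_of_22_below_threshold(self, cohort_22_56):
        variants = [v("H00", "G1"), v("H01", "G2"), v("H02", "G2")]
        mm = build_mutation_matrix(variants, cohort_22_56)
        assert find_group_specific_mutations(mm, cohort_22_56) == [("G2", "p.A1T")]

    def test_sample_permutation_invariance(self, cohort_22_56):
        rng = np.random.default_rng(0)
        variants = [
            v(f"H{rng.integers(22):02d}", f"G{rng.integers(5)}") for _ in range(30)
        ]
        mm = build_mutation_matrix(variants, cohort_22_56)
        perm = rng.permutation(len(mm.samples))
        shuffled = MutationMatrix(
            [mm.samples[i] for i in perm], mm.mutations, mm.values[perm]
        )
        assert find_group_specific_mutations(
            mm, cohort_22_56
        ) == find_group_specific_mutations(shuffled, cohort_22_56)

    def test_sorted_by_descending_frequency(self, cohort_22_56):
        variants = [v("H00", "G2"), v("H01", "G2"), v("H02", "G2")]
        variants += [v("H00", "G1"), v("H01", "G1")]
        mm = build_mutation_matrix(variants, cohort_22_56)
        keys = find_group_specific_mutations(mm, cohort_22_56)
        assert keys == [("G2", "p.A1T"), ("G1", "p.A1T")]


class TestBurden:
    def test_identical_groups_are_degenerate(self, small_labels):
        variants = [v(s, "G1") for s in small_labels.samples]
        mm = build_mutation_matrix(variants, small_labels)
        summary = summarize_burden(mm, small_labels)
        assert summary.t_statistic == 0.0
        assert summary.p_value == 0.5
        assert summary.degenerate

    def test_separated_groups_significant(self, small_labels):
        variants = []
        for s in ("h1", "h2", "h3"):
            variants += [v(s, f"G{k}") for k in range(5)]
        for s in ("l1", "l2", "l3"):
            variants += [v(s, "G0")]
        mm = build_mutation_matrix(variants, small_labels)
        summary = summarize_burden(mm, small_labels)
        assert summary.group_means["HRM"] == 5.0
        assert summary.group_means["LRM"] == 1.0
        assert summary.p_value < 0.05

    def test_one_sided_antisymmetry(self, small_labels):
        rng = np.random.default_rng(1)
        variants = []
        for s in small_labels.samples:
            for k in range(int(rng.integers(1, 8))):
                variants.append(v(s, f"G{k}"))
        mm = build_mutation_matrix(variants, small_labels)
        p_greater = summarize_burden(mm, small_labels, "greater").p_value
        swapped = CohortLabels(
            {s: ("LRM" if g == "HRM" else "HRM") for s, g in small_labels.as_dict().items()}
        )
        p_swapped = summarize_burden(mm, swapped, "greater").p_value
        assert p_greater + p_swapped == pytest.approx(1.0, abs=1e-12)


class TestCohortTable:
    def test_transcribed_clinical_counts_reproduce_percentages(self):
        table = cohort_table_from_counts(
            {
                "er_status": {
                    "positive": {"HRM": 10, "LRM": 24},
                    "negative": {"HRM": 12, "LRM": 32},
                },
                "molecular_subtype": {"luminal": {"HRM": 11, "LRM": 27}},
            },
            {"HRM": 22, "LRM": 56},
        )
        lookup = table.set_index(["characteristic", "level", "group"])["percent"]
        assert lookup[("er_status", "positive", "HRM")] == 45.5
        assert lookup[("er_status", "negative", "LRM")] == 57.1
        assert lookup[("molecular_subtype", "luminal", "HRM")] == 50.0

    def test_single_sample_group_is_100(self):
        labels = CohortLabels({"a": "HRM", "b": "LRM"})
        table = cohort_table(labels, {"grade": {"a": "II", "b": "III"}})
        assert (table["percent"] == 100.0).all()

    def test_missing_attribute_counts_as_unknown(self, small_labels):
        table = cohort_table(small_labels, {"er": {"h1": "pos"}})
        hrm = table[(table["group"] == "HRM")]
        assert set(hrm["level"]) == {"pos", "unknown"}
        assert hrm.loc[hrm["level"] == "unknown", "count"].item() == 2
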