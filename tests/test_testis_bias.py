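import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctscreen.io import ExpressionMatrix, TissueProfile, ValidationError
from ctscreen.simulate import gen_normal_atlases
from ctscreen.testis_bias import (
    aggregate_replicates,
    consensus,
    passing_set,
    proportional_score,
    proportional_scores,
    screen_source,
)


class TestAggregateReplicates:
    def test_mean_of_replicates(self):
        m = ExpressionMatrix(
            pd.DataFrame({"s1": [2.0], "s2": [4.0], "s3": [7.0]}, index=["G"]),
            unit="FPKM",
        )
        prof = aggregate_replicates(
            m, {"s1": "liver", "s2": "liver", "s3": "testis"}, source="u"
        )
        assert prof.values.loc["G", "liver"] == 3.0
        assert prof.values.loc["G", "testis"] == 7.0

    def test_one_sample_per_tissue_is_identity(self):
        m = ExpressionMatrix(
            pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}, index=["G1", "G2"]),
            unit="TPM",
        )
        prof = aggregate_replicates(m, {"a": "testis", "b": "lung"})
        assert prof.values.loc["G2", "testis"] == 2.0
        assert prof.values.loc["G1", "lung"] == 3.0

    def test_unmapped_sample_named(self):
        m = ExpressionMatrix(pd.DataFrame({"s1": [1.0], "s2": [1.0]}, index=["G"]),
                             unit="TPM")
        with pytest.raises(ValidationError, match="s2"):
            aggregate_replicates(m, {"s1": "testis"})


class TestProportionalScore:
    def test_exclusive_expression_scores_one(self, small_profile):
        assert proportional_score(small_profile, "EXCL") == 1.0

    def test_uniform_gene_scores_one_over_n(self, small_profile):
        assert proportional_score(small_profile, "UNIF") == pytest.approx(0.25)

    def test_uniform_sixteen_tissues(self):
        df = pd.DataFrame(np.ones((1, 16)), index=["G"],
                          columns=["testis"] + [f"t{i}" for i in range(15)])
        assert proportional_score(TissueProfile(df), "G") == pytest.approx(1 / 16)

    def test_boundary_point_nine_passes_inclusively(self, small_profile):
        # testis 9.0 vs one other tissue 1.0: score exactly 0.9, "at least 0.9"
        assert proportional_score(small_profile, "EDGE") == pytest.approx(0.9)
        screen = screen_source(small_profile, tiers=(0.9, 0.99))
        assert screen.loc["EDGE", "pass_0.9"]
        assert not screen.loc["EDGE", "pass_0.99"]

    def test_zero_row_undefined(self, small_profile):
        assert np.isnan(proportional_score(small_profile, "ZERO"))

    def test_absent_gene_raises(self, small_profile):
        with pytest.raises(KeyError, match="NOPE"):
            proportional_score(small_profile, "NOPE")

    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(min_value=1e-6, max_value=1e6),
           vals=st.lists(st.floats(min_value=0.01, max_value=1e4),
                         min_size=3, max_size=8))
    def test_scale_invariance(self, scale, vals):
        cols = ["testis"] + [f"t{i}" for i in range(len(vals) - 1)]
        base = TissueProfile(pd.DataFrame([vals], index=["G"], columns=cols))
        scaled = TissueProfile(
            pd.DataFrame([[v * scale for v in vals]], index=["G"], columns=cols))
        assert proportional_score(base, "G") == pytest.approx(
            proportional_score(scaled, "G"), rel=1e-9)

    def test_swapping_testis_with_other_tissue_is_positional(self):
        df = pd.DataFrame([[8.0, 2.0, 0.0]], index=["G"],
                          columns=["testis", "liver", "lung"])
        swapped = df.rename(columns={"testis": "liver", "liver": "testis"})
        s1 = proportional_score(TissueProfile(df), "G")
        s2 = proportional_score(TissueProfile(swapped[df.columns]), "G")
        assert (s1, s2) == (0.8, 0.2)


class TestScreenSource:
    def test_threshold_bracketing(self):
        df = pd.DataFrame([[95.0, 5.0], [99.0, 1.0], [50.0, 50.0]],
                          index=["A", "B", "C"], columns=["testis", "liver"])
        screen = screen_source(TissueProfile(df), tiers=(0.9, 0.99))
        assert screen.loc["A", "pass_0.9"] and not screen.loc["A", "pass_0.99"]
        assert screen.loc["B", "pass_0.9"] and screen.loc["B", "pass_0.99"]
        assert not screen.loc["C", "pass_0.9"]

    def test_stringent_set_nested_in_lenient(self, small_profile):
        screen = screen_source(small_profile, tiers=(0.9, 0.99))
        assert passing_set(screen, 0.99) <= passing_set(screen, 0.9)

    def test_all_zero_gene_fails_all_tiers(self, small_profile):
        screen = screen_source(small_profile, tiers=(0.9, 0.99))
        assert np.isnan(screen.loc["ZERO", "proportional_score"])
        assert not screen.loc["ZERO", "pass_0.9"]

    def test_empty_tier_list_rejected(self, small_profile):
        with pytest.raises(ValidationError):
            screen_source(small_profile, tiers=())


class TestConsensus:
    def test_union_and_region_counts(self):
        cs = consensus({"s1": {"A", "B"}, "s2": {"B", "C"}, "s3": set()})
        assert cs.genes == {"A", "B", "C"}
        counts = cs.venn_counts()
        assert counts[frozenset({"s1"})] == 1          # A only
        assert counts[frozenset({"s2"})] == 1          # C only
        assert counts[frozenset({"s1", "s2"})] == 1    # B
        assert counts[frozenset({"s1", "s2", "s3"})] == 0

    def test_idempotent_on_identical_sets(self):
        cs = consensus({"a": {"X", "Y"}, "b": {"X", "Y"}, "c": {"X", "Y"}})
        assert cs.genes == {"X", "Y"}
        assert consensus({"a": {"X", "Y"}}, mode="union").genes == {"X", "Y"}

    def test_union_size_matches_inclusion_exclusion(self):
        sets = {"a": {"A", "B", "C"}, "b": {"B", "D"}, "c": {"C", "D", "E"}}
        cs = consensus(sets)
        assert len(cs.genes) == len(set().union(*sets.values()))
        assert sum(cs.venn_counts().values()) == len(cs.genes)

    def test_intersection_mode(self):
        cs = consensus({"a": {"A", "B"}, "b": {"B", "C"}}, mode="intersection")
        assert cs.genes == {"B"}


class TestPlantedRecovery:
    def test_screen_recovers_planted_venn_design(self):
        """Venn-region counts of the recovered sets equal the planting design,
        verified by brute-force set enumeration over the serialized truth."""
        design = {
            ("atlas1", "atlas2", "atlas3"): 20,
            ("atlas1", "atlas2"): 6, ("atlas1", "atlas3"): 6,
            ("atlas2", "atlas3"): 6,
            ("atlas1",): 4, ("atlas2",): 4, ("atlas3",): 4,
        }
        profiles, truth = gen_normal_atlases(
            n_genes=1000, testis_fraction=0.05, overlap_design=design, seed=11)
        recovered = {
            s: passing_set(screen_source(p, tiers=(0.9,)), 0.9)
            for s, p in profiles.items()
        }
        # brute-force region counts from the ground-truth membership lists
        truth_sets = {s: set(v) for s, v in truth.planted_testis.items()}
        assert recovered == truth_sets
        cs = consensus(recovered)
        counts = cs.venn_counts()
        for region, n in design.items():
            assert counts[frozenset(region)] == n
        assert len(cs.genes) == 50

    def test_zero_fraction_recovers_empty_set(self):
        profiles, _ = gen_normal_atlases(n_genes=200, testis_fraction=0.0, seed=2)
        for p in profiles.values():
            assert passing_set(screen_source(p, tiers=(0.9,)), 0.9) == set()
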