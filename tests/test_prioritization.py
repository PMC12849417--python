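"""Cascade criteria: boundaries, segregation, vote oracle, invariants."""

import random

import pytest
from hypothesis import given, strategies as st

from famprio.predictors import PREDICTORS
from famprio.prioritization import (
    CANONICAL_SPLICE,
    FAIL,
    MISSENSE,
    NOT_EVALUABLE,
    OTHER,
    PASS,
    STOP_GAIN,
    Thresholds,
    classify_consequence,
    conservation_consensus,
    constraint_annotation,
    deleteriousness_vote,
    filter_cadd,
    filter_canonical,
    filter_frequency,
    known_gene_screen,
    prioritize,
    prioritized_set,
    segregation_filter,
)
from conftest import make_cohort, make_record


class TestClassifyConsequence:
    @pytest.mark.parametrize(
        "consequence,hgvsc,expected",
        [
            ("missense_variant", "", MISSENSE),                      # e.g. p.Gly553Ser
            ("stop_gained", "", STOP_GAIN),                          # e.g. p.Glu829Ter
            ("splice_donor_variant", "c.371+2T>C", CANONICAL_SPLICE),
            ("frameshift_variant", "", "frameshift"),
            ("splice_region_variant", "c.371+2T>C", CANONICAL_SPLICE),
            ("splice_region_variant", "c.371+7T>C", OTHER),          # beyond +-2
            ("synonymous_variant", "", OTHER),
            ("made_up_term", "", OTHER),
            ("missense_variant&splice_region_variant", "", MISSENSE),
        ],
    )
    def test_classes(self, consequence, hgvsc, expected):
        rec = make_record(consequence=consequence, hgvsc=hgvsc)
        assert classify_consequence(rec) == expected


class TestSimpleFilters:
    def test_canonical(self, thresholds):
        assert filter_canonical(make_record(canonical=True)) == PASS
        assert filter_canonical(make_record(canonical=False)) == FAIL
        assert filter_canonical(make_record(canonical=None)) == NOT_EVALUABLE
        strict = Thresholds(canonical_fail_closed=True)
        assert filter_canonical(make_record(canonical=None), strict) == FAIL

    @pytest.mark.parametrize(
        "afs,expected",
        [
            ((0.0005, 0.0004, 0.0009), PASS),
            ((0.0005, 0.0004, 0.002), FAIL),   # popmax too common
            ((None, None, None), PASS),        # absent from gnomAD = rare
            ((0.001, None, None), FAIL),       # boundary: 0.1% is not < 0.1%
            ((0.0, 0.0, 0.0), PASS),
        ],
    )
    def test_frequency(self, afs, expected, thresholds):
        rec = make_record(afs=afs)
        assert filter_frequency(rec.annotations, thresholds) == expected

    @pytest.mark.parametrize(
        "cadd,expected",
        [(23.5, PASS), (20.0, FAIL), (20.01, PASS), (None, FAIL), (0.0, FAIL)],
    )
    def test_cadd_strict_boundary(self, cadd, expected, thresholds):
        assert filter_cadd(cadd, thresholds) == expected


class TestVote:
    def test_nine_of_eleven_passes(self, thresholds):
        calls = {p: "deleterious" for p in PREDICTORS[:9]}
        calls.update({p: "benign" for p in PREDICTORS[9:]})
        v = deleteriousness_vote(calls, thresholds)
        assert (v.credits, v.n_tools_with_call, v.verdict) == (9.0, 11, PASS)

    def test_fractional_credits_6_5_of_11_passes(self, thresholds):
        # 4 deleterious + 5 intermediate + 2 benign = 6.5 credits
        calls = {p: "deleterious" for p in PREDICTORS[:4]}
        calls.update({p: "intermediate" for p in PREDICTORS[4:9]})
        calls.update({p: "benign" for p in PREDICTORS[9:]})
        v = deleteriousness_vote(calls, thresholds)
        assert v.credits == 6.5
        assert v.fraction == pytest.approx(6.5 / 11)
        assert v.verdict == PASS

    def test_exactly_half_fails_strict(self, thresholds):
        # 5.5 / 11 == 0.5 exactly -> fail
        calls = {p: "deleterious" for p in PREDICTORS[:5]}
        calls.update({PREDICTORS[5]: "intermediate"})
        calls.update({p: "benign" for p in PREDICTORS[6:]})
        v = deleteriousness_vote(calls, thresholds)
        assert v.fraction == 0.5
        assert v.verdict == FAIL

    def test_missing_leaves_denominator(self, thresholds):
        calls = {p: "missing" for p in PREDICTORS}
        calls.update({PREDICTORS[0]: "deleterious"})
        v = deleteriousness_vote(calls, thresholds)
        assert (v.n_tools_with_call, v.fraction, v.verdict) == (1, 1.0, PASS)

    def test_all_missing_not_evaluable(self, thresholds):
        v = deleteriousness_vote({p: "missing" for p in PREDICTORS}, thresholds)
        assert v.verdict == NOT_EVALUABLE
        assert v.fraction is None

    def test_unknown_predictor_name_rejected(self, thresholds):
        calls = {p: "benign" for p in PREDICTORS}
        calls["not_a_tool"] = "deleterious"
        with pytest.raises(KeyError):
            deleteriousness_vote(calls, thresholds)

    def test_brute_force_recount_oracle(self, thresholds):
        """Vote agrees with an independent recount on 10^4 random mappings."""
        rng = random.Random(12345)
        cats = ["deleterious", "intermediate", "benign", "missing"]
        credit = {"deleterious": 1.0, "intermediate": 0.5, "benign": 0.0}
        for _ in range(10_000):
            calls = {p: rng.choice(cats) for p in PREDICTORS}
            called = [c for c in calls.values() if c != "missing"]
            v = deleteriousness_vote(calls, thresholds)
            if not called:
                assert v.verdict == NOT_EVALUABLE
                continue
            expect_credits = sum(credit[c] for c in called)
            assert v.credits == expect_credits
            assert v.n_tools_with_call == len(called)
            assert v.verdict == (PASS if expect_credits / len(called) > 0.5 else FAIL)


class TestConservation:
    @pytest.mark.parametrize(
        "scores,positives,verdict",
        [
            ((2.5, 0.4, 1.0), 2, PASS),
            ((3.0, 0.31, 3.0), 3, PASS),
            ((1.9, 0.3, 2.9), 0, FAIL),      # all at/below their strict cutoffs
            ((2.0, 0.3, 2.99), 0, FAIL),     # GERP 2.0 and PhastCons 0.3 are not >
            ((None, None, 3.0), 1, FAIL),    # PhyloP 3.0 is inclusive but alone
            ((2.1, None, 3.0), 2, PASS),
        ],
    )
    def test_consensus(self, scores, positives, verdict, thresholds):
        got = conservation_consensus(*scores, thresholds)
        assert got == (positives, verdict)


class TestConstraint:
    def test_flags_are_advisory(self, thresholds):
        assert constraint_annotation(1.2, None, thresholds) == {"z_constrained": True}
        assert constraint_annotation(None, 0.45, thresholds) == {"loeuf_constrained": True}
        assert constraint_annotation(None, None, thresholds) == {}
        assert constraint_annotation(-0.5, 0.6, thresholds) == {
            "z_constrained": False,
            "loeuf_constrained": False,
        }


class TestSegregation:
    def test_shared_het_retained_partial_dropped(self, two_case_cohort):
        shared = make_record(
            "1_100_A_G", genotypes={"A1": "het", "A2": "hom_alt", "P1": "hom_ref"}
        )
        partial = make_record(
            "2_200_C_T", genotypes={"A1": "het", "A2": "hom_ref", "P1": "hom_ref"}
        )
        sets = segregation_filter(two_case_cohort, [shared, partial])
        assert sets["F1"] == [shared]

    def test_single_case_proband(self, two_case_cohort):
        rec = make_record(
            "3_300_G_A", genotypes={"A1": "hom_ref", "A2": "hom_ref", "P1": "het"}
        )
        sets = segregation_filter(two_case_cohort, [rec])
        assert sets["Mx1"] == [rec]

    def test_missing_genotype_counts_as_absent(self, two_case_cohort):
        rec = make_record(
            "1_100_A_G",
            genotypes={"A1": "het", "A2": "missing", "P1": "hom_ref"},
        )
        assert segregation_filter(two_case_cohort, [rec])["F1"] == []

    def test_ungenotyped_family_is_an_error(self):
        cohort = make_cohort({"F9": [("Z1", True, True)]})
        rec = make_record(genotypes={"other": "het"})
        with pytest.raises(ValueError, match="F9"):
            segregation_filter(cohort, [rec])


class TestKnownGeneScreen:
    def test_hits_and_case_insensitivity(self):
        records = [make_record(gene="MSH2"), make_record("2_2_A_C", gene="FLNC")]
        assert known_gene_screen(records, {"MSH2"}) == [records[0]]
        assert known_gene_screen(records, {"msh2"}) == [records[0]]
        assert known_gene_screen(records, {"APC"}) == []
        with pytest.raises(ValueError):
            known_gene_screen(records, set())


class TestCascade:
    def test_spiked_causal_variant_prioritized(self, two_case_cohort):
        rec = make_record(genotypes={"A1": "het", "A2": "het"})
        trails = prioritize([rec], two_case_cohort)
        assert len(trails) == 1
        assert trails[0].final_status == "prioritized"
        assert trails[0].rejection_reason is None

    def test_common_variant_rejected_at_frequency_with_na_downstream(
        self, two_case_cohort
    ):
        rec = make_record(afs=(None, None, 0.01), genotypes={"A1": "het", "A2": "het"})
        trail = prioritize([rec], two_case_cohort)[0]
        assert trail.final_status == "rejected"
        assert trail.rejection_reason == "frequency"
        assert trail.verdict("cadd") == "not_applicable"
        # raw outcome still recorded for auditability
        cadd_entry = next(e for e in trail.entries if e.criterion == "cadd")
        assert cadd_entry.inputs["raw_verdict"] == PASS

    def test_trail_carries_every_criterion_once(self, two_case_cohort):
        rec = make_record(genotypes={"P1": "het"})
        trail = prioritize([rec], two_case_cohort)[0]
        names = [e.criterion for e in trail.entries]
        assert sorted(names) == sorted(set(names))
        assert set(names) == {
            "canonical", "consequence_class", "frequency", "cadd",
            "segregation", "deleteriousness_vote", "conservation", "last_exon",
        }

    def test_final_status_reproducible_from_verdicts(self, two_case_cohort):
        recs = [
            make_record("1_100_A_G", genotypes={"A1": "het", "A2": "het"}),
            make_record("2_200_C_T", cadd=3.0, genotypes={"P1": "het"}),
            make_record("3_300_G_A", canonical=False, genotypes={"A1": "het", "A2": "het"}),
        ]
        for trail in prioritize(recs, two_case_cohort):
            any_fail = any(e.verdict == FAIL for e in trail.entries)
            assert (trail.final_status == "rejected") == any_fail

    def test_order_independence(self, two_case_cohort):
        recs = [
            make_record("1_100_A_G", genotypes={"A1": "het", "A2": "het"}),
            make_record("2_200_C_T", cadd=3.0, genotypes={"P1": "het"}),
            make_record("3_300_G_A", genotypes={"P1": "het"}),
        ]
        fwd = {(str(t.variant), t.family_id): t.final_status
               for t in prioritize(recs, two_case_cohort)}
        rev = {(str(t.variant), t.family_id): t.final_status
               for t in prioritize(recs[::-1], two_case_cohort)}
        assert fwd == rev

    @given(
        cadds=st.lists(st.floats(min_value=0, max_value=60), min_size=1, max_size=8),
        afs=st.lists(st.floats(min_value=0, max_value=0.02), min_size=1, max_size=8),
        loose_cadd=st.floats(min_value=5, max_value=19),
        loose_maf=st.floats(min_value=0.002, max_value=0.05),
    )
    def test_monotonicity_of_thresholds(self, cadds, afs, loose_cadd, loose_maf):
        """Loosening maf_max/cadd_min never shrinks the prioritized set."""
        cohort = make_cohort({"F1": [("A1", True, True), ("A2", True, True)]})
        n = min(len(cadds), len(afs))
        recs = [
            make_record(f"1_{1000 + i}_A_G", cadd=cadds[i], afs=(afs[i], None, None),
                        genotypes={"A1": "het", "A2": "het"})
            for i in range(n)
        ]
        tight = Thresholds()
        loose = Thresholds(cadd_min=loose_cadd, maf_max=loose_maf)
        keep_tight = {str(t.variant) for t in prioritized_set(prioritize(recs, cohort, tight))}
        keep_loose = {str(t.variant) for t in prioritized_set(prioritize(recs, cohort, loose))}
        assert keep_tight <= keep_loose
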