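"""The selection cascade: filters, in-phase recoding, and full-screen verdicts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rarescreen.core import CohortGenotypes, VariantRecord, column_from_counts
from rarescreen.fixtures import (
    DEFB1_KEY,
    DEFB119_KEY,
    MBL2_KEY,
    METTL7B_KEY,
    METTL7B_MODIFIER_KEY,
    combined_mettl7b_cases,
    fixture_from_tables,
)
from rarescreen.screening import (
    PhaseRule,
    ScreenParams,
    ancestry_specificity,
    case_only_filter,
    expression_filter,
    filter_damaging_nonsense,
    rarity_filter,
    recode_in_phase,
    run_screen,
)


class TestDamagingNonsenseFilter:
    def test_keeps_hc_nonsense_only(self, paper_fixture):
        kept = filter_damaging_nonsense(paper_fixture.annotation)
        assert DEFB1_KEY in kept
        assert METTL7B_KEY in kept
        # the second alt allele of the same rsid is synonymous -> dropped
        assert ("chr8", 6728299, "G", "A") not in kept
        # low-confidence LoF call -> dropped
        assert ("chr7", 20725325, "A", "T") not in kept
        # the in-phase modifier is missense -> dropped
        assert METTL7B_MODIFIER_KEY not in kept

    def test_missense_only_table_is_empty(self):
        from rarescreen.core import PopulationFrequencies
        from rarescreen.io import AnnotationTable

        rec = VariantRecord("chr1", 5, "A", "T", consequence="missense")
        table = AnnotationTable.from_records(
            [(rec, PopulationFrequencies(af_global=0.001), None)]
        )
        assert filter_damaging_nonsense(table) == set()


class TestCaseOnlyFilter:
    def test_fixture_pattern(self, paper_fixture):
        cases = paper_fixture.cohorts["discovery_cases"]
        controls = paper_fixture.cohorts["discovery_controls"]
        keys = set(cases.keys)
        kept = case_only_filter(keys, cases, controls)
        assert DEFB1_KEY in kept
        assert METTL7B_KEY in kept
        # carried by five controls -> not case-only
        assert DEFB119_KEY not in kept

    def test_control_only_direction_reverses_roles(self, paper_fixture):
        cases = paper_fixture.cohorts["discovery_cases"]
        controls = paper_fixture.cohorts["discovery_controls"]
        kept = case_only_filter(set(cases.keys), cases, controls,
                                direction="control_only")
        # every fixture variant with control carriers also has case carriers
        assert kept == set()
        with pytest.raises(ValueError):
            case_only_filter(set(), cases, controls, direction="sideways")


class TestRarityFilter:
    def test_threshold_strict_and_missing_routed(self, paper_fixture):
        ann = paper_fixture.annotation
        keys = {MBL2_KEY, METTL7B_KEY, ("chr14", 74416836, "G", "A"),
                ("chr1", 236882310, "G", "T")}
        kept, indeterminate = rarity_filter(keys, ann)
        assert MBL2_KEY in kept          # 0.000594
        assert METTL7B_KEY in kept       # 0.004004
        assert ("chr14", 74416836, "G", "A") not in kept  # 0.012
        assert indeterminate == {("chr1", 236882310, "G", "T")}  # no AF reported

    def test_boundary_af_is_dropped(self):
        from rarescreen.core import PopulationFrequencies
        from rarescreen.io import AnnotationTable

        rec = VariantRecord("chr1", 9, "A", "T", consequence="stop_gained",
                            lof_confidence="HC")
        table = AnnotationTable.from_records(
            [(rec, PopulationFrequencies(af_global=0.01), None)]
        )
        kept, _ = rarity_filter({rec.key}, table, threshold=0.01)
        assert kept == set()


class TestAncestrySpecificity:
    def test_afr_concentrated_passes(self, paper_fixture):
        assert ancestry_specificity(DEFB1_KEY, paper_fixture.annotation) == "pass"

    def test_uniform_frequencies_fail(self, paper_fixture):
        assert ancestry_specificity(("chr16", 81194437, "C", "T"),
                                    paper_fixture.annotation) == "fail"

    def test_missing_population_is_indeterminate(self, paper_fixture):
        # EAS frequency unreported for this fixture row
        assert ancestry_specificity(("chr7", 100371358, "G", "A"),
                                    paper_fixture.annotation) == "unknown"

    def test_unknown_population_code_is_config_error(self, paper_fixture):
        with pytest.raises(ValueError):
            ancestry_specificity(DEFB1_KEY, paper_fixture.annotation,
                                 target_pop="XYZ")


class TestExpressionFilter:
    def test_membership_case_insensitive(self, paper_fixture):
        keys = {DEFB1_KEY, MBL2_KEY, ("chr7", 2752059, "C", "T")}
        kept = expression_filter(keys, paper_fixture.annotation,
                                 {"defb1", "Mbl2", "METTL7B"})
        assert kept == {DEFB1_KEY, MBL2_KEY}

    def test_empty_list_empty_result(self, paper_fixture):
        assert expression_filter({DEFB1_KEY}, paper_fixture.annotation, set()) == set()


class TestRecodeInPhase:
    def test_combined_case_example(self, paper_fixture):
        cohort = combined_mettl7b_cases()
        assert cohort.allele_count(METTL7B_KEY).mac == 20
        recoded = recode_in_phase(cohort, paper_fixture.phase_rule)
        count = recoded.allele_count(METTL7B_KEY)
        assert count.mac == 19
        assert count.total_alleles == 318
        assert float(count.maf) == pytest.approx(19 / 318)

    def test_no_modifier_carriers_is_identity_on_target(self, paper_fixture):
        cohort = combined_mettl7b_cases()
        cohort.column(METTL7B_MODIFIER_KEY)[:] = 0
        recoded = recode_in_phase(cohort, paper_fixture.phase_rule)
        assert np.array_equal(recoded.column(METTL7B_KEY),
                              cohort.column(METTL7B_KEY))

    def test_hom_target_het_modifier(self):
        target = VariantRecord("chr12", 100, "C", "T", consequence="stop_gained",
                               lof_confidence="HC")
        modifier = VariantRecord("chr12", 101, "G", "T", consequence="missense")
        cohort = CohortGenotypes(
            "cases", ["s1"], [target, modifier],
            np.array([[2, 1]], dtype=np.int8),
        )
        rule = PhaseRule(target.key, modifier.key)
        recoded = recode_in_phase(cohort, rule)
        assert recoded.column(target.key)[0] == 1

    def test_missing_modifier_column_is_noop(self):
        target = VariantRecord("chr12", 100, "C", "T", consequence="stop_gained",
                               lof_confidence="HC")
        cohort = CohortGenotypes("cases", ["s1"], [target],
                                 np.array([[1]], dtype=np.int8))
        rule = PhaseRule(target.key, ("chr12", 101, "G", "T"))
        assert recode_in_phase(cohort, rule) is cohort

    @given(
        dosages=st.lists(
            st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=1, max_size=30
        )
    )
    @settings(deadline=None)
    def test_total_site_dosage_conserved(self, dosages):
        target = VariantRecord("chr5", 10, "A", "T", consequence="stop_gained",
                               lof_confidence="HC")
        modifier = VariantRecord("chr5", 11, "G", "C", consequence="missense")
        matrix = np.array(dosages, dtype=np.int8)
        cohort = CohortGenotypes(
            "c", [f"s{i}" for i in range(len(dosages))], [target, modifier], matrix
        )
        recoded = recode_in_phase(cohort, PhaseRule(target.key, modifier.key))
        synthetic_key = next(k for k in recoded.keys
                             if k not in (target.key, modifier.key))
        total_before = cohort.column(target.key)
        total_after = recoded.column(target.key) + recoded.column(synthetic_key)
        assert np.array_equal(total_before, total_after)


class TestRunScreen:
    def _run(self, fx, **kwargs):
        params = ScreenParams(family_m=3, phase_rules=[fx.phase_rule])
        return run_screen(fx.cohorts, fx.annotation, fx.expressed_genes,
                          fx.evidence, params,
                          combined_counts=fx.combined_counts_recoded, **kwargs)

    def test_reproduces_published_verdict_pattern(self, paper_fixture):
        sheets = {s.key: s for s in self._run(paper_fixture)}
        assert sheets[DEFB1_KEY].verdict == "candidate"
        assert sheets[MBL2_KEY].verdict == "candidate"
        assert sheets[METTL7B_KEY].verdict == "rejected"
        assert sheets[METTL7B_KEY].criteria["replicated"] == "fail"
        # both failure modes reported independently: replication fails and
        # the in-cohort frequency exceeds the rarity definition
        assert any("rarity threshold" in note for note in sheets[METTL7B_KEY].notes)

    def test_cascade_is_monotone(self, paper_fixture):
        fx = paper_fixture
        ann = fx.annotation
        cases = fx.cohorts["discovery_cases"]
        controls = fx.cohorts["discovery_controls"]
        s1 = filter_damaging_nonsense(ann)
        s2 = case_only_filter(s1, cases, controls)
        s3, _ = rarity_filter(s2, ann)
        s4 = {k for k in s3 if ancestry_specificity(k, ann) == "pass"}
        s5 = expression_filter(s4, ann, fx.expressed_genes)
        assert s1 >= s2 >= s3 >= s4 >= s5

    def test_deterministic(self, paper_fixture):
        first = self._run(paper_fixture)
        second = self._run(paper_fixture)
        assert [(s.key, s.verdict, s.criteria) for s in first] == [
            (s.key, s.verdict, s.criteria) for s in second
        ]

    def test_missing_replication_data_leaves_criterion_unknown(self, paper_fixture):
        fx = paper_fixture
        sheets = run_screen(fx.cohorts, fx.annotation, fx.expressed_genes,
                            fx.evidence, ScreenParams(family_m=3))
        by_key = {s.key: s for s in sheets}
        assert by_key[DEFB1_KEY].criteria["replicated"] == "unknown"
        assert by_key[DEFB1_KEY].verdict == "indeterminate"
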