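"""Mamdani engine: membership, firing, aggregation, defuzzification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brcarisk import (
    CLASS_LABELS,
    PatientRecord,
    Rule,
    RuleBase,
    UndefinedScoreError,
    aggregate,
    aggregate_from_strengths,
    build_rulebase,
    defuzzify_centroid,
    encode_record,
    infer,
    membership,
    rule_strength,
)
from brcarisk.datamodel import MembershipFunctionSpec


@pytest.fixture
def triangle():
    return MembershipFunctionSpec(label="40-59", center=0.75, half_width=0.25)


class TestMembership:
    @pytest.mark.parametrize(
        "x, expected", [(0.75, 1.0), (0.5, 0.0), (0.625, 0.5), (1.0, 0.0)]
    )
    def test_piecewise_linear_triangle(self, triangle, x, expected):
        assert membership(triangle, x) == pytest.approx(expected)

    def test_out_of_domain_rejected(self, triangle):
        with pytest.raises(ValueError):
            membership(triangle, 1.5)

    @given(x=st.floats(0, 1))
    def test_degree_always_in_unit_interval(self, x):
        mf = MembershipFunctionSpec(label="mid", center=0.5, half_width=0.5)
        assert 0.0 <= membership(mf, x) <= 1.0


class TestRuleStrength:
    def _encoded(self, catalogue, **values):
        return encode_record(PatientRecord.from_values(**values), catalogue)

    def test_min_of_matching_clauses_is_one(self, catalogue):
        rule = Rule(
            antecedents={"sex": "Female", "lymph_node": "Positive"},
            consequent="VUS",
        )
        enc = self._encoded(catalogue, sex="Female", lymph_node="Positive")
        assert rule_strength(rule, enc, catalogue) == 1.0

    def test_any_zero_clause_annihilates(self, catalogue):
        rule = Rule(
            antecedents={"sex": "Female", "lymph_node": "Positive"},
            consequent="VUS",
        )
        enc = self._encoded(catalogue, sex="Female", lymph_node="Negative")
        assert rule_strength(rule, enc, catalogue) == 0.0

    def test_clauses_on_missing_inputs_are_skipped(self, catalogue):
        rule = Rule(
            antecedents={"sex": "Female", "grade": "Grade 3",
                         "diagnosis": "Yes"},
            consequent="Pathogenic",
        )
        enc = self._encoded(catalogue, sex="Female")  # grade, diagnosis unknown
        assert rule_strength(rule, enc, catalogue) == 1.0

    def test_unknown_factor_rejected(self, catalogue):
        rule = Rule(antecedents={"shoe_size": "44"}, consequent="VUS")
        enc = self._encoded(catalogue, sex="Female")
        with pytest.raises(KeyError, match="shoe_size"):
            rule_strength(rule, enc, catalogue)


class TestAggregateAndCentroid:
    def test_single_full_strength_rule_reproduces_output_mf(self, catalogue):
        fs = aggregate_from_strengths({"Likely Pathogenic": 1.0}, catalogue)
        expected = np.maximum(0.0, 1.0 - np.abs(fs.grid - 0.75) / 0.25)
        assert np.allclose(fs.mu, expected)

    def test_zero_strength_yields_flagged_empty_set(self, catalogue):
        fs = aggregate_from_strengths({"VUS": 0.0}, catalogue)
        assert fs.fired_rule_count == 0
        assert fs.mu.sum() == 0.0
        with pytest.raises(UndefinedScoreError):
            defuzzify_centroid(fs)

    def test_duplicate_rules_are_idempotent_under_max(self, catalogue):
        rule = Rule(antecedents={"sex": "Female"}, consequent="VUS")
        enc = encode_record(PatientRecord.from_values(sex="Female"), catalogue)
        one = aggregate(RuleBase(rules=(rule,)), enc, catalogue)
        two = aggregate(RuleBase(rules=(rule, rule)), enc, catalogue)
        assert np.array_equal(one.mu, two.mu)

    def test_empty_rulebase_rejected(self, catalogue):
        enc = encode_record(PatientRecord.from_values(sex="Female"), catalogue)
        with pytest.raises(ValueError):
            aggregate(RuleBase(rules=()), enc, catalogue)

    def test_coarse_resolution_rejected(self, catalogue):
        with pytest.raises(ValueError):
            aggregate_from_strengths({"VUS": 1.0}, catalogue, resolution=50)

    @pytest.mark.parametrize(
        "label, expected",
        [
            ("Likely Pathogenic", 0.75),  # symmetric triangle
            ("VUS", 0.5),
            ("Pathogenic", 0.75 + 2 / 3 * 0.25),  # right-edge shoulder ramp
            ("Benign", 1 / 3 * 0.25),
        ],
    )
    def test_centroid_of_single_class(self, catalogue, label, expected):
        fs = aggregate_from_strengths({label: 1.0}, catalogue)
        assert defuzzify_centroid(fs) == pytest.approx(expected, abs=1e-3)

    @given(
        strengths=st.lists(
            st.floats(0.05, 1.0), min_size=5, max_size=5
        )
    )
    def test_fine_grid_oracle_agreement(self, catalogue, strengths):
        """Centroid at resolution 1001 matches resolution 100001 within
        1e-3 for arbitrary clipped-max aggregates."""
        named = dict(zip(CLASS_LABELS, strengths))
        coarse = defuzzify_centroid(
            aggregate_from_strengths(named, catalogue, 1001))
        fine = defuzzify_centroid(
            aggregate_from_strengths(named, catalogue, 100001))
        assert abs(coarse - fine) <= 1e-3

    @given(strengths=st.lists(st.floats(0, 1), min_size=5, max_size=5))
    def test_centroid_inside_aggregate_support(self, catalogue, strengths):
        named = dict(zip(CLASS_LABELS, strengths))
        fs = aggregate_from_strengths(named, catalogue)
        if fs.mu.sum() == 0:
            return
        support = fs.grid[fs.mu > 0]
        assert support.min() <= defuzzify_centroid(fs) <= support.max()

    def test_raising_strength_toward_higher_class_never_lowers_score(
        self, catalogue
    ):
        base = {"VUS": 0.6, "Likely Benign": 0.3}
        scores = []
        for s in np.linspace(0.0, 1.0, 11):
            named = dict(base, Pathogenic=float(s))
            fs = aggregate_from_strengths(named, catalogue)
            scores.append(defuzzify_centroid(fs))
        assert all(b >= a - 1e-12 for a, b in zip(scores, scores[1:]))


class TestInfer:
    def test_sole_training_patient_scores_at_its_class_center(self, catalogue):
        patient = PatientRecord.from_values(
            class_label="Likely Pathogenic", record_id="p1",
            age=40, sex="Female", consanguinity="No", family_history="Yes",
            n_affected_family=2, tumour_size_cm=3.0, lymph_node="Negative",
            grade="Grade 2", position="Left Breast",
            estrogen_receptor="Positive", progesterone="Positive",
            brca1="Positive", brca2="Negative", other_genes="Negative",
            diagnosis="Yes",
        )
        rb = build_rulebase([patient], catalogue)
        score = infer(rb, patient, catalogue)
        assert score.value == pytest.approx(0.75, abs=1e-3)
        assert score.max_strength == 1.0

    def test_record_matching_no_rule_raises_with_record_id(self, catalogue):
        rule = Rule(antecedents={"sex": "Male"}, consequent="VUS")
        record = PatientRecord.from_values(sex="Female", record_id="R9")
        with pytest.raises(UndefinedScoreError, match="R9"):
            infer(RuleBase(rules=(rule,)), record, catalogue)

    def test_rule_order_permutation_leaves_scores_bit_identical(
        self, catalogue, cohort, rulebase
    ):
        rng = np.random.default_rng(7)
        shuffled = list(rulebase.rules)
        rng.shuffle(shuffled)
        permuted = RuleBase(rules=tuple(shuffled))
        for patient in cohort[:25]:
            a = infer(rulebase, patient, catalogue).value
            b = infer(permuted, patient, catalogue).value
            assert a == b

    def test_training_records_fire_their_own_rule_at_full_strength(
        self, catalogue
    ):
        from brcarisk import CohortConfig, generate_cohort

        config = CohortConfig(missingness_rate=0.0)
        complete = generate_cohort(config, seed=3)[:30]
        rb = build_rulebase(complete, catalogue)
        for patient, rule in zip(complete, rb):
            enc = encode_record(patient, catalogue)
            assert rule_strength(rule, enc, catalogue) == 1.0
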