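"""CURB-65 scoring, biomarker categorization and disposition routing."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bayesgains.clinical import (
    BiomarkerReading,
    Curb65Inputs,
    DispositionRule,
    DispositionRuleSet,
    assign_disposition,
    classify_biomarker,
    curb65_score,
    default_ruleset,
    export_tree,
)
from bayesgains.gains import PretestStratum, enumerate_branches

NORMAL = dict(confusion=False, bun=10, respiratory_rate=16, systolic_bp=120, diastolic_bp=80, age=40)


@pytest.mark.parametrize(
    "overrides, score, stratum",
    [
        ({}, 0, "outpatient"),
        (dict(confusion=True, bun=25, respiratory_rate=32, systolic_bp=85,
              diastolic_bp=55, age=70), 5, "high"),
        # boundary battery: DBP <= 60 and age >= 65 score; BUN > 19 strictly does not
        (dict(bun=19, diastolic_bp=60, age=65), 2, "discretion"),
        (dict(bun=19.1), 1, "outpatient"),
        (dict(respiratory_rate=30), 1, "outpatient"),
        (dict(systolic_bp=89.9), 1, "outpatient"),
        (dict(systolic_bp=85, diastolic_bp=55), 1, "outpatient"),  # BP scores once
        (dict(confusion=True, age=70, bun=30), 3, "intermediate"),
        (dict(confusion=True, age=70, bun=30, respiratory_rate=35), 4, "high"),
    ],
)
def test_curb65_scoring_and_strata(overrides, score, stratum):
    got_score, got_stratum = curb65_score(Curb65Inputs(**{**NORMAL, **overrides}))
    assert (got_score, got_stratum) == (score, stratum)


@given(st.tuples(*[st.booleans()] * 5), st.integers(0, 4))
def test_curb65_monotone_in_criteria(flags, flip_index):
    """Turning one more criterion on never lowers the score; score stays in [0, 5]."""

    def build(f):
        return Curb65Inputs(
            confusion=f[0],
            bun=25 if f[1] else 10,
            respiratory_rate=32 if f[2] else 16,
            systolic_bp=85 if f[3] else 120,
            diastolic_bp=80,
            age=70 if f[4] else 40,
        )

    base_score, _ = curb65_score(build(flags))
    raised = list(flags)
    raised[flip_index] = True
    raised_score, _ = curb65_score(build(tuple(raised)))
    assert 0 <= base_score <= raised_score <= 5


def test_negative_vitals_rejected():
    with pytest.raises(ValueError):
        Curb65Inputs(**{**NORMAL, "bun": -1})


@pytest.mark.parametrize(
    "name, value, outcome",
    [
        ("PCT", 0.3, "negative"),
        ("PCT", 0.5, "indeterminate"),
        ("PCT", 1.0, "indeterminate"),
        ("PCT", 2.0, "indeterminate"),
        ("PCT", 2.5, "positive"),
        ("Lactate", 2.0, "negative"),
        ("Lactate", 2.5, "positive"),
    ],
)
def test_biomarker_categorization(name, value, outcome):
    assert classify_biomarker(BiomarkerReading(name, value)) == outcome


def test_unknown_biomarker_rejected():
    with pytest.raises(ValueError, match="unknown biomarker"):
        classify_biomarker(BiomarkerReading("CRP", 5.0))


@given(st.floats(min_value=0, max_value=10))
def test_biomarker_outcomes_partition_the_axis(value):
    for name in ("PCT", "Lactate"):
        outcome = classify_biomarker(BiomarkerReading(name, value))
        assert outcome in ("negative", "indeterminate", "positive")


@pytest.fixture()
def intermediate_branches(study):
    stratum = study.stratum("intermediate")
    tests = [study.test(n) for n in study.sequence]
    return enumerate_branches(stratum, tests, lr_overrides=study.printed_lrs)


def test_default_rules_route_double_positive_to_icu(study, intermediate_branches):
    rules = default_ruleset()
    assignment = assign_disposition("intermediate", intermediate_branches[0], rules)
    assert assignment.disposition == "ICU"
    assert assignment.rule_index == 0  # the explicit published rule, not a threshold


def test_default_rules_route_positive_negative_below_icu(study, intermediate_branches):
    rules = default_ruleset()
    pos_neg = intermediate_branches[1]
    assert pos_neg.pattern == ("positive", "negative")
    assignment = assign_disposition("intermediate", pos_neg, rules)
    assert assignment.disposition != "ICU"
    assert assignment.disposition == "Observation"  # posterior 17% in [0.15, 0.50)


def test_assignments_are_total_and_deterministic(study):
    rules = default_ruleset()
    for stratum in study.strata:
        branches = enumerate_branches(stratum, [study.test(n) for n in study.sequence])
        for br in branches:
            first = assign_disposition(stratum.label, br, rules)
            second = assign_disposition(stratum.label, br, rules)
            assert first == second
            assert first.disposition in ("ICU", "StepDown", "Observation", "Ward", "Outpatient")


def test_single_wildcard_rule_catches_everything(intermediate_branches):
    rules = DispositionRuleSet((DispositionRule("Ward"),))
    for br in intermediate_branches:
        assert assign_disposition("intermediate", br, rules).disposition == "Ward"


def test_non_total_ruleset_rejected_at_load():
    with pytest.raises(ValueError, match="not total"):
        DispositionRuleSet((DispositionRule("ICU", posterior_min=0.5, posterior_max=1.0),))
    with pytest.raises(ValueError, match="not total"):
        # only a stratum-specific rule: no full-wildcard coverage
        DispositionRuleSet((DispositionRule("ICU", stratum="intermediate"),))


def test_tree_export_round_trip(study, intermediate_branches):
    rules = default_ruleset()
    doc = export_tree(rules, intermediate_branches)
    data = json.loads(doc.to_json())
    reloaded = DispositionRuleSet.from_list(data["rules"])
    for br, entry in zip(intermediate_branches, data["branches"]):
        again = assign_disposition("intermediate", br, reloaded)
        assert again.disposition == entry["disposition"]
        assert again.rule_index == entry["rule_index"]


def test_tree_dot_annotates_published_posteriors(study, intermediate_branches):
    doc = export_tree(default_ruleset(), intermediate_branches)
    assert "digraph" in doc.dot
    assert "posterior 93%" in doc.dot and "ICU" in doc.dot
    assert "posterior 17%" in doc.dot
    # deterministic output
    assert doc.dot == export_tree(default_ruleset(), intermediate_branches).dot


def test_tree_export_empty_panel_single_leaf():
    stratum = PretestStratum("intermediate", 0.14)
    branches = enumerate_branches(stratum, [])
    doc = export_tree(default_ruleset(), branches)
    assert "leaf" in doc.dot
    data = json.loads(doc.to_json())
    assert len(data["branches"]) == 1 and data["tests"] == []
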