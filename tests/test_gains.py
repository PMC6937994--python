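"""Sequential chaining, branch enumeration, diagnostic gains and ANOVA."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from bayesgains.bayes import TestAccuracy, posttest_probability
from bayesgains.gains import (
    PretestStratum,
    absolute_gain,
    bayesian_nnd,
    enumerate_branches,
    gains_table,
    one_way_anova,
    relative_gain,
    round_posterior,
    sequential_posterior,
    stage_groups,
)

probs = st.floats(min_value=0.01, max_value=0.99)
lrs_strategy = st.floats(min_value=0.01, max_value=100.0)


@pytest.mark.parametrize(
    "pretest, lrs, expected_pct",
    [
        (0.14, [4.63, 19.0], 93),
        (0.278, [4.63, 19.0], 97),
        (0.14, [4.63, 0.28], 17),
        (0.278, [4.63, 0.28], 33),
    ],
)
def test_sequential_posterior_matches_published(pretest, lrs, expected_pct):
    trace = sequential_posterior(pretest, lrs)
    assert len(trace) == len(lrs)
    assert round(trace[-1] * 100) == expected_pct


def test_empty_sequence_returns_pretest():
    assert sequential_posterior(0.14, []) == []  # posterior stays at the pretest


@given(probs, lrs_strategy, lrs_strategy)
def test_chaining_equals_product_lr_update(p, a, b):
    chained = sequential_posterior(p, [a, b])[-1]
    single = posttest_probability(p, a * b)
    assert chained == pytest.approx(single, abs=1e-12)
    permuted = sequential_posterior(p, [b, a])[-1]
    assert chained == pytest.approx(permuted, abs=1e-12)


@given(
    probs,
    st.lists(st.tuples(probs, probs), min_size=1, max_size=3),
)
def test_branch_probabilities_obey_total_probability(pretest, accuracies):
    """Branch masses sum to 1 and average the posterior back to the pretest."""
    stratum = PretestStratum("s", pretest)
    tests = [TestAccuracy(f"t{i}", se, sp) for i, (se, sp) in enumerate(accuracies)]
    branches = enumerate_branches(stratum, tests)
    assert len(branches) == 2 ** len(tests)
    total = sum(b.branch_probability for b in branches)
    assert total == pytest.approx(1.0, abs=1e-12)
    mixture = sum(b.branch_probability * b.final_posterior for b in branches)
    assert mixture == pytest.approx(pretest, abs=1e-10)


def test_branch_enumeration_order_and_posteriors(study):
    """Four branches, positive-first; the +/- branch reproduces the 17% figure."""
    stratum = study.stratum("intermediate")
    tests = [study.test(n) for n in study.sequence]
    branches = enumerate_branches(stratum, tests, lr_overrides=study.printed_lrs)
    patterns = [b.pattern for b in branches]
    assert patterns == [
        ("positive", "positive"),
        ("positive", "negative"),
        ("negative", "positive"),
        ("negative", "negative"),
    ]
    assert round(branches[0].final_posterior * 100) == 93
    assert round(branches[1].final_posterior * 100) == 17


def test_perfect_test_branch_probability():
    stratum = PretestStratum("s", 0.3)
    branches = enumerate_branches(stratum, [TestAccuracy("perfect", 1.0, 1.0)])
    positive = branches[0]
    assert positive.pattern == ("positive",)
    assert positive.branch_probability == pytest.approx(0.3)
    assert positive.final_posterior == 1.0


def test_empty_panel_yields_single_pretest_branch():
    stratum = PretestStratum("s", 0.14)
    (branch,) = enumerate_branches(stratum, [])
    assert branch.final_posterior == 0.14
    assert branch.branch_probability == pytest.approx(1.0)


@pytest.mark.parametrize(
    "pretest, posttest, adg",
    [(0.14, 0.43, 29.0), (0.278, 0.05, -22.8), (0.6, 0.6, 0.0)],
)
def test_absolute_gain(pretest, posttest, adg):
    assert absolute_gain(pretest, posttest) == pytest.approx(adg, abs=1e-9)


def test_relative_gain_magnitude_and_direction():
    up = relative_gain(0.14, 0.43)
    assert round(up.magnitude, 1) == 207.1 and up.direction == "gain"
    down = relative_gain(0.14, 0.04)
    assert round(down.magnitude, 1) == 71.4 and down.direction == "loss"
    flat = relative_gain(0.25, 0.25)
    assert flat.magnitude == 0.0
    with pytest.raises(ValueError):
        relative_gain(0.0, 0.5)


@pytest.mark.parametrize(
    "adg, value, integer",
    [(0.29, 3.45, 3), (0.79, 1.27, 1), (0.62, 1.61, 2), (1.0, 1.0, 1)],
)
def test_bayesian_nnd_published_values(adg, value, integer):
    b = bayesian_nnd(adg)
    assert round(b.value, 2) == value
    assert b.integer == integer


@pytest.mark.parametrize("adg", [0.0, -0.1])
def test_bayesian_nnd_requires_positive_gain(adg):
    with pytest.raises(ValueError):
        bayesian_nnd(adg)


@given(st.floats(min_value=0.01, max_value=1.0))
def test_bnnd_reciprocal_identity(adg):
    assert bayesian_nnd(adg).value * adg == pytest.approx(1.0, abs=1e-12)


def test_gains_identity_without_rounding(study):
    """Under policy 'none', ADG + pretest equals the post-test exactly."""
    df = gains_table(study.strata, study.tests, study.sequence, "none", study.printed_lrs)
    recon = df["pretest_pct"] + df["adg_pp"]
    assert np.allclose(recon, df["posttest_pct"], atol=1e-6)


def test_gains_table_reproduces_published_rows(study):
    df = gains_table(
        study.strata, study.tests, study.sequence, "nomogram", study.printed_lrs
    ).set_index(["stratum", "step", "outcome"])
    row = df.loc[("intermediate", "PCT", "positive")]
    assert (row["posttest_pct"], round(row["adg_pp"], 1), round(row["rdg_pct"], 1)) == (
        43.0, 29.0, 207.1,
    )
    row = df.loc[("intermediate", "Lactate", "positive")]
    assert (row["posttest_pct"], round(row["rdg_pct"], 1)) == (76.0, 442.9)
    row = df.loc[("high", "Lactate", "positive")]
    assert (row["posttest_pct"], round(row["adg_pp"], 1)) == (88.0, 60.2)
    row = df.loc[("intermediate", "PCT+Lactate", "positive,positive")]
    assert (row["posttest_pct"], round(row["bnnd"], 2)) == (93.0, 1.27)


def test_gains_table_unit_lr_degenerate():
    stratum = PretestStratum("s", 0.2)
    test = TestAccuracy("coin", 0.5, 0.5)  # LR+ = LR- = 1
    df = gains_table([stratum], [test], rounding_policy="none")
    assert (df["adg_pp"] == 0).all()
    assert (df["rdg_pct"] == 0).all()
    assert df["bnnd"].isna().all()


def test_unknown_sequence_name_rejected(study):
    with pytest.raises(ValueError, match="unknown test"):
        gains_table(study.strata, study.tests, ["PCT", "CRP"])


def test_rounding_policy_validation():
    with pytest.raises(ValueError, match="rounding policy"):
        round_posterior(0.5, "bankers")


def test_stage_groups_match_published_model(study):
    pos_lrs = [study.lr_pair(n)[0] for n in study.sequence]
    groups = stage_groups(study.strata, pos_lrs, "nomogram")
    assert groups == [[14.0, 27.8], [43.0, 64.0], [93.0, 97.0]]


def test_anova_reproduces_published_f_and_p():
    res = one_way_anova([[14.0, 27.8], [43, 64], [93, 97]])
    assert res.f_statistic == pytest.approx(25.565, abs=0.001)
    assert res.p_value == pytest.approx(0.013, abs=0.0005)
    assert (res.df_between, res.df_within) == (2, 3)


def test_anova_identical_groups_give_zero_f():
    res = one_way_anova([[1, 2], [1, 2], [1, 2]])
    assert res.f_statistic == 0.0
    assert res.p_value == 1.0


def test_anova_matches_scipy_on_random_groups():
    rng = np.random.default_rng(7)
    for _ in range(20):
        groups = [rng.normal(loc, 1.0, size=5) for loc in rng.uniform(0, 3, size=3)]
        res = one_way_anova(groups)
        ref_f, ref_p = stats.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(ref_f, abs=1e-10)
        assert res.p_value == pytest.approx(ref_p, abs=1e-10)


def test_anova_invariances():
    rng = np.random.default_rng(11)
    groups = [rng.normal(m, 1.0, size=4) for m in (0.0, 1.0, 2.5)]
    base = one_way_anova(groups)
    shifted = one_way_anova([g + 17.3 for g in groups])
    scaled = one_way_anova([g * 4.2 for g in groups])
    assert shifted.f_statistic == pytest.approx(base.f_statistic, rel=1e-9)
    assert scaled.f_statistic == pytest.approx(base.f_statistic, rel=1e-9)


def test_anova_p_monotone_in_f():
    fs = np.linspace(0.5, 40, 30)
    ps = [float(stats.f.sf(f, 2, 3)) for f in fs]
    res_low = one_way_anova([[0, 1], [0.2, 1.2], [0.1, 1.1]])
    res_high = one_way_anova([[0, 0.1], [5, 5.1], [10, 10.1]])
    assert res_high.f_statistic > res_low.f_statistic
    assert res_high.p_value < res_low.p_value
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_anova_degenerate_and_invalid_inputs():
    res = one_way_anova([[1.0, 1.0], [2.0, 2.0]])
    assert math.isinf(res.f_statistic) and res.p_value == 0.0
    with pytest.raises(ValueError):
        one_way_anova([[1.0, 2.0]])
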