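"""Sequential posterior chaining, branch enumeration, diagnostic gains and ANOVA.

Chaining assumes conditional independence of test results given true disease
status, so a sequence of odds updates equals a single update by the product
of the likelihood ratios.  Branch probabilities come from the matching
generative model::

    P(results) = pretest * prod P(result_i | diseased)
               + (1 - pretest) * prod P(result_i | healthy)

Bayesian Diagnostic Gains compare pretest and post-test probability:
ADG = post - pre (percentage points, signed); RDG = 100 * |ADG| / pre with a
gain/loss direction flag; B-NND = 1 / ADG (ADG as a proportion), the
diagnostic analogue of the number needed to treat.

Two rounding policies are supported.  ``"nomogram"`` (the default for
reproducing published tables) rounds every posterior to the nearest whole
percent *before* gains are computed, emulating values read off a Fagan
nomogram; ``"none"`` keeps full precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import TestAccuracy, lr_from_accuracy, posttest_probability

__all__ = [
    "PretestStratum",
    "TestResult",
    "SequentialBranch",
    "GainsRecord",
    "RelativeGain",
    "Bnnd",
    "AnovaResult",
    "ROUNDING_POLICIES",
    "round_posterior",
    "sequential_posterior",
    "enumerate_branches",
    "absolute_gain",
    "relative_gain",
    "bayesian_nnd",
    "gains_record",
    "gains_table",
    "stage_groups",
    "one_way_anova",
]

ROUNDING_POLICIES = ("nomogram", "none")

GAINS_COLUMNS = [
    "stratum",
    "step",
    "outcome",
    "pretest_pct",
    "posttest_pct",
    "adg_pp",
    "rdg_pct",
    "bnnd",
]


@dataclass(frozen=True)
class PretestStratum:
    """A named pretest probability, e.g. a CURB-65 risk class prevalence."""

    label: str
    pretest: float
    source: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.pretest < 1):
            raise ValueError(
                f"stratum {self.label!r}: pretest must be in (0, 1), got {self.pretest!r}"
            )


@dataclass(frozen=True)
class TestResult:
    test_name: str
    outcome: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.outcome not in ("positive", "negative"):
            raise ValueError(f"outcome must be positive/negative, got {self.outcome!r}")


@dataclass(frozen=True)
class SequentialBranch:
    """One path through a test panel: outcomes, posterior trace, branch mass."""

    stratum: PretestStratum
    results: Tuple[TestResult, ...]
    step_posteriors: Tuple[float, ...]
    final_posterior: float
    branch_probability: float

    @property
    def pattern(self) -> Tuple[str, ...]:
        return tuple(r.outcome for r in self.results)


@dataclass(frozen=True)
class RelativeGain:
    magnitude: float  # percent of pretest, always >= 0
    direction: str  # "gain" | "loss"


@dataclass(frozen=True)
class Bnnd:
    value: float
    integer: int  # the published nearest-integer presentation


@dataclass(frozen=True)
class GainsRecord:
    stratum: str
    step: str
    outcome: str
    pretest: float  # proportion
    posttest: float  # proportion, rounded per policy
    adg_pp: float  # signed percentage points
    rdg: RelativeGain
    bnnd: Optional[Bnnd]  # defined only for adg > 0
    rounding_policy: str


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: Tuple[float, ...]


def round_posterior(p: float, policy: str) -> float:
    """Apply a rounding policy to a posterior probability (proportion in/out)."""
    if policy not in ROUNDING_POLICIES:
        raise ValueError(f"unknown rounding policy {policy!r}; use one of {ROUNDING_POLICIES}")
    if policy == "nomogram":
        return math.floor(p * 100 + 0.5) / 100
    return p


def sequential_posterior(pretest: float, lrs: Sequence[float]) -> List[float]:
    """Chain odds-form updates; returns the posterior trace, one value per step.

    Under conditional independence the final value equals a single update by
    the product of the LRs.  An empty sequence returns an empty trace (the
    posterior is the pretest).

    Examples
    --------
    >>> trace = sequential_posterior(0.14, [4.63, 19.0])
    >>> round(trace[-1] * 100)
    93
    """
    trace: List[float] = []
    p = pretest
    for lr in lrs:
        p = posttest_probability(p, lr)
        trace.append(p)
    return trace


def enumerate_branches(
    stratum: PretestStratum,
    tests: Sequence[TestAccuracy],
    lr_overrides: Optional[dict] = None,
) -> List[SequentialBranch]:
    """All 2^k outcome branches of a test panel, with posteriors and masses.

    Branches come in deterministic lexicographic order, positive before
    negative, first test most significant.  By default posteriors are chained
    from LRs recomputed from each test's sensitivity/specificity, so the law
    of total probability holds exactly: branch probabilities sum to 1 and
    sum(branch_probability * posterior) equals the pretest.

    ``lr_overrides`` (test name -> (LR+, LR-)) substitutes externally
    published LR values into the posterior trace — used to reproduce printed
    figures — while branch masses always come from the accuracies; with
    overrides the conservation identity holds only approximately.

    An empty panel yields the single pretest branch.
    """
    lr_overrides = lr_overrides or {}
    branches: List[SequentialBranch] = []
    for pattern in itertools.product(("positive", "negative"), repeat=len(tests)):
        p = stratum.pretest
        prod_diseased = 1.0
        prod_healthy = 1.0
        trace: List[float] = []
        for test, outcome in zip(tests, pattern):
            if test.name in lr_overrides:
                pair = lr_overrides[test.name]
            else:
                lrs = lr_from_accuracy(test)
                pair = (lrs.lr_positive, lrs.lr_negative)
            if outcome == "positive":
                lr = pair[0]
                prod_diseased *= test.sensitivity
                prod_healthy *= 1 - test.specificity
            else:
                lr = pair[1]
                prod_diseased *= 1 - test.sensitivity
                prod_healthy *= test.specificity
            p = posttest_probability(p, lr)
            trace.append(p)
        mass = stratum.pretest * prod_diseased + (1 - stratum.pretest) * prod_healthy
        branches.append(
            SequentialBranch(
                stratum=stratum,
                results=tuple(TestResult(t.name, o) for t, o in zip(tests, pattern)),
                step_posteriors=tuple(trace),
                final_posterior=trace[-1] if trace else stratum.pretest,
                branch_probability=mass,
            )
        )
    return branches


def absolute_gain(pretest: float, posttest: float) -> float:
    """ADG: post-test minus pretest probability, in signed percentage points."""
    for name, v in (("pretest", pretest), ("posttest", posttest)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must be in [0, 1], got {v!r}")
    return (posttest - pretest) * 100


def relative_gain(pretest: float, posttest: float) -> RelativeGain:
    """RDG: absolute gain as a percentage of pretest, magnitude + direction.

    Published tables print RDG as a positive magnitude even when the absolute
    gain is negative (a "loss"); the direction flag preserves the sign.
    """
    if pretest <= 0:
        raise ValueError("relative gain undefined for pretest = 0")
    adg = posttest - pretest
    return RelativeGain(
        magnitude=100 * abs(adg) / pretest,
        direction="loss" if adg < 0 else "gain",
    )


def bayesian_nnd(adg: float) -> Bnnd:
    """Bayesian Number Needed to Diagnose: 1 / ADG with ADG as a proportion.

    Defined only for positive gains; the ideal value is 1.  The ``integer``
    field carries the nearest-integer presentation used in published tables.

    Examples
    --------
    >>> bayesian_nnd(0.29)
    Bnnd(value=3.4482758620689657, integer=3)
    """
    if adg <= 0:
        raise ValueError(
            f"B-NND is undefined for non-positive absolute gain (got {adg!r}); "
            "it applies to positive diagnostic gains only"
        )
    value = 1.0 / adg
    return Bnnd(value=value, integer=int(math.floor(value + 0.5)))


def gains_record(
    stratum: PretestStratum,
    step: str,
    outcome: str,
    lrs: Sequence[float],
    rounding_policy: str = "nomogram",
) -> GainsRecord:
    """Build one pretest/post-test gains record for a chained LR sequence."""
    trace = sequential_posterior(stratum.pretest, lrs)
    post_raw = trace[-1] if trace else stratum.pretest
    post = round_posterior(post_raw, rounding_policy)
    adg_pp = absolute_gain(stratum.pretest, post)
    rdg = relative_gain(stratum.pretest, post)
    bnnd = bayesian_nnd(adg_pp / 100) if adg_pp > 0 else None
    return GainsRecord(
        stratum=stratum.label,
        step=step,
        outcome=outcome,
        pretest=stratum.pretest,
        posttest=post,
        adg_pp=adg_pp,
        rdg=rdg,
        bnnd=bnnd,
        rounding_policy=rounding_policy,
    )


def _records_frame(records: Sequence[GainsRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "stratum": r.stratum,
                "step": r.step,
                "outcome": r.outcome,
                "pretest_pct": round(r.pretest * 100, 4),
                "posttest_pct": round(r.posttest * 100, 4),
                "adg_pp": round(r.adg_pp, 4),
                "rdg_pct": round(r.rdg.magnitude, 4),
                "bnnd": round(r.bnnd.value, 4) if r.bnnd is not None else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=GAINS_COLUMNS)


def gains_table(
    strata: Sequence[PretestStratum],
    tests: Sequence[TestAccuracy],
    sequence: Optional[Sequence[str]] = None,
    rounding_policy: str = "nomogram",
    printed_lrs: Optional[dict] = None,
) -> pd.DataFrame:
    """Assemble the full gains table: single tests plus sequential branches.

    For each stratum the table holds one row per (test, outcome) single-step
    update, then one row per outcome branch of the ordered ``sequence``
    (2^k rows, positive-first order).  ``printed_lrs`` optionally maps test
    name -> (lr_positive, lr_negative) to reproduce published tables from the
    LRs as printed rather than as recomputed.

    Columns: stratum, step, outcome, pretest_pct, posttest_pct, adg_pp,
    rdg_pct, bnnd (NaN where the gain is not positive).
    """
    by_name = {t.name: t for t in tests}
    if sequence:
        unknown = [n for n in sequence if n not in by_name]
        if unknown:
            raise ValueError(f"sequence refers to unknown test name(s): {unknown}")

    def lr_pair(test: TestAccuracy) -> Tuple[float, float]:
        if printed_lrs and test.name in printed_lrs:
            return tuple(printed_lrs[test.name])  # type: ignore[return-value]
        lrs = lr_from_accuracy(test)
        return (lrs.lr_positive, lrs.lr_negative)

    records: List[GainsRecord] = []
    for stratum in strata:
        for test in tests:
            pos, neg = lr_pair(test)
            records.append(gains_record(stratum, test.name, "positive", [pos], rounding_policy))
            records.append(gains_record(stratum, test.name, "negative", [neg], rounding_policy))
        if sequence and len(sequence) > 1:
            step = "+".join(sequence)
            seq_tests = [by_name[n] for n in sequence]
            for pattern in itertools.product(("positive", "negative"), repeat=len(seq_tests)):
                lrs = [
                    lr_pair(t)[0] if o == "positive" else lr_pair(t)[1]
                    for t, o in zip(seq_tests, pattern)
                ]
                records.append(
                    gains_record(stratum, step, ",".join(pattern), lrs, rounding_policy)
                )
    return _records_frame(records)


def stage_groups(
    strata: Sequence[PretestStratum],
    lr_steps: Sequence[float],
    rounding_policy: str = "nomogram",
) -> List[List[float]]:
    """Stage-comparison groups for the model ANOVA, in percent.

    Group 1 holds the stratum pretests; group i+1 holds each stratum's
    posterior after chaining the first i likelihood ratios, rounded per
    policy.  With k LR steps this yields k+1 groups of len(strata) values.
    """
    groups: List[List[float]] = [[round(s.pretest * 100, 9) for s in strata]]
    for i in range(1, len(lr_steps) + 1):
        groups.append(
            [
                round(
                    round_posterior(
                        sequential_posterior(s.pretest, lr_steps[:i])[-1], rounding_policy
                    )
                    * 100,
                    9,
                )
                for s in strata
            ]
        )
    return groups


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Fixed-effects one-way ANOVA from the sum-of-squares decomposition.

    F = (SSB / (k - 1)) / (SSW / (N - k)); the p-value is the upper tail of
    the F distribution with (k - 1, N - k) degrees of freedom.  Zero
    within-group variance with non-zero between-group variance reports an
    explicit infinite F with p = 0.
    """
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must contain at least one observation")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    if df_within < 1:
        raise ValueError("one-way ANOVA needs at least 1 within-group degree of freedom")

    grand_mean = np.concatenate(arrays).mean()
    means = tuple(float(a.mean()) for a in arrays)
    ssb = float(sum(a.size * (a.mean() - grand_mean) ** 2 for a in arrays))
    ssw = float(sum(((a - a.mean()) ** 2).sum() for a in arrays))

    if ssw == 0.0:
        f = math.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    else:
        f = (ssb / df_between) / (ssw / df_within)
        p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(
        f_statistic=f,
        df_between=df_between,
        df_within=df_within,
        p_value=p,
        group_means=means,
    )
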