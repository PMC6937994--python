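"""Likelihood-ratio arithmetic and single-step Bayesian (Fagan-nomogram) updating.

The central operation is the odds form of Bayes' theorem used by the Fagan
nomogram: post-test odds = pre-test odds x likelihood ratio.  All functions
in this module work on *proportions* in [0, 1]; percentage conversion happens
only at the I/O boundary (see :mod:`bayesgains.config` and the CLI).

An infinite positive likelihood ratio (specificity exactly 1) is a first-class
value and propagates to a posterior of 1 for any non-degenerate pretest.
Boundary pretest probabilities 0 and 1 are absorbing: no likelihood ratio
moves them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "TestAccuracy",
    "LikelihoodRatios",
    "lr_from_accuracy",
    "prob_to_odds",
    "odds_to_prob",
    "posttest_probability",
    "posterior_interval",
]

Interval = Tuple[float, float]


def _check_proportion(name: str, value: float, *, allow_zero: bool = False) -> None:
    lo_ok = value >= 0 if allow_zero else value > 0
    if not (lo_ok and value <= 1):
        bound = "[0, 1]" if allow_zero else "(0, 1]"
        raise ValueError(f"{name} must be a proportion in {bound}, got {value!r}")


def _check_ci(name: str, point: float, ci: Optional[Interval]) -> None:
    if ci is None:
        return
    low, high = ci
    _check_proportion(f"{name} CI low", low)
    _check_proportion(f"{name} CI high", high)
    if not (low <= point <= high):
        raise ValueError(
            f"{name} CI ({low}, {high}) does not contain the point estimate {point}"
        )


@dataclass(frozen=True)
class TestAccuracy:
    """A diagnostic test's accuracy: sensitivity/specificity with optional 95% CIs.

    Parameters
    ----------
    name : str
        Test identifier, e.g. ``"PCT"`` (procalcitonin) or ``"Lactate"``.
    sensitivity, specificity : float
        Proportions in (0, 1]: P(test positive | diseased) and
        P(test negative | healthy).
    sens_ci, spec_ci : (float, float), optional
        Confidence intervals around the point estimates.
    positivity_definition : str
        Human-readable positivity cut, e.g. ``"lactate > 2 mmol/L"``.
    """

    __test__ = False  # not a pytest class, despite the Test* name

    name: str
    sensitivity: float
    specificity: float
    sens_ci: Optional[Interval] = None
    spec_ci: Optional[Interval] = None
    positivity_definition: str = ""

    def __post_init__(self) -> None:
        _check_proportion("sensitivity", self.sensitivity)
        _check_proportion("specificity", self.specificity)
        _check_ci("sensitivity", self.sensitivity, self.sens_ci)
        _check_ci("specificity", self.specificity, self.spec_ci)


@dataclass(frozen=True)
class LikelihoodRatios:
    """Positive and negative likelihood ratios, optionally with intervals.

    ``lr_positive`` may be ``math.inf`` (perfect specificity);
    ``lr_negative`` may be 0 (perfect sensitivity).  For an informative test
    (sensitivity + specificity > 1), LR+ > 1 and LR- < 1.
    """

    lr_positive: float
    lr_negative: float
    lr_positive_interval: Optional[Interval] = None
    lr_negative_interval: Optional[Interval] = None

    def __post_init__(self) -> None:
        if not (self.lr_positive > 0):
            raise ValueError(f"lr_positive must be > 0, got {self.lr_positive!r}")
        if not (self.lr_negative >= 0):
            raise ValueError(f"lr_negative must be >= 0, got {self.lr_negative!r}")


def lr_from_accuracy(acc: TestAccuracy) -> LikelihoodRatios:
    """Compute LR+ = sens / (1 - spec) and LR- = (1 - sens) / spec.

    Specificity of exactly 1 gives an infinite LR+; sensitivity of exactly 1
    gives LR- = 0.  When both accuracy CIs are present, approximate LR
    intervals are attached by evaluating the LR formulas over all four
    (sensitivity, specificity) CI corners and taking the extrema.  These are
    approximate — without the underlying 2x2 counts the standard log-method
    interval cannot be computed.

    Examples
    --------
    >>> lrs = lr_from_accuracy(TestAccuracy("PCT", 0.88, 0.81))
    >>> round(lrs.lr_positive, 2), round(lrs.lr_negative, 2)
    (4.63, 0.15)
    """
    lr_pos = math.inf if acc.specificity == 1 else acc.sensitivity / (1 - acc.specificity)
    lr_neg = (1 - acc.sensitivity) / acc.specificity

    pos_iv = neg_iv = None
    if acc.sens_ci is not None and acc.spec_ci is not None:
        corners = [
            (se, sp) for se in acc.sens_ci for sp in acc.spec_ci
        ]
        pos_vals = [math.inf if sp == 1 else se / (1 - sp) for se, sp in corners]
        neg_vals = [(1 - se) / sp for se, sp in corners]
        pos_iv = (min(pos_vals), max(pos_vals))
        neg_iv = (min(neg_vals), max(neg_vals))

    return LikelihoodRatios(lr_pos, lr_neg, pos_iv, neg_iv)


def prob_to_odds(p: float) -> float:
    """Convert a probability to odds, p / (1 - p).  p = 1 maps to +inf."""
    _check_proportion("probability", p, allow_zero=True)
    if p == 1:
        return math.inf
    return p / (1 - p)


def odds_to_prob(odds: float) -> float:
    """Convert odds to a probability, odds / (1 + odds).  +inf maps to 1."""
    if odds < 0:
        raise ValueError(f"odds must be non-negative, got {odds!r}")
    if math.isinf(odds):
        return 1.0
    return odds / (1 + odds)


def posttest_probability(pretest: float, lr: float) -> float:
    """Single Fagan-nomogram update: posterior from pretest probability and an LR.

    Equivalent to the direct Bayes form
    ``pretest * sens / (pretest * sens + (1 - pretest) * (1 - spec))``
    when ``lr`` is the LR+ of the test in question.

    Pretest 0 and 1 are absorbing regardless of the likelihood ratio.

    Examples
    --------
    >>> round(posttest_probability(0.14, 4.63), 2)
    0.43
    """
    _check_proportion("pretest", pretest, allow_zero=True)
    if lr < 0:
        raise ValueError(f"likelihood ratio must be non-negative, got {lr!r}")
    if pretest in (0.0, 1.0):
        return pretest
    if lr == 1:
        return pretest  # an uninformative result leaves the probability unchanged
    if math.isinf(lr):
        return 1.0
    return odds_to_prob(prob_to_odds(pretest) * lr)


def posterior_interval(pretest: float, lr_interval: Interval) -> Interval:
    """Posterior interval from an LR interval: the update at each bound.

    The odds update is monotone increasing in the LR, so the posterior at the
    low LR bound is the low posterior bound.  Inverted bounds are rejected.
    """
    low, high = lr_interval
    if not (0 < low <= high):
        raise ValueError(
            f"LR interval bounds must satisfy 0 < low <= high, got ({low!r}, {high!r})"
        )
    return (posttest_probability(pretest, low), posttest_probability(pretest, high))
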