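"""Monte-Carlo patient-cohort simulator: the empirical oracle for the chain.

Disease status is drawn Bernoulli(prevalence); each test result is drawn
conditionally on status — positive with probability ``sensitivity`` if
diseased and ``1 - specificity`` if healthy — independently across tests
given status.  That generative model is exactly the conditional-independence
assumption under which likelihood ratios multiply, so empirical branch
frequencies and within-branch disease fractions converge to the analytic
branch probabilities and chained posteriors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .bayes import TestAccuracy
from .gains import PretestStratum, enumerate_branches

__all__ = [
    "SimulationConfig",
    "CohortCounts",
    "simulate_cohort",
    "empirical_posterior",
    "counts_frame",
]

Pattern = Tuple[str, ...]


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int
    prevalence: float
    tests: Tuple[TestAccuracy, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not (0 <= self.prevalence <= 1):
            raise ValueError("prevalence must be in [0, 1]")


@dataclass(frozen=True)
class CohortCounts:
    """Per-branch diseased/healthy tallies for one simulated cohort."""

    config: SimulationConfig
    diseased: Dict[Pattern, int]
    healthy: Dict[Pattern, int]

    @property
    def n_patients(self) -> int:
        return sum(self.diseased.values()) + sum(self.healthy.values())

    def branch_total(self, pattern: Pattern) -> int:
        return self.diseased[pattern] + self.healthy[pattern]


def _all_patterns(k: int) -> list:
    return list(itertools.product(("positive", "negative"), repeat=k))


def simulate_cohort(config: SimulationConfig) -> CohortCounts:
    """Simulate a cohort and tally each outcome branch, reproducibly by seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    diseased_mask = rng.random(n) < config.prevalence

    # Encode each patient's result pattern as bits, first test most significant.
    k = len(config.tests)
    codes = np.zeros(n, dtype=np.int64)
    for test in config.tests:
        p_pos = np.where(diseased_mask, test.sensitivity, 1 - test.specificity)
        positive = rng.random(n) < p_pos
        codes = codes * 2 + np.where(positive, 0, 1)  # 0 = positive, keeps order

    patterns = _all_patterns(k)
    diseased: Dict[Pattern, int] = {}
    healthy: Dict[Pattern, int] = {}
    dis_counts = np.bincount(codes[diseased_mask], minlength=2**k)
    hea_counts = np.bincount(codes[~diseased_mask], minlength=2**k)
    for code, pattern in enumerate(patterns):
        diseased[pattern] = int(dis_counts[code])
        healthy[pattern] = int(hea_counts[code])
    return CohortCounts(config=config, diseased=diseased, healthy=healthy)


def empirical_posterior(counts: CohortCounts, pattern: Pattern) -> Tuple[float, float]:
    """Observed disease fraction in a branch, with its binomial standard error.

    Returns (p_hat, se) where se = sqrt(p_hat (1 - p_hat) / n_branch).
    An empty branch has no defined posterior and is rejected explicitly.
    """
    pattern = tuple(pattern)
    if pattern not in counts.diseased:
        raise ValueError(f"unknown branch pattern {pattern!r}")
    n_branch = counts.branch_total(pattern)
    if n_branch == 0:
        raise ValueError(f"branch {pattern!r} is empty; empirical posterior undefined")
    p_hat = counts.diseased[pattern] / n_branch
    se = float(np.sqrt(p_hat * (1 - p_hat) / n_branch))
    return p_hat, se


def counts_frame(counts: CohortCounts, stratum_label: str = "simulated") -> pd.DataFrame:
    """Tabulate a cohort next to the analytic branch probabilities/posteriors."""
    cfg = counts.config
    if 0 < cfg.prevalence < 1:
        stratum = PretestStratum(stratum_label, cfg.prevalence)
        analytic = {
            b.pattern: (b.branch_probability, b.final_posterior)
            for b in enumerate_branches(stratum, cfg.tests)
        }
    else:  # degenerate prevalence: no Bayesian stratum, analytic posterior trivial
        analytic = {
            tuple(p): (float("nan"), cfg.prevalence)
            for p in _all_patterns(len(cfg.tests))
        }
    rows = []
    for pattern in _all_patterns(len(cfg.tests)):
        n_branch = counts.branch_total(tuple(pattern))
        if n_branch:
            p_hat, se = empirical_posterior(counts, tuple(pattern))
        else:
            p_hat, se = float("nan"), float("nan")
        rows.append(
            {
                "branch": ",".join("+" if o == "positive" else "-" for o in pattern),
                "diseased": counts.diseased[tuple(pattern)],
                "healthy": counts.healthy[tuple(pattern)],
                "empirical_posterior": p_hat,
                "analytic_posterior": analytic[tuple(pattern)][1],
                "analytic_branch_probability": analytic[tuple(pattern)][0],
                "se": se,
            }
        )
    return pd.DataFrame(rows)
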