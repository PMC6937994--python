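"""CURB-65 scoring, biomarker categorization and the disposition decision tree.

CURB-65 awards one point each for Confusion, BUN > 19 mg/dL, respiratory
rate >= 30/min, low blood pressure (systolic < 90 or diastolic <= 60 mmHg —
a single point even if both limbs are low) and age >= 65.  Scores map to
0-1 outpatient, 2 physician's discretion, 3 intermediate risk and 4-5 high
risk; only the intermediate and high strata carry a pretest probability for
Bayesian chaining.

The disposition ruleset routes each enumerated test branch to a care level
(ICU, StepDown, Observation, Ward, Outpatient).  The default ruleset encodes
the published ICU rule — intermediate CURB-65 with positive procalcitonin and
positive lactate warrants ICU admission — and falls back to configurable
posterior-probability thresholds for every other branch.  The threshold
defaults are this package's own calibration, not published values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .gains import SequentialBranch

__all__ = [
    "Curb65Inputs",
    "BiomarkerReading",
    "DispositionRule",
    "DispositionRuleSet",
    "DEFAULT_BIOMARKER_THRESHOLDS",
    "DISPOSITIONS",
    "curb65_score",
    "classify_biomarker",
    "default_ruleset",
    "assign_disposition",
    "export_tree",
    "TreeDocument",
]

DISPOSITIONS = ("ICU", "StepDown", "Observation", "Ward", "Outpatient")

STRATUM_BY_SCORE = {
    0: "outpatient",
    1: "outpatient",
    2: "discretion",
    3: "intermediate",
    4: "high",
    5: "high",
}


@dataclass(frozen=True)
class Curb65Inputs:
    """The five CURB-65 components plus the vitals they are read from."""

    confusion: bool
    bun: float  # mg/dL
    respiratory_rate: float  # breaths/min
    systolic_bp: float  # mmHg
    diastolic_bp: float  # mmHg
    age: float  # years

    def __post_init__(self) -> None:
        for name in ("bun", "respiratory_rate", "systolic_bp", "diastolic_bp", "age"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def curb65_score(inputs: Curb65Inputs) -> Tuple[int, str]:
    """Score CURB-65 and return (score, stratum label).

    The printed inequalities are applied strictly: BUN strictly greater than
    19 mg/dL scores, BUN exactly 19 does not; diastolic BP exactly 60 and age
    exactly 65 do score.  The blood-pressure criterion counts once even when
    both limbs are satisfied.
    """
    points = (
        int(inputs.confusion)
        + int(inputs.bun > 19)
        + int(inputs.respiratory_rate >= 30)
        + int(inputs.systolic_bp < 90 or inputs.diastolic_bp <= 60)
        + int(inputs.age >= 65)
    )
    return points, STRATUM_BY_SCORE[points]


@dataclass(frozen=True)
class BiomarkerReading:
    name: str
    value: float  # ng/mL for PCT, mmol/L for lactate

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("biomarker value must be non-negative")


# PCT < 0.5 ng/mL negative, > 2.0 positive, [0.5, 2.0] indeterminate;
# lactate > 2 mmol/L positive.  The indeterminate PCT band is kept explicit
# rather than collapsed into either binary outcome.
DEFAULT_BIOMARKER_THRESHOLDS: Dict[str, Dict[str, float]] = {
    "pct": {"negative_below": 0.5, "positive_above": 2.0},
    "lactate": {"positive_above": 2.0},
}


def classify_biomarker(
    reading: BiomarkerReading,
    thresholds: Optional[Dict[str, Dict[str, float]]] = None,
) -> str:
    """Categorize a biomarker value as negative / indeterminate / positive.

    Every non-negative value maps to exactly one outcome.  A biomarker with
    only a ``positive_above`` cut is binary; one with both cuts has an
    explicit indeterminate band between them (closed on both ends).
    """
    table = thresholds if thresholds is not None else DEFAULT_BIOMARKER_THRESHOLDS
    key = reading.name.lower()
    if key not in table:
        raise ValueError(f"unknown biomarker {reading.name!r}; configured: {sorted(table)}")
    cuts = table[key]
    if reading.value > cuts["positive_above"]:
        return "positive"
    if "negative_below" in cuts and reading.value >= cuts["negative_below"]:
        return "indeterminate"
    return "negative"


@dataclass(frozen=True)
class DispositionRule:
    """One first-match-wins rule.

    ``stratum`` is a label or ``"*"``.  ``outcomes`` is a tuple of
    ``"+"``/``"-"``/``"*"`` matched positionally against the branch pattern
    (None matches any pattern of any length).  The posterior interval is
    half-open [min, max) except that max = 1 is inclusive.
    """

    disposition: str
    stratum: str = "*"
    outcomes: Optional[Tuple[str, ...]] = None
    posterior_min: float = 0.0
    posterior_max: float = 1.0

    def __post_init__(self) -> None:
        if self.disposition not in DISPOSITIONS:
            raise ValueError(
                f"disposition must be one of {DISPOSITIONS}, got {self.disposition!r}"
            )
        if not (0 <= self.posterior_min <= self.posterior_max <= 1):
            raise ValueError("posterior interval must satisfy 0 <= min <= max <= 1")
        if self.outcomes is not None:
            for o in self.outcomes:
                if o not in ("+", "-", "*"):
                    raise ValueError(f"outcome pattern symbols are + - *, got {o!r}")

    def matches(self, stratum: str, pattern: Sequence[str], posterior: float) -> bool:
        if self.stratum != "*" and self.stratum != stratum:
            return False
        if self.outcomes is not None:
            if len(self.outcomes) != len(pattern):
                return False
            for sym, outcome in zip(self.outcomes, pattern):
                if sym == "*":
                    continue
                if (sym == "+") != (outcome == "positive"):
                    return False
        if posterior < self.posterior_min:
            return False
        if posterior > self.posterior_max:
            return False
        if posterior == self.posterior_max and self.posterior_max < 1.0:
            # half-open upper bound, except at 1
            return False
        return True

    def to_dict(self) -> dict:
        return {
            "disposition": self.disposition,
            "stratum": self.stratum,
            "outcomes": list(self.outcomes) if self.outcomes is not None else None,
            "posterior_min": self.posterior_min,
            "posterior_max": self.posterior_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DispositionRule":
        return cls(
            disposition=d["disposition"],
            stratum=d.get("stratum", "*"),
            outcomes=tuple(d["outcomes"]) if d.get("outcomes") is not None else None,
            posterior_min=float(d.get("posterior_min", 0.0)),
            posterior_max=float(d.get("posterior_max", 1.0)),
        )


@dataclass(frozen=True)
class DispositionRuleSet:
    """Ordered, total, first-match-wins disposition rules.

    Totality is checked at construction: the fully-wildcarded rules (any
    stratum, any outcome pattern) must cover the whole posterior axis [0, 1],
    so every possible branch matches at least one rule.
    """

    rules: Tuple[DispositionRule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("ruleset must contain at least one rule")
        self._check_total()

    def _check_total(self) -> None:
        intervals = sorted(
            (r.posterior_min, r.posterior_max)
            for r in self.rules
            if r.stratum == "*" and r.outcomes is None
        )
        covered_to = 0.0
        for lo, hi in intervals:
            if lo > covered_to:
                break
            covered_to = max(covered_to, hi)
        if covered_to < 1.0:
            raise ValueError(
                "ruleset is not total: fully-wildcarded rules cover the posterior "
                f"axis only up to {covered_to}; add catch-all threshold rules"
            )

    def match(self, stratum: str, pattern: Sequence[str], posterior: float):
        for i, rule in enumerate(self.rules):
            if rule.matches(stratum, pattern, posterior):
                return i, rule
        raise RuntimeError("total ruleset failed to match — internal error")

    def to_list(self) -> List[dict]:
        return [r.to_dict() for r in self.rules]

    @classmethod
    def from_list(cls, items: Sequence[dict]) -> "DispositionRuleSet":
        return cls(tuple(DispositionRule.from_dict(d) for d in items))


def default_ruleset(
    icu_threshold: float = 0.90,
    stepdown_threshold: float = 0.50,
    observation_threshold: float = 0.15,
) -> DispositionRuleSet:
    """The default disposition rules.

    Rule 1 is the published ICU rule (intermediate stratum, all tests
    positive).  Rules 2-6 are posterior-threshold fallbacks: >= 0.90 ICU,
    [0.50, 0.90) step-down, [0.15, 0.50) observation, < 0.15 ward for the
    admitted (intermediate/high) strata and outpatient otherwise.  The
    thresholds are configurable package defaults, not published values.
    """
    if not (0 < observation_threshold < stepdown_threshold < icu_threshold < 1):
        raise ValueError("thresholds must satisfy 0 < obs < stepdown < icu < 1")
    return DispositionRuleSet(
        (
            DispositionRule("ICU", stratum="intermediate", outcomes=("+", "+")),
            DispositionRule("ICU", posterior_min=icu_threshold, posterior_max=1.0),
            DispositionRule(
                "StepDown", posterior_min=stepdown_threshold, posterior_max=icu_threshold
            ),
            DispositionRule(
                "Observation",
                posterior_min=observation_threshold,
                posterior_max=stepdown_threshold,
            ),
            DispositionRule(
                "Ward", stratum="intermediate", posterior_min=0.0, posterior_max=observation_threshold
            ),
            DispositionRule(
                "Ward", stratum="high", posterior_min=0.0, posterior_max=observation_threshold
            ),
            DispositionRule(
                "Outpatient", posterior_min=0.0, posterior_max=observation_threshold
            ),
        )
    )


@dataclass(frozen=True)
class Assignment:
    disposition: str
    rule_index: int
    rule: DispositionRule
    posterior: float


def assign_disposition(
    stratum_label: str, branch: SequentialBranch, rules: DispositionRuleSet
) -> Assignment:
    """Route one branch through the ruleset; deterministic first match wins."""
    idx, rule = rules.match(stratum_label, branch.pattern, branch.final_posterior)
    return Assignment(
        disposition=rule.disposition,
        rule_index=idx,
        rule=rule,
        posterior=branch.final_posterior,
    )


@dataclass(frozen=True)
class TreeDocument:
    """Structural export of the disposition tree: DOT text and a JSON dict."""

    dot: str
    data: dict

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.data, **kwargs)


def _branch_node_id(pattern: Sequence[str]) -> str:
    return "b_" + "".join("P" if o == "positive" else "N" for o in pattern) or "b_root"


def export_tree(
    rules: DispositionRuleSet, branches: Sequence[SequentialBranch]
) -> TreeDocument:
    """Render the branch set and its dispositions as DOT and JSON documents.

    Internal nodes are the stratum and each test split; leaves carry the
    final posterior (percent) and the assigned disposition.  Node ordering
    follows branch enumeration order, so output is deterministic.  The JSON
    document round-trips: re-importing its rules reproduces identical
    assignments for the same branches.
    """
    if not branches:
        raise ValueError("need at least one branch to export")
    stratum = branches[0].stratum
    test_names = [r.test_name for r in branches[0].results]

    entries = []
    for br in branches:
        a = assign_disposition(stratum.label, br, rules)
        entries.append(
            {
                "pattern": list(br.pattern),
                "posterior": br.final_posterior,
                "branch_probability": br.branch_probability,
                "disposition": a.disposition,
                "rule_index": a.rule_index,
            }
        )

    data = {
        "stratum": stratum.label,
        "pretest": stratum.pretest,
        "tests": test_names,
        "rules": rules.to_list(),
        "branches": entries,
    }

    lines = ["digraph disposition {", "  rankdir=LR;", "  node [shape=box];"]
    root = "stratum"
    lines.append(
        f'  {root} [label="CURB-65 {stratum.label}\\npretest {stratum.pretest * 100:.1f}%"];'
    )
    seen = set()
    for br in branches:
        parent = root
        for depth, outcome in enumerate(br.pattern):
            prefix = br.pattern[: depth + 1]
            node = _branch_node_id(prefix)
            sign = "+" if outcome == "positive" else "−"
            if node not in seen:
                seen.add(node)
                if depth == len(br.pattern) - 1:
                    entry = next(
                        e for e in entries if tuple(e["pattern"]) == tuple(br.pattern)
                    )
                    label = (
                        f"{test_names[depth]} {sign}\\n"
                        f"posterior {entry['posterior'] * 100:.0f}%\\n{entry['disposition']}"
                    )
                else:
                    label = f"{test_names[depth]} {sign}"
                lines.append(f'  {node} [label="{label}"];')
                lines.append(f"  {parent} -> {node};")
            parent = node
    if not test_names:  # empty panel: single leaf under the stratum
        entry = entries[0]
        lines.append(
            f'  leaf [label="posterior {entry["posterior"] * 100:.0f}%\\n{entry["disposition"]}"];'
        )
        lines.append(f"  {root} -> leaf;")
    lines.append("}")
    return TreeDocument(dot="\n".join(lines) + "\n", data=data)
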