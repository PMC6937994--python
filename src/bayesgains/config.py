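"""Study configuration: schema-validated YAML/JSON loading and dumping.

Probabilities in configuration files are *percentages*, matching clinical
presentation; they are converted to proportions at this boundary and nowhere
else.  Validation errors name the offending field path
(e.g. ``tests[1].sensitivity_pct``).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import yaml

from .bayes import TestAccuracy
from .clinical import DispositionRuleSet, default_ruleset
from .gains import ROUNDING_POLICIES, PretestStratum

__all__ = ["ConfigError", "StudyConfig", "load_config", "loads_config", "dump_config"]


class ConfigError(ValueError):
    """Raised for a missing, malformed or out-of-range configuration field."""


def _require(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise ConfigError(f"{path}.{key}: required field is missing")
    return mapping[key]


def _pct(value, path: str, lo: float = 0.0, hi: float = 100.0, open_ends: bool = False) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{path}: expected a number, got {value!r}") from None
    ok = lo < v < hi if open_ends else lo <= v <= hi
    if not ok:
        bounds = f"({lo}, {hi})" if open_ends else f"[{lo}, {hi}]"
        raise ConfigError(f"{path}: percentage {v} outside {bounds}")
    return v / 100.0


@dataclass(frozen=True)
class StudyConfig:
    """A fully validated study: tests, strata, test sequence and policies.

    ``printed_lrs`` maps a test name to externally published (LR+, LR-)
    values used verbatim for table reproduction; recomputed LRs from
    sensitivity/specificity are always available via
    :func:`bayesgains.bayes.lr_from_accuracy`.
    """

    tests: Tuple[TestAccuracy, ...]
    strata: Tuple[PretestStratum, ...]
    sequence: Tuple[str, ...]
    rounding_policy: str = "nomogram"
    printed_lrs: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    dispositions: DispositionRuleSet = field(default_factory=default_ruleset)

    def __post_init__(self) -> None:
        names = {t.name for t in self.tests}
        for n in self.sequence:
            if n not in names:
                raise ConfigError(f"sequence: test name {n!r} does not resolve to a configured test")
        for n in self.printed_lrs:
            if n not in names:
                raise ConfigError(f"printed_lrs: unknown test name {n!r}")
        if self.rounding_policy not in ROUNDING_POLICIES:
            raise ConfigError(
                f"rounding_policy: {self.rounding_policy!r} not one of {ROUNDING_POLICIES}"
            )

    def test(self, name: str) -> TestAccuracy:
        for t in self.tests:
            if t.name == name:
                return t
        raise KeyError(name)

    def stratum(self, label: str) -> PretestStratum:
        for s in self.strata:
            if s.label == label:
                return s
        raise KeyError(label)

    def lr_pair(self, name: str, printed: bool = True) -> Tuple[float, float]:
        """(LR+, LR-) for a test; printed values take precedence when present."""
        if printed and name in self.printed_lrs:
            return self.printed_lrs[name]
        from .bayes import lr_from_accuracy

        lrs = lr_from_accuracy(self.test(name))
        return (lrs.lr_positive, lrs.lr_negative)

    def to_mapping(self) -> dict:
        """Plain-dict form that round-trips through :func:`loads_config`."""
        return {
            "tests": [
                {
                    "name": t.name,
                    "sensitivity_pct": t.sensitivity * 100,
                    "specificity_pct": t.specificity * 100,
                    **(
                        {"sensitivity_ci_pct": [t.sens_ci[0] * 100, t.sens_ci[1] * 100]}
                        if t.sens_ci
                        else {}
                    ),
                    **(
                        {"specificity_ci_pct": [t.spec_ci[0] * 100, t.spec_ci[1] * 100]}
                        if t.spec_ci
                        else {}
                    ),
                    **(
                        {"positivity": t.positivity_definition}
                        if t.positivity_definition
                        else {}
                    ),
                    **(
                        {
                            "printed_lr_positive": self.printed_lrs[t.name][0],
                            "printed_lr_negative": self.printed_lrs[t.name][1],
                        }
                        if t.name in self.printed_lrs
                        else {}
                    ),
                }
                for t in self.tests
            ],
            "strata": [
                {"label": s.label, "pretest_pct": s.pretest * 100, "source": s.source}
                for s in self.strata
            ],
            "sequence": list(self.sequence),
            "rounding_policy": self.rounding_policy,
            "dispositions": self.dispositions.to_list(),
        }

    def content_hash(self) -> str:
        """Stable sha256 of the canonical config mapping, for output provenance."""
        canon = json.dumps(self.to_mapping(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _parse_ci(entry: dict, key: str, path: str) -> Optional[Tuple[float, float]]:
    if key not in entry:
        return None
    raw = entry[key]
    if not (isinstance(raw, (list, tuple)) and len(raw) == 2):
        raise ConfigError(f"{path}.{key}: expected [low, high] percentages")
    return (_pct(raw[0], f"{path}.{key}[0]"), _pct(raw[1], f"{path}.{key}[1]"))


def loads_config(mapping: dict) -> StudyConfig:
    """Validate a plain mapping (parsed YAML/JSON) into a StudyConfig."""
    if not isinstance(mapping, dict):
        raise ConfigError("config root must be a mapping")

    tests: List[TestAccuracy] = []
    printed: Dict[str, Tuple[float, float]] = {}
    for i, entry in enumerate(_require(mapping, "tests", "config")):
        path = f"tests[{i}]"
        name = _require(entry, "name", path)
        try:
            acc = TestAccuracy(
                name=name,
                sensitivity=_pct(_require(entry, "sensitivity_pct", path), f"{path}.sensitivity_pct", open_ends=False),
                specificity=_pct(_require(entry, "specificity_pct", path), f"{path}.specificity_pct", open_ends=False),
                sens_ci=_parse_ci(entry, "sensitivity_ci_pct", path),
                spec_ci=_parse_ci(entry, "specificity_ci_pct", path),
                positivity_definition=entry.get("positivity", ""),
            )
        except ValueError as e:
            raise ConfigError(f"{path}: {e}") from None
        tests.append(acc)
        if "printed_lr_positive" in entry or "printed_lr_negative" in entry:
            try:
                printed[name] = (
                    float(_require(entry, "printed_lr_positive", path)),
                    float(_require(entry, "printed_lr_negative", path)),
                )
            except (TypeError, ValueError):
                raise ConfigError(f"{path}: printed LRs must be numbers") from None

    strata: List[PretestStratum] = []
    for i, entry in enumerate(_require(mapping, "strata", "config")):
        path = f"strata[{i}]"
        try:
            strata.append(
                PretestStratum(
                    label=_require(entry, "label", path),
                    pretest=_pct(_require(entry, "pretest_pct", path), f"{path}.pretest_pct", open_ends=True),
                    source=entry.get("source", ""),
                )
            )
        except ValueError as e:
            if isinstance(e, ConfigError):
                raise
            raise ConfigError(f"{path}: {e}") from None

    if "rounding_policy" not in mapping:
        policy = "nomogram"  # default logged by callers
    else:
        policy = mapping["rounding_policy"]

    dispo_raw = mapping.get("dispositions", "default")
    if dispo_raw == "default":
        dispositions = default_ruleset()
    else:
        try:
            dispositions = DispositionRuleSet.from_list(dispo_raw)
        except (ValueError, KeyError, TypeError) as e:
            raise ConfigError(f"dispositions: {e}") from None

    return StudyConfig(
        tests=tuple(tests),
        strata=tuple(strata),
        sequence=tuple(mapping.get("sequence", [])),
        rounding_policy=policy,
        printed_lrs=printed,
        dispositions=dispositions,
    )


def load_config(path: Union[str, Path]) -> StudyConfig:
    """Load and validate a YAML (or JSON — a YAML subset) config file."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        mapping = yaml.safe_load(p.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"{p}: not valid YAML/JSON: {e}") from None
    return loads_config(mapping)


def dump_config(config: StudyConfig, path: Union[str, Path]) -> None:
    """Write a config back to YAML; load(dump(c)) == c."""
    Path(path).write_text(yaml.safe_dump(config.to_mapping(), sort_keys=True))
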