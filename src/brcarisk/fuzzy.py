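"""Mamdani fuzzy inference over the encoded risk factors.

The engine follows the classical five-step pipeline: fuzzify the crisp
inputs, evaluate each rule's antecedents, combine them with the AND
(minimum) operator, clip each rule's consequent membership function at
the rule's firing strength (minimum implication), aggregate the clipped
sets pointwise by maximum, and defuzzify the aggregate by its centroid
on a uniform grid over the [0, 1] output axis.

Missing inputs are handled by skipping the corresponding antecedent
clause — the clause is treated as fully satisfied — which is the only
mechanism that lets records with "Unknown" fields produce a score
without imputing values or altering the rule base.  If no rule fires at
all the aggregated set has zero mass and the score is reported as an
explicit error (:class:`UndefinedScoreError`) rather than a fabricated
midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .datamodel import (
    CLASS_LABELS,
    EncodedRecord,
    FactorDefinition,
    MembershipFunctionSpec,
    PatientRecord,
    encode_record,
)

__all__ = [
    "Rule",
    "RuleBase",
    "FuzzySet",
    "RiskScore",
    "UndefinedScoreError",
    "membership",
    "rule_strength",
    "aggregate",
    "aggregate_from_strengths",
    "defuzzify_centroid",
    "infer",
]

DEFAULT_RESOLUTION = 1001


class UndefinedScoreError(ValueError):
    """No rule fired: the aggregated output set has zero mass."""


@dataclass(frozen=True)
class Rule:
    """An if-then rule: AND-combined antecedent clauses and one
    consequent ACMG class.

    ``antecedents`` maps factor names to category labels; factors absent
    from the map are unconstrained.  ``provenance`` records the training
    patient the rule was built from.
    """

    antecedents: Mapping[str, str]
    consequent: str
    provenance: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.antecedents:
            raise ValueError("a rule needs at least one antecedent clause")
        if self.consequent not in CLASS_LABELS:
            raise ValueError(f"unknown consequent class {self.consequent!r}")


@dataclass(frozen=True)
class RuleBase:
    """An ordered collection of rules.

    Aggregation is pointwise maximum, so evaluation is independent of
    rule order; the order is kept only for provenance.
    """

    rules: tuple[Rule, ...]

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


@dataclass(frozen=True)
class FuzzySet:
    """A membership curve sampled on a uniform grid over [0, 1]."""

    grid: np.ndarray
    mu: np.ndarray
    fired_rule_count: int = 0
    max_strength: float = 0.0

    def __post_init__(self) -> None:
        if self.grid.shape != self.mu.shape:
            raise ValueError("grid and mu must have identical shape")
        if self.mu.size and (self.mu.min() < 0 or self.mu.max() > 1):
            raise ValueError("membership degrees must lie in [0, 1]")

    @property
    def resolution(self) -> int:
        return self.grid.size


@dataclass(frozen=True)
class RiskScore:
    """A defuzzified risk score with firing diagnostics."""

    value: float
    fired_rule_count: int
    max_strength: float
    record_id: Optional[str] = None


def membership(mf: MembershipFunctionSpec, x: float) -> float:
    """Degree of membership of ``x`` in ``mf`` (piecewise linear).

    Triangles and edge shoulders share one closed form on the clipped
    [0, 1] domain: ``max(0, 1 - |x - center| / half_width)``.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"membership argument {x} outside [0, 1]")
    return max(0.0, 1.0 - abs(x - mf.center) / mf.half_width)


def _factor_index(catalogue: Sequence[FactorDefinition]) -> dict[str, int]:
    return {f.name: i for i, f in enumerate(catalogue)}


def rule_strength(
    rule: Rule,
    encoded: EncodedRecord,
    catalogue: Sequence[FactorDefinition],
) -> float:
    """Firing strength of a rule: minimum antecedent degree.

    Clauses whose input entry is missing are skipped (fully satisfied);
    a rule whose clauses are all skipped fires at strength 1.
    """
    index = _factor_index(catalogue)
    strength = 1.0
    for name, label in rule.antecedents.items():
        if name not in index:
            raise KeyError(f"rule references unknown factor {name!r}")
        i = index[name]
        if not encoded.mask[i]:
            continue
        mf = catalogue[i].mf_by_label(label)
        degree = membership(mf, float(encoded.values[i]))
        if degree < strength:
            strength = degree
        if strength == 0.0:
            return 0.0
    return strength


def _output_mfs(
    catalogue: Sequence[FactorDefinition],
) -> dict[str, MembershipFunctionSpec]:
    for factor in catalogue:
        if factor.name == "classification":
            return {mf.label: mf for mf in factor.mfs}
    raise KeyError("catalogue has no classification factor")


def aggregate_from_strengths(
    class_strengths: Mapping[str, float],
    catalogue: Sequence[FactorDefinition],
    resolution: int = DEFAULT_RESOLUTION,
) -> FuzzySet:
    """Clip each output-class membership function at its strength and
    combine pointwise by maximum."""
    if resolution < 101:
        raise ValueError("resolution must be at least 101")
    out_mfs = _output_mfs(catalogue)
    grid = np.linspace(0.0, 1.0, resolution)
    mu = np.zeros(resolution)
    fired = 0
    max_strength = 0.0
    for label, s in class_strengths.items():
        if label not in out_mfs:
            raise KeyError(f"unknown output class {label!r}")
        if s <= 0.0:
            continue
        fired += 1
        max_strength = max(max_strength, s)
        mf = out_mfs[label]
        curve = np.maximum(0.0, 1.0 - np.abs(grid - mf.center) / mf.half_width)
        np.maximum(mu, np.minimum(curve, s), out=mu)
    return FuzzySet(grid=grid, mu=mu, fired_rule_count=fired,
                    max_strength=max_strength)


def aggregate(
    rulebase: RuleBase,
    encoded: EncodedRecord,
    catalogue: Sequence[FactorDefinition],
    resolution: int = DEFAULT_RESOLUTION,
) -> FuzzySet:
    """Fire every rule against ``encoded`` and aggregate the clipped
    consequent sets by maximum."""
    if len(rulebase) == 0:
        raise ValueError("empty rule base")
    # max is idempotent and associative, so rules sharing a consequent
    # collapse to the strongest strength per output class.
    class_strengths: dict[str, float] = {}
    fired = 0
    for rule in rulebase:
        s = rule_strength(rule, encoded, catalogue)
        if s > 0.0:
            fired += 1
        prev = class_strengths.get(rule.consequent, 0.0)
        if s > prev:
            class_strengths[rule.consequent] = s
    fs = aggregate_from_strengths(class_strengths, catalogue, resolution)
    return FuzzySet(grid=fs.grid, mu=fs.mu, fired_rule_count=fired,
                    max_strength=fs.max_strength)


def defuzzify_centroid(fuzzy_set: FuzzySet) -> float:
    """Center of mass of the aggregated set on its sampling grid."""
    total = float(fuzzy_set.mu.sum())
    if total <= 0.0:
        raise UndefinedScoreError("zero-mass fuzzy set: no rule fired")
    return float((fuzzy_set.grid * fuzzy_set.mu).sum() / total)


def infer(
    rulebase: RuleBase,
    record: PatientRecord,
    catalogue: Sequence[FactorDefinition],
    resolution: int = DEFAULT_RESOLUTION,
) -> RiskScore:
    """Full pipeline: encode, fire rules, aggregate, defuzzify."""
    encoded = encode_record(record, catalogue)
    fs = aggregate(rulebase, encoded, catalogue, resolution)
    try:
        value = defuzzify_centroid(fs)
    except UndefinedScoreError as err:
        rid = record.record_id or "<unnamed record>"
        raise UndefinedScoreError(f"{rid}: {err}") from None
    return RiskScore(
        value=value,
        fired_rule_count=fs.fired_rule_count,
        max_strength=fs.max_strength,
        record_id=record.record_id,
    )
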