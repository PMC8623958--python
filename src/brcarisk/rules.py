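"""Rule-base construction: one if-then rule per training patient.

Every labelled patient contributes exactly one rule whose antecedents
name, for each non-missing factor, the membership function its encoded
value falls on, and whose consequent is the patient's recorded ACMG
class.  No deduplication or merging is performed — a cohort of N
patients always yields N rules — and missing fields simply drop their
clause, mirroring the engine's missing-input handling.

By default the variant-classification factor contributes an antecedent
clause like any other input cluster; ``include_classification=False``
builds a non-circular rule base from the 15 clinical factors only.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

from .datamodel import FactorDefinition, PatientRecord
from .fuzzy import Rule, RuleBase

__all__ = ["build_rule", "build_rulebase", "save_rulebase", "load_rulebase"]


def build_rule(
    patient: PatientRecord,
    catalogue: Sequence[FactorDefinition],
    include_classification: bool = True,
) -> Rule:
    """Turn one labelled patient into an if-then rule."""
    if patient.class_label is None:
        raise ValueError(
            f"patient {patient.record_id or '<unnamed>'} has no class label; "
            "cannot form a consequent"
        )
    antecedents: dict[str, str] = {}
    for factor in catalogue:
        if factor.name == "classification" and not include_classification:
            continue
        raw = patient.values.get(factor.name)
        if raw is None:
            continue
        antecedents[factor.name] = factor.mf_for_raw(raw).label
    return Rule(
        antecedents=antecedents,
        consequent=patient.class_label,
        provenance=patient.record_id,
    )


def build_rulebase(
    cohort: Sequence[PatientRecord],
    catalogue: Sequence[FactorDefinition],
    include_classification: bool = True,
) -> RuleBase:
    """One rule per patient, in cohort order; |rules| == |cohort|."""
    if not cohort:
        raise ValueError("cannot build a rule base from an empty cohort")
    rules = []
    for i, patient in enumerate(cohort):
        try:
            rules.append(build_rule(patient, catalogue, include_classification))
        except ValueError as err:
            raise ValueError(f"patient index {i}: {err}") from None
    return RuleBase(rules=tuple(rules))


def save_rulebase(path: Union[str, Path], rulebase: RuleBase) -> None:
    """Write a rule base to a human-readable JSON rules file."""
    payload = {
        "format": "brcarisk-rules-v1",
        "rules": [
            {
                "if": dict(rule.antecedents),
                "then": rule.consequent,
                "provenance": rule.provenance,
            }
            for rule in rulebase
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_rulebase(path: Union[str, Path]) -> RuleBase:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "brcarisk-rules-v1":
        raise ValueError(f"{path}: not a brcarisk rules file")
    rules = tuple(
        Rule(
            antecedents=entry["if"],
            consequent=entry["then"],
            provenance=entry.get("provenance"),
        )
        for entry in payload["rules"]
    )
    return RuleBase(rules=rules)
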