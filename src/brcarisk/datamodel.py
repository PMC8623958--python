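"""Domain types and the 16-factor risk catalogue.

The risk model scores breast-cancer patients on sixteen clinical and
genetic factors: age, sex, consanguinity, family history, number of
affected family members, tumour size, lymph-node involvement, degree of
malignancy (grade), tumour position, oestrogen- and
progesterone-receptor status, BRCA1/BRCA2/other-gene variant status,
diagnosis, and the ACMG variant classification.  Each factor is
partitioned into linguistic categories (membership functions) whose
representative values lie on a common [0, 1] axis; the full catalogue
contains 43 membership functions.

Raw observations (age in years, tumour size in cm, category labels) are
encoded onto that axis: continuous factors are binned and represented by
the bin's value, categorical factors map directly to their category's
value.  ``"Unknown"`` is a first-class missing marker and is never
imputed here — each inference engine decides its own handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

__all__ = [
    "CLASS_LABELS",
    "CLASS_VALUES",
    "FACTOR_NAMES",
    "MembershipFunctionSpec",
    "FactorDefinition",
    "PatientRecord",
    "EncodedRecord",
    "FactorValueError",
    "build_catalogue",
    "encode_record",
    "decode_value",
]

#: The five ACMG variant classes, ordered from benign to pathogenic.
CLASS_LABELS: tuple[str, ...] = (
    "Benign",
    "Likely Benign",
    "VUS",
    "Likely Pathogenic",
    "Pathogenic",
)

#: Output-axis value of each ACMG class.
CLASS_VALUES: dict[str, float] = {
    "Benign": 0.0,
    "Likely Benign": 0.25,
    "VUS": 0.5,
    "Likely Pathogenic": 0.75,
    "Pathogenic": 1.0,
}


class FactorValueError(ValueError):
    """Raised when a raw observation cannot be encoded for its factor."""


@dataclass(frozen=True)
class MembershipFunctionSpec:
    """One linguistic category of a risk factor.

    The membership curve is piecewise linear on the encoded [0, 1] axis:
    degree 1 at ``center``, falling linearly to 0 at distance
    ``half_width``.  Categories whose center sits on a domain edge are
    shoulders (trapezoidal after clipping to [0, 1]); interior
    categories are triangles.
    """

    label: str
    center: float
    half_width: float
    shape: str = "triangular"  # "triangular" | "trapezoidal"
    shoulder: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.center <= 1.0:
            raise ValueError(f"MF center {self.center} outside [0, 1]")
        if self.half_width <= 0:
            raise ValueError("MF half_width must be positive")
        if self.shape not in ("triangular", "trapezoidal"):
            raise ValueError(f"unknown MF shape {self.shape!r}")


@dataclass(frozen=True)
class FactorDefinition:
    """A risk factor with its ordered membership-function set.

    ``kind`` is ``"categorical"`` (raw value is a category label) or
    ``"binned"`` (raw value is a number binned by ``bin_edges`` before
    encoding; edges are half-open ``[e[i], e[i+1])`` in raw units).
    """

    name: str
    kind: str
    mfs: tuple[MembershipFunctionSpec, ...]
    bin_edges: Optional[tuple[float, ...]] = None
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        centers = [mf.center for mf in self.mfs]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError(f"{self.name}: MF centers must be strictly increasing")
        if self.kind == "binned" and (
            self.bin_edges is None or len(self.bin_edges) != len(self.mfs) + 1
        ):
            raise ValueError(f"{self.name}: need one bin per membership function")

    def mf_by_label(self, label: str) -> MembershipFunctionSpec:
        key = _norm(label)
        canon = self.aliases.get(key)
        for mf in self.mfs:
            if _norm(mf.label) == key or mf.label == canon:
                return mf
        raise FactorValueError(f"factor {self.name!r}: unknown category {label!r}")

    def mf_for_raw(self, raw: Union[str, float, int]) -> MembershipFunctionSpec:
        """Resolve a raw observation to its membership function."""
        if self.kind == "categorical":
            if not isinstance(raw, str):
                raise FactorValueError(
                    f"factor {self.name!r}: expected a category label, got {raw!r}"
                )
            return self.mf_by_label(raw)
        try:
            x = float(raw)
        except (TypeError, ValueError):
            raise FactorValueError(
                f"factor {self.name!r}: expected a number, got {raw!r}"
            ) from None
        if not math.isfinite(x) or x < 0:
            raise FactorValueError(f"factor {self.name!r}: invalid value {raw!r}")
        assert self.bin_edges is not None
        for i, mf in enumerate(self.mfs):
            if self.bin_edges[i] <= x < self.bin_edges[i + 1]:
                return mf
        raise FactorValueError(f"factor {self.name!r}: value {raw!r} outside all bins")

    def mf_at_center(self, value: float) -> MembershipFunctionSpec:
        for mf in self.mfs:
            if abs(mf.center - value) < 1e-12:
                return mf
        raise FactorValueError(
            f"factor {self.name!r}: no membership function centered at {value}"
        )


def _norm(label: str) -> str:
    return " ".join(label.strip().lower().split())


def _factor(
    name: str,
    kind: str,
    labels: Sequence[str],
    centers: Sequence[float],
    bin_edges: Optional[Sequence[float]] = None,
    aliases: Optional[Mapping[str, Sequence[str]]] = None,
) -> FactorDefinition:
    # half-width = distance to the nearest neighbouring center, so each
    # category has degree 1 at its own value and 0 at its neighbours'.
    widths = []
    for i, c in enumerate(centers):
        gaps = []
        if i > 0:
            gaps.append(c - centers[i - 1])
        if i + 1 < len(centers):
            gaps.append(centers[i + 1] - c)
        widths.append(min(gaps))
    alias_map: dict[str, str] = {}
    if aliases:
        for canon, alts in aliases.items():
            for alt in alts:
                alias_map[_norm(alt)] = canon
    mfs = tuple(
        MembershipFunctionSpec(
            label=lab,
            center=c,
            half_width=w,
            shape="trapezoidal" if c in (0.0, 1.0) else "triangular",
            shoulder=c in (0.0, 1.0),
        )
        for lab, c, w in zip(labels, centers, widths)
    )
    return FactorDefinition(
        name=name,
        kind=kind,
        mfs=mfs,
        bin_edges=tuple(bin_edges) if bin_edges is not None else None,
        aliases=alias_map,
    )


_NEG_POS_ALIASES = {"Negative": ("no", "neg", "-"), "Positive": ("yes", "pos", "+")}
_NO_YES_ALIASES = {"No": ("negative", "-"), "Yes": ("positive", "+")}

_INF = float("inf")


def build_catalogue() -> tuple[FactorDefinition, ...]:
    """Build the 16-factor catalogue (43 membership functions in total).

    Factor order and category values follow the published input-cluster
    table; age and tumour size are binned from raw units (years, cm).
    """
    return (
        _factor(
            "age",
            "binned",
            ("<15", "15-19", "20-39", "40-59", ">=60"),
            (0.0, 0.25, 0.5, 0.75, 1.0),
            bin_edges=(0, 15, 20, 40, 60, _INF),
        ),
        _factor("sex", "categorical", ("Male", "Female"), (0.0, 1.0),
                aliases={"Male": ("m",), "Female": ("f",)}),
        _factor("consanguinity", "categorical", ("No", "Yes"), (0.0, 1.0),
                aliases=_NO_YES_ALIASES),
        _factor("family_history", "categorical", ("No", "Yes"), (0.0, 1.0),
                aliases=_NO_YES_ALIASES),
        _factor(
            "n_affected_family",
            "binned",
            ("0", "1-2", ">=3"),
            (0.0, 0.5, 1.0),
            bin_edges=(0, 1, 3, _INF),
        ),
        _factor(
            "tumour_size_cm",
            "binned",
            ("0-19", "20-39", ">=40"),
            (0.0, 0.5, 1.0),
            bin_edges=(0, 20, 40, _INF),
        ),
        _factor("lymph_node", "categorical", ("Negative", "Positive"), (0.0, 1.0),
                aliases=_NEG_POS_ALIASES),
        _factor(
            "grade",
            "categorical",
            ("Grade 1", "Grade 2", "Grade 3"),
            (0.0, 0.5, 1.0),
            aliases={"Grade 1": ("1", "g1"), "Grade 2": ("2", "g2"),
                     "Grade 3": ("3", "g3")},
        ),
        _factor(
            "position",
            "categorical",
            ("Other", "Right Breast", "Left Breast", "Both Breast"),
            (0.25, 0.5, 0.75, 1.0),
            aliases={"Right Breast": ("right",), "Left Breast": ("left",),
                     "Both Breast": ("both", "both breasts", "bilateral")},
        ),
        _factor("estrogen_receptor", "categorical", ("Negative", "Positive"),
                (0.0, 1.0), aliases=_NEG_POS_ALIASES),
        _factor("progesterone", "categorical", ("Negative", "Positive"),
                (0.0, 1.0), aliases=_NEG_POS_ALIASES),
        _factor("brca1", "categorical", ("Negative", "Positive"), (0.0, 1.0),
                aliases=_NEG_POS_ALIASES),
        _factor("brca2", "categorical", ("Negative", "Positive"), (0.0, 1.0),
                aliases=_NEG_POS_ALIASES),
        _factor("other_genes", "categorical", ("Negative", "Positive"), (0.0, 1.0),
                aliases=_NEG_POS_ALIASES),
        _factor("diagnosis", "categorical", ("No", "Yes"), (0.0, 1.0),
                aliases=_NO_YES_ALIASES),
        _factor(
            "classification",
            "categorical",
            CLASS_LABELS,
            (0.0, 0.25, 0.5, 0.75, 1.0),
            aliases={"Likely Benign": ("likely_benign",),
                     "Likely Pathogenic": ("likely_pathogenic",),
                     "VUS": ("variant of unknown significance", "vus*")},
        ),
    )


#: Canonical factor order (classification last).
FACTOR_NAMES: tuple[str, ...] = tuple(f.name for f in build_catalogue())


@dataclass
class PatientRecord:
    """One patient's raw 16-factor observation.

    ``values`` maps every factor name to a raw observation (number for
    binned factors, label for categorical ones) or ``None`` for
    missing/"Unknown".  ``class_label`` is the recorded ACMG class of the
    patient's variant (the supervision target); the ``classification``
    entry of ``values`` is the same quantity in its role as an input
    factor.
    """

    values: dict[str, Union[str, float, None]]
    class_label: Optional[str] = None
    record_id: Optional[str] = None

    @classmethod
    def from_values(
        cls,
        class_label: Optional[str] = None,
        record_id: Optional[str] = None,
        **values: Union[str, float, None],
    ) -> "PatientRecord":
        full: dict[str, Union[str, float, None]] = {n: None for n in FACTOR_NAMES}
        for name, raw in values.items():
            if name not in full:
                raise FactorValueError(f"unknown factor {name!r}")
            full[name] = raw
        if class_label is not None and full["classification"] is None:
            full["classification"] = class_label
        return cls(values=full, class_label=class_label, record_id=record_id)

    def n_missing(self) -> int:
        return sum(1 for v in self.values.values() if v is None)


@dataclass(frozen=True)
class EncodedRecord:
    """A patient encoded onto the [0, 1] factor axes.

    ``values[i]`` is the membership-function center of factor ``i``'s
    observed category (0.0 placeholder where missing); ``mask[i]`` is
    True where the observation is present.
    """

    values: np.ndarray
    mask: np.ndarray
    class_value: Optional[float] = None
    record_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have identical shape")


def encode_record(
    record: PatientRecord, catalogue: Sequence[FactorDefinition]
) -> EncodedRecord:
    """Encode raw observations onto the catalogue's [0, 1] axes.

    Present entries become the center of exactly one membership function
    of their factor; missing entries are masked out.  Unknown category
    labels and negative/non-finite numbers are rejected with the
    offending factor named.
    """
    n = len(catalogue)
    values = np.zeros(n)
    mask = np.zeros(n, dtype=bool)
    for i, factor in enumerate(catalogue):
        raw = record.values.get(factor.name)
        if raw is None or (isinstance(raw, float) and math.isnan(raw)):
            continue
        mf = factor.mf_for_raw(raw)
        values[i] = mf.center
        mask[i] = True
    class_value = None
    if record.class_label is not None:
        if record.class_label not in CLASS_VALUES:
            raise FactorValueError(
                f"unknown variant class {record.class_label!r}"
            )
        class_value = CLASS_VALUES[record.class_label]
    return EncodedRecord(
        values=values, mask=mask, class_value=class_value,
        record_id=record.record_id,
    )


def decode_value(factor: FactorDefinition, value: float) -> str:
    """Return the category label whose membership function is centered
    at ``value`` (inverse of categorical encoding)."""
    return factor.mf_at_center(value).label


def catalogue_to_dict(catalogue: Sequence[FactorDefinition]) -> dict:
    """Serializable view of a catalogue (geometry included), so the
    membership widths and bin edges can be overridden from a config
    file without code changes."""
    return {
        "format": "brcarisk-catalogue-v1",
        "factors": [
            {
                "name": f.name,
                "kind": f.kind,
                "bin_edges": list(f.bin_edges) if f.bin_edges else None,
                "mfs": [
                    {
                        "label": mf.label,
                        "center": mf.center,
                        "half_width": mf.half_width,
                        "shape": mf.shape,
                        "shoulder": mf.shoulder,
                    }
                    for mf in f.mfs
                ],
            }
            for f in catalogue
        ],
    }


def catalogue_from_dict(payload: Mapping) -> tuple[FactorDefinition, ...]:
    if payload.get("format") != "brcarisk-catalogue-v1":
        raise ValueError("not a brcarisk catalogue config")
    base = {f.name: f for f in build_catalogue()}
    factors = []
    for spec in payload["factors"]:
        mfs = tuple(
            MembershipFunctionSpec(
                label=m["label"],
                center=float(m["center"]),
                half_width=float(m["half_width"]),
                shape=m.get("shape", "triangular"),
                shoulder=bool(m.get("shoulder", False)),
            )
            for m in spec["mfs"]
        )
        edges = spec.get("bin_edges")
        aliases = base[spec["name"]].aliases if spec["name"] in base else {}
        factors.append(
            FactorDefinition(
                name=spec["name"],
                kind=spec["kind"],
                mfs=mfs,
                bin_edges=tuple(edges) if edges else None,
                aliases=aliases,
            )
        )
    return tuple(factors)


def save_catalogue(path, catalogue: Sequence[FactorDefinition]) -> None:
    """Write a catalogue config (YAML by suffix, JSON otherwise)."""
    import json
    from pathlib import Path

    payload = catalogue_to_dict(catalogue)
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=1) + "\n")


def load_catalogue(path) -> tuple[FactorDefinition, ...]:
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        import yaml

        payload = yaml.safe_load(path.read_text())
    else:
        payload = json.loads(path.read_text())
    return catalogue_from_dict(payload)
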