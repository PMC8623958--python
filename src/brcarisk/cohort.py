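"""Synthetic patient-cohort generator.

The generator emits labelled cohorts with the study population's exact
composition: 268 patients, variant-gene census 61 BRCA1 / 128 BRCA2 /
11 both / 68 other genes, ACMG-class census 87 pathogenic / 23 likely
pathogenic / 128 VUS / 29 likely benign / 1 benign, and 22 male
patients.  Censuses are drawn as exact pools (sampling without
replacement), never as independent draws, so they hold for every seed.

Clinical factor values are synthetic.  Each class is populated from two
sources:

* a small library of **carrier archetypes** — full clinical profiles
  modelled on the recurrent germline variants carried by the packaged
  test subjects.  Real hereditary-cancer cohorts contain families and
  recurrent founder variants, so several training patients sharing a
  carrier profile is the realistic structure, and it gives the test
  harness informative same-class neighbours; and
* class-conditional background draws, biased so higher-risk classes
  skew toward family-history-positive, node-positive, grade-3 profiles.

Gene census groups are defined by the (BRCA1, BRCA2) status pattern;
the other-genes flag may additionally be positive inside a BRCA group
(a secondary finding), which is how profiles like "BRCA1 positive with
an other-gene variant" arise.

A per-factor missingness rate (default 10%) masks clinical fields with
the "Unknown" marker; the class label (and hence the classification
input) is never masked in generated training data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .datamodel import CLASS_LABELS, PatientRecord

__all__ = [
    "CohortConfig",
    "default_config",
    "config_from_dict",
    "generate_cohort",
    "ARCHETYPES",
    "BACKGROUND_DISTRIBUTIONS",
]

#: Gene census groups, keyed by (brca1, brca2) status pattern.
GENE_GROUPS = ("brca1", "brca2", "both", "other")
_GROUP_PATTERN = {
    "brca1": ("Positive", "Negative"),
    "brca2": ("Negative", "Positive"),
    "both": ("Positive", "Positive"),
    "other": ("Negative", "Negative"),
}

_CLINICAL_FACTORS = (
    "age",
    "sex",
    "consanguinity",
    "family_history",
    "n_affected_family",
    "tumour_size_cm",
    "lymph_node",
    "grade",
    "position",
    "estrogen_receptor",
    "progesterone",
    "diagnosis",
)

#: Class-conditional category probabilities for background patients.
#: Ordered per factor as in the catalogue; binned factors are sampled
#: as a bin first, then a raw value uniformly inside the bin.
BACKGROUND_DISTRIBUTIONS: dict[str, dict[str, tuple[float, ...]]] = {
    "Pathogenic": {
        "age": (0.01, 0.04, 0.40, 0.40, 0.15),
        "consanguinity": (0.70, 0.30),
        "family_history": (0.25, 0.75),
        "n_affected_family": (0.25, 0.50, 0.25),
        "tumour_size_cm": (0.60, 0.30, 0.10),
        "lymph_node": (0.35, 0.65),
        "grade": (0.10, 0.35, 0.55),
        "position": (0.05, 0.45, 0.42, 0.08),
        "estrogen_receptor": (0.55, 0.45),
        "progesterone": (0.55, 0.45),
        "diagnosis": (0.05, 0.95),
    },
    "Likely Pathogenic": {
        "age": (0.01, 0.04, 0.40, 0.40, 0.15),
        "consanguinity": (0.70, 0.30),
        "family_history": (0.30, 0.70),
        "n_affected_family": (0.30, 0.50, 0.20),
        "tumour_size_cm": (0.65, 0.28, 0.07),
        "lymph_node": (0.40, 0.60),
        "grade": (0.15, 0.40, 0.45),
        "position": (0.05, 0.45, 0.42, 0.08),
        "estrogen_receptor": (0.50, 0.50),
        "progesterone": (0.50, 0.50),
        "diagnosis": (0.10, 0.90),
    },
    "VUS": {
        "age": (0.02, 0.03, 0.35, 0.40, 0.20),
        "consanguinity": (0.80, 0.20),
        "family_history": (0.60, 0.40),
        "n_affected_family": (0.60, 0.30, 0.10),
        "tumour_size_cm": (0.70, 0.25, 0.05),
        "lymph_node": (0.55, 0.45),
        "grade": (0.30, 0.50, 0.20),
        "position": (0.05, 0.45, 0.42, 0.08),
        "estrogen_receptor": (0.30, 0.70),
        "progesterone": (0.30, 0.70),
        "diagnosis": (0.10, 0.90),
    },
    "Likely Benign": {
        "age": (0.02, 0.03, 0.30, 0.40, 0.25),
        "consanguinity": (0.85, 0.15),
        "family_history": (0.70, 0.30),
        "n_affected_family": (0.70, 0.25, 0.05),
        "tumour_size_cm": (0.80, 0.17, 0.03),
        "lymph_node": (0.70, 0.30),
        "grade": (0.50, 0.35, 0.15),
        "position": (0.05, 0.45, 0.42, 0.08),
        "estrogen_receptor": (0.35, 0.65),
        "progesterone": (0.35, 0.65),
        "diagnosis": (0.30, 0.70),
    },
    "Benign": {
        "age": (0.02, 0.03, 0.30, 0.40, 0.25),
        "consanguinity": (0.85, 0.15),
        "family_history": (0.80, 0.20),
        "n_affected_family": (0.80, 0.15, 0.05),
        "tumour_size_cm": (0.80, 0.17, 0.03),
        "lymph_node": (0.80, 0.20),
        "grade": (0.60, 0.30, 0.10),
        "position": (0.05, 0.45, 0.42, 0.08),
        "estrogen_receptor": (0.40, 0.60),
        "progesterone": (0.40, 0.60),
        "diagnosis": (0.50, 0.50),
    },
}

_FACTOR_CATEGORIES: dict[str, tuple] = {
    "age": ("<15", "15-19", "20-39", "40-59", ">=60"),
    "consanguinity": ("No", "Yes"),
    "family_history": ("No", "Yes"),
    "n_affected_family": ("0", "1-2", ">=3"),
    "tumour_size_cm": ("0-19", "20-39", ">=40"),
    "lymph_node": ("Negative", "Positive"),
    "grade": ("Grade 1", "Grade 2", "Grade 3"),
    "position": ("Other", "Right Breast", "Left Breast", "Both Breast"),
    "estrogen_receptor": ("Negative", "Positive"),
    "progesterone": ("Negative", "Positive"),
    "diagnosis": ("No", "Yes"),
}

#: Raw-unit sampling ranges for binned factors: bin label -> (low, high).
_BIN_RANGES = {
    "age": {"<15": (5, 15), "15-19": (15, 20), "20-39": (20, 40),
            "40-59": (40, 60), ">=60": (60, 86)},
    "tumour_size_cm": {"0-19": (0.3, 19.5), "20-39": (20.0, 39.5),
                       ">=40": (40.0, 55.0)},
    "n_affected_family": {"0": (0, 1), "1-2": (1, 3), ">=3": (3, 7)},
}


@dataclass(frozen=True)
class Archetype:
    """A recurrent-variant carrier profile: the fixed clinical fields of
    one variant family plus its gene-status triple."""

    name: str
    class_label: str
    fields: Mapping[str, object]
    genes: tuple[str, str, str]  # (brca1, brca2, other_genes)

    @property
    def gene_group(self) -> str:
        pattern = (self.genes[0], self.genes[1])
        for group, pat in _GROUP_PATTERN.items():
            if pat == pattern:
                return group
        raise ValueError(f"archetype {self.name}: bad gene pattern {pattern}")


ARCHETYPES: tuple[Archetype, ...] = (
    Archetype("P-fs-a1", "Pathogenic",
              {"age": 43, "sex": "Female", "tumour_size_cm": 17.5,
               "lymph_node": "Negative", "position": "Right Breast",
               "progesterone": "Positive", "diagnosis": "Yes"},
              ("Negative", "Positive", "Negative")),
    Archetype("P-fs-a2", "Pathogenic",
              {"age": 36, "sex": "Female", "tumour_size_cm": 0.5,
               "lymph_node": "Negative", "grade": "Grade 2",
               "position": "Right Breast", "progesterone": "Positive",
               "diagnosis": "Yes"},
              ("Negative", "Positive", "Negative")),
    Archetype("P-dup-b1", "Pathogenic",
              {"age": 44, "sex": "Female", "consanguinity": "Yes",
               "family_history": "Yes", "n_affected_family": 1,
               "position": "Right Breast", "diagnosis": "Yes"},
              ("Positive", "Negative", "Negative")),
    Archetype("P-dup-b2", "Pathogenic",
              {"age": 42, "sex": "Female", "tumour_size_cm": 6.6,
               "lymph_node": "Negative", "grade": "Grade 3",
               "position": "Right Breast", "estrogen_receptor": "Positive",
               "progesterone": "Negative", "diagnosis": "Yes"},
              ("Positive", "Negative", "Negative")),
    Archetype("LP-del-a", "Likely Pathogenic",
              {"age": 34, "sex": "Female", "consanguinity": "Yes",
               "family_history": "Yes", "n_affected_family": 1,
               "position": "Right Breast"},
              ("Positive", "Negative", "Negative")),
    Archetype("LP-del-b", "Likely Pathogenic",
              {"age": 33, "sex": "Female", "family_history": "Yes",
               "n_affected_family": 3, "diagnosis": "No"},
              ("Positive", "Negative", "Negative")),
    Archetype("VUS-mis-a", "VUS",
              {"age": 38, "sex": "Female", "family_history": "No",
               "n_affected_family": 0, "tumour_size_cm": 3.5,
               "lymph_node": "Negative", "grade": "Grade 3",
               "position": "Right Breast", "estrogen_receptor": "Positive",
               "progesterone": "Positive", "diagnosis": "Yes"},
              ("Positive", "Positive", "Negative")),
    Archetype("VUS-mis-b", "VUS",
              {"age": 42, "sex": "Female", "consanguinity": "No",
               "family_history": "No", "n_affected_family": 0,
               "tumour_size_cm": 0.5, "lymph_node": "Negative",
               "grade": "Grade 2", "position": "Right Breast",
               "estrogen_receptor": "Positive", "progesterone": "Positive",
               "diagnosis": "Yes"},
              ("Negative", "Positive", "Negative")),
    Archetype("VUS-mis-c", "VUS",
              {"age": 58, "sex": "Female", "family_history": "Yes",
               "grade": "Grade 2", "position": "Right Breast",
               "estrogen_receptor": "Positive", "progesterone": "Positive",
               "diagnosis": "Yes"},
              ("Positive", "Negative", "Negative")),
    Archetype("VUS-mis-d", "VUS",
              {"age": 58, "sex": "Female", "family_history": "No",
               "n_affected_family": 0, "lymph_node": "Positive",
               "grade": "Grade 2", "position": "Right Breast",
               "estrogen_receptor": "Positive", "progesterone": "Positive",
               "diagnosis": "Yes"},
              ("Positive", "Negative", "Negative")),
    Archetype("VUS-rad-a", "VUS",
              {"age": 32, "sex": "Female", "consanguinity": "Yes",
               "family_history": "No", "n_affected_family": 0,
               "lymph_node": "Positive", "position": "Right Breast",
               "estrogen_receptor": "Positive", "progesterone": "Positive",
               "diagnosis": "Yes"},
              ("Negative", "Negative", "Positive")),
    Archetype("VUS-rad-b", "VUS",
              {"age": 40, "sex": "Female", "consanguinity": "No",
               "family_history": "No", "n_affected_family": 0,
               "tumour_size_cm": 30, "lymph_node": "Positive",
               "grade": "Grade 2", "position": "Both Breast",
               "estrogen_receptor": "Positive", "progesterone": "Positive",
               "diagnosis": "Yes"},
              ("Positive", "Negative", "Positive")),
)


@dataclass
class CohortConfig:
    """Composition of a synthetic cohort (counts are exact censuses)."""

    n_patients: int = 268
    gene_distribution: dict[str, int] = field(
        default_factory=lambda: {"brca1": 61, "brca2": 128, "both": 11,
                                 "other": 68}
    )
    class_distribution: dict[str, int] = field(
        default_factory=lambda: {"Pathogenic": 87, "Likely Pathogenic": 23,
                                 "VUS": 128, "Likely Benign": 29, "Benign": 1}
    )
    n_male: int = 22
    missingness_rate: float = 0.1
    archetype_fraction: float = 0.35
    rng_seed: int = 0

    def validate(self) -> None:
        if sum(self.gene_distribution.values()) != self.n_patients:
            raise ValueError("gene counts must sum to n_patients")
        if sum(self.class_distribution.values()) != self.n_patients:
            raise ValueError("class counts must sum to n_patients")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must lie in [0, 1)")
        if not 0.0 <= self.archetype_fraction <= 1.0:
            raise ValueError("archetype_fraction must lie in [0, 1]")
        if self.n_male < 0 or self.n_male > self.n_patients:
            raise ValueError("n_male out of range")
        unknown = set(self.class_distribution) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels {sorted(unknown)}")
        if set(self.gene_distribution) != set(GENE_GROUPS):
            raise ValueError(f"gene_distribution needs keys {GENE_GROUPS}")


def default_config() -> CohortConfig:
    """The study composition: n=268, genes 61/128/11/68, classes
    87/23/128/29/1, 22 male, 10% missingness."""
    return CohortConfig()


def config_from_dict(payload: Mapping) -> CohortConfig:
    """Build a config from a plain mapping (e.g. a YAML/JSON file),
    starting from the defaults; unknown keys are rejected."""
    config = default_config()
    known = set(vars(config))
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown cohort config keys {sorted(unknown)}")
    for key, value in payload.items():
        setattr(config, key, dict(value) if isinstance(value, Mapping)
                else value)
    config.validate()
    return config


def _sample_raw(rng: np.random.Generator, factor: str, category: str):
    """Draw a raw value consistent with a sampled category."""
    if factor in _BIN_RANGES:
        low, high = _BIN_RANGES[factor][category]
        if factor == "tumour_size_cm":
            return round(float(rng.uniform(low, high)), 1)
        return int(rng.integers(int(low), int(high)))
    return category


def _background_fields(
    rng: np.random.Generator, class_label: str
) -> dict[str, object]:
    dist = BACKGROUND_DISTRIBUTIONS[class_label]
    fields: dict[str, object] = {}
    for factor, probs in dist.items():
        cats = _FACTOR_CATEGORIES[factor]
        category = cats[rng.choice(len(cats), p=np.asarray(probs))]
        fields[factor] = _sample_raw(rng, factor, category)
    return fields


def _archetype_counts(config: CohortConfig) -> dict[str, list[int]]:
    """Deterministic per-archetype patient counts for each class."""
    by_class: dict[str, list[Archetype]] = {}
    for arch in ARCHETYPES:
        by_class.setdefault(arch.class_label, []).append(arch)
    counts: dict[str, list[int]] = {}
    for label, archs in by_class.items():
        total = config.class_distribution.get(label, 0)
        k = int(round(config.archetype_fraction * total))
        k = min(k, total)
        base, extra = divmod(k, len(archs))
        counts[label] = [base + (1 if i < extra else 0)
                         for i in range(len(archs))]
    return counts


def generate_cohort(
    config: Optional[CohortConfig] = None,
    seed: Optional[int] = None,
) -> list[PatientRecord]:
    """Generate a labelled cohort with the configured exact censuses.

    ``seed`` overrides ``config.rng_seed``.  Identical seeds reproduce
    identical cohorts; different seeds vary the clinical values but
    never the censuses.
    """
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)

    arch_counts = _archetype_counts(config)
    by_class: dict[str, list[Archetype]] = {}
    for arch in ARCHETYPES:
        by_class.setdefault(arch.class_label, []).append(arch)

    # Check gene-pool feasibility of the archetype demand up front.
    gene_pool = dict(config.gene_distribution)
    for label, counts in arch_counts.items():
        for arch, count in zip(by_class[label], counts):
            gene_pool[arch.gene_group] -= count
    if any(v < 0 for v in gene_pool.values()):
        raise ValueError(
            "gene_distribution too small for the archetype demand; "
            "lower archetype_fraction or raise the gene counts"
        )

    # Plan each patient as (class, archetype-or-None).
    plan: list[tuple[str, Optional[Archetype]]] = []
    for label in CLASS_LABELS:
        total = config.class_distribution.get(label, 0)
        assigned = 0
        for arch, count in zip(by_class.get(label, []),
                               arch_counts.get(label, [])):
            plan.extend((label, arch) for _ in range(count))
            assigned += count
        plan.extend((label, None) for _ in range(total - assigned))

    # Remaining gene groups are shuffled over the background patients.
    bg_groups: list[str] = []
    for group in GENE_GROUPS:
        bg_groups.extend([group] * gene_pool[group])
    rng.shuffle(bg_groups)

    # Sex pool: males are allocated among background patients (the
    # archetype profiles are all female carriers).
    n_background = sum(1 for _, arch in plan if arch is None)
    if config.n_male > n_background:
        raise ValueError("n_male exceeds the background patient count")
    sexes = ["Male"] * config.n_male + \
            ["Female"] * (n_background - config.n_male)
    rng.shuffle(sexes)

    records: list[PatientRecord] = []
    bg_i = 0
    for label, arch in plan:
        fields = _background_fields(rng, label)
        if arch is None:
            group = bg_groups[bg_i]
            fields["sex"] = sexes[bg_i]
            brca1, brca2 = _GROUP_PATTERN[group]
            other = "Positive" if group == "other" else "Negative"
            bg_i += 1
        else:
            fields.update(arch.fields)
            brca1, brca2, other = arch.genes
        fields["brca1"] = brca1
        fields["brca2"] = brca2
        fields["other_genes"] = other
        # Missingness masks clinical inputs; the class label, sex and
        # genotype columns stay observed (they always are in a genetics
        # cohort, and the censuses are counted from them).
        if config.missingness_rate > 0:
            for factor in list(fields):
                if factor in ("sex", "brca1", "brca2", "other_genes"):
                    continue
                if rng.random() < config.missingness_rate:
                    fields[factor] = None
        records.append(
            PatientRecord.from_values(class_label=label, **fields)
        )

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    for i, rec in enumerate(records):
        rec.record_id = f"SYN-{i + 1:04d}"
    return records
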