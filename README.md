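# brcarisk

Risk scoring for *BRCA*-associated breast cancer variants from sixteen
clinical and genetic risk factors, with two independently trained
engines: a Mamdani fuzzy-inference system and a feed-forward neural
network. Both emit a risk score in [0, 1] that maps onto the five ACMG
variant classes (benign, likely benign, VUS, likely pathogenic,
pathogenic), making the tool primarily a triage aid for variants of
uncertain significance (VUS): given a patient's clinical picture and a
variant whose class is uncertain, the engines place the combined
evidence on the benign–pathogenic axis.

The intended users are clinical-genetics and biostatistics groups who
want a transparent, rule-inspectable risk model next to a black-box
regressor, trained on cohort tables rather than sequence data.

## The model

Each of the 16 risk factors (age, sex, consanguinity, family history,
number of affected family members, tumour size, lymph-node status,
grade, tumour position, ER, PR, BRCA1/BRCA2/other-gene variant status,
diagnosis, ACMG classification) is partitioned into linguistic
categories with a representative value on a common [0, 1] axis — 43
membership functions in all. Membership curves are triangular with
half-width equal to the distance to the neighbouring category value
(trapezoidal shoulders at the domain edges).

**Fuzzy engine.** Every training patient contributes one if-then rule:
the conjunction (AND = min) of their observed factor categories implies
their variant class. Inference clips each fired rule's output
membership function at its firing strength (min implication), combines
the clipped sets pointwise by max, and defuzzifies by the centroid

    score = Σᵢ xᵢ μ(xᵢ) / Σᵢ μ(xᵢ)

on a 1001-point grid over [0, 1]. Unknown inputs skip their clauses;
if no rule fires at all the score is reported as undefined rather than
invented.

**Neural engine.** A 16–10–1 network (tanh hidden layer, linear
output) is trained by full-batch backpropagation with momentum on
mean-squared error to regress the class value (0, 0.25, 0.5, 0.75, 1),
with a 160/54/54 train/test/validation split and early stopping on
validation error. Success is reported as the Pearson correlation R
between outputs and targets.

**Class bands.** A score maps to the nearest class value, so the band
boundaries sit at 0.125, 0.375, 0.625 and 0.875.

Because the source cohort is not publicly deposited, the package
includes a synthetic-cohort generator reproducing the study
composition exactly (268 patients; gene census 61 BRCA1 / 128 BRCA2 /
11 both / 68 other; class census 87/23/128/29/1; 22 male), and ships
the twelve published held-out test subjects as a fixture. See
`docs/methods.md` for what the generator does and does not emulate.

## Worked example

```sh
brcarisk generate --seed 1 -o cohort.csv
brcarisk build-fis cohort.csv -o rules.json
brcarisk train-nn cohort.csv --seed 1 -o net.json
brcarisk evaluate rules.json net.json -o results.csv
```

prints (abridged):

```
[brcarisk] seed=1: wrote 268 patients to cohort.csv
[brcarisk] built 268 rules from 268 patients -> rules.json
[brcarisk] seed=1: R_train=0.99961 R_val=0.99831 R_test=0.99911 R_all=0.99927 (2000 epochs, max_epochs)
[brcarisk] S01: fuzzy=0.917 (Pathogenic) network=1.000 (Pathogenic) expected=Pathogenic
[brcarisk] S05: fuzzy=0.750 (Likely Pathogenic) network=0.771 (Likely Pathogenic) expected=Likely Pathogenic
[brcarisk] S12: fuzzy=0.500 (VUS) network=0.500 (VUS) expected=VUS
[brcarisk] fuzzy class agreement: 12/12
```

Reading the numbers: the rule base has one rule per training patient
(268). The network's near-unity R values reflect that the
classification factor is itself among the inputs (the faithful default;
pass `--no-classification-input` to `build-fis` for the non-circular
fuzzy mode). Each held-out subject's fuzzy score is the centroid of
the output classes its matching rules assert — e.g. 0.917 is the
centroid of the pathogenic shoulder set — and both engines recover
every subject's recorded class.

The same pipeline is available as a library:

```python
from brcarisk import (build_catalogue, generate_cohort, build_rulebase,
                      infer, classify_score)

catalogue = build_catalogue()
cohort = generate_cohort(seed=1)
rulebase = build_rulebase(cohort, catalogue)
score = infer(rulebase, cohort[0], catalogue)
print(score.value, classify_score(score.value))
```

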