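# Methods

## Factor encoding and membership geometry

Every factor is a small ordinal or categorical scale with fixed
representative values on [0, 1] (e.g. age <15 → 0, 15–19 → 0.25,
20–39 → 0.5, 40–59 → 0.75, ≥60 → 1; tumour position Other → 0.25
through Both Breast → 1; the ACMG classes 0/0.25/0.5/0.75/1).
Continuous observations are binned first — age by the five ranges
above (years, half-open intervals), tumour size by 0–19 / 20–39 / ≥40
cm, affected family members by 0 / 1–2 / ≥3 — and then represented by
the bin's value, so all fuzziness lives on the encoded axis.

The published description fixes the membership shapes (triangular and
trapezoidal) and the category values but not the curve widths. We use
the standard full-overlap partition: each membership function is
triangular, centred on its category value, with half-width equal to
the distance to the nearest neighbouring centre within the factor
(0.25 for five-level factors, 0.5 for three-level, 1.0 for binary);
centres on a domain edge become shoulders, identical to a triangle
clipped to [0, 1]. Two consequences matter:

* a record encoded onto the category values satisfies its own
  categories with degree exactly 1 and all neighbouring categories
  with degree 0, so rules built from encoded records fire at binary
  strength; and
* the output sets have closed-form centroids — 0.25/0.5/0.75 for the
  interior classes and 0.25/3 ≈ 0.083, 0.75 + 0.5/3 ≈ 0.917 for the
  benign/pathogenic edge shoulders — all of which fall inside their
  own class band (boundaries 0.125/0.375/0.625/0.875).

## Fuzzy inference

Mamdani inference with AND = min over antecedent degrees, min
(clipping) implication, max aggregation, and numeric centroid
defuzzification on a uniform 1001-point grid. The grid size was
chosen so the centroid agrees with a 100-fold finer grid within 1e-3
(asserted by a property test); the cost is negligible. Aggregation is
computed per output class (max is idempotent), which makes inference
independent of rule order and count beyond the strongest strength per
class.

Unknown inputs skip the corresponding antecedent clauses — the clause
counts as fully satisfied. This is the only treatment that lets
records with many unknown fields score at all without imputation or
rule rewriting; it also means a rule built from a sparsely observed
patient is effectively a more general rule. A record that fires no
rule raises an explicit undefined-score error; we never substitute a
midpoint, because the centroid of an empty set is meaningless and a
silent 0.5 would masquerade as a confident VUS call.

The classification factor is both an input cluster and the output
scale. The faithful default keeps it as a rule antecedent like any
other factor; `include_classification=False` throughout the API (and
`--no-classification-input` on the CLI) gives the non-circular variant
driven by the 15 clinical factors only. With the circular default,
training accuracy on a generated cohort is 100%, comfortably above the
95.5% reference value — unsurprising, since each patient's own rule
fires at full strength and rules of other classes are vetoed by the
classification clause. We report it as measured and flag the
circularity here rather than hiding it.

## Score-to-class mapping

A crisp score maps to the nearest class value; exact midpoints
(0.125, 0.375, 0.625, 0.875) resolve to the lower class, the
conservative direction for pathogenicity claims. This is the unique
symmetric banding given the five class values; the reference system's
actual thresholds were never published (its narrative places 0.571 in
the likely-pathogenic band, which no symmetric banding reproduces —
nearest-centre calls it VUS).

## Neural regressor

Architecture 16–10–1 (tanh hidden, linear output), the smallest
conventional fitting-network layout; hidden size is configurable.
Training is full-batch gradient descent on MSE with momentum 0.9,
learning rate 0.05, at most 2000 epochs, early stopping when
validation MSE fails to improve for 50 epochs, best-validation weights
restored. These defaults fit the 268-patient problem in well under a
second on one CPU; fancier optimisers are unnecessary because the
target (the class value) is itself among the inputs, making the
regression nearly an identity extraction. Missing inputs are imputed
with the neutral mid-scale 0.5 for the network only. The 160/54/54
train/test/validation split generalises to other cohort sizes by
proportion, with rounding remainders going to the training set.

## Synthetic cohort generator

The source cohort is not deposited, so the generator emulates its
published composition exactly: 268 patients; variant-gene census 61
BRCA1 / 128 BRCA2 / 11 both / 68 other genes; class census 87
pathogenic / 23 likely pathogenic / 128 VUS / 29 likely benign / 1
benign; 22 male. All censuses are drawn as exact pools (shuffled
without replacement), never independent draws, so they hold for every
seed. Gene census groups are keyed on the (BRCA1, BRCA2) status
pattern; the other-genes flag can additionally be positive inside a
BRCA group, representing a secondary finding — the published subject
profiles require such combinations.

Clinical factor values are invented, in two strata:

* **Carrier archetypes.** 35% of each class (configurable) is drawn
  from a small library of full clinical profiles modelled on the
  recurrent germline variants carried by the packaged test subjects.
  Hereditary-cancer cohorts genuinely contain families and recurrent
  founder variants, so repeated carrier profiles are the realistic
  cohort structure; they are also what gives the held-out subjects
  informative same-class neighbours in the rule base — with binary
  firing strengths, a subject can only score if some training patient
  matches every one of its observed categories.
* **Background draws.** The remainder uses class-conditional
  categorical distributions (module constants, documented in
  `cohort.py`), biased so higher-risk classes skew toward
  family-history-positive, node-positive, grade-3,
  hormone-receptor-negative profiles.

A per-factor missingness rate (default 10%) masks clinical fields with
"Unknown"; sex, genotype columns and the class label stay observed, as
they do in a genetics cohort (and the censuses are counted from them).

What the generator does **not** emulate: real covariance between
clinical factors beyond the class-conditional and archetype structure,
measurement noise in the raw units, label noise in the ACMG
assignments, or the 652 excluded patients. Tests passing on this
cohort therefore demonstrate the pipeline's mechanics and the
published composition, not clinical validity on real data; in
particular, the 100% fuzzy training accuracy and near-unity network R
are properties of the circular classification-as-input design, which
the synthetic cohort reproduces rather than hides.

## Problem sizes and runtimes

All shipped defaults run the full published problem size: 268-patient
cohorts, 268-rule bases, 1001-point defuzzification grids, 2000-epoch
training. The test suite and the acceptance script each complete in a
few seconds on one CPU; the acceptance script repeats the fuzzy
accuracy over five cohort seeds and reports the worst case.

## Known limitations

* The exact published per-subject scores (0.900, 0.661, 0.425, …)
  depend on the original 268-patient rule base and unpublished
  membership widths; they are unrecoverable, and the harness targets
  class-level agreement, printing the reported scores alongside for
  inspection.
* The rule base grows linearly with the cohort and keeps duplicates
  verbatim (the reference design); inference is O(rules × factors)
  per record.
* In non-circular mode nothing prevents cross-class rule collisions;
  accuracy then genuinely depends on how separable the clinical
  profiles are.
* "Unknown"-heavy records are scored by increasingly general rules;
  with everything unknown, every rule fires fully and the score
  collapses toward the centroid of all classes.
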