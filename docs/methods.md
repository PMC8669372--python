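# Methods

## Model and procedure

`pcoscreen` treats questionnaire-only screening for PCOS and associated
mental-health issues as two parallel multi-criteria ranking problems fused
by a rule base.

**Triangular fuzzy numbers.** Every linguistic quantity is a TFN
`(l, m, u)` with membership 1 at the mode and 0 outside the support.
Arithmetic is component-wise (sum, product, reciprocal `(1/u, 1/m, 1/l)`),
which is exact for sums and a standard first-order approximation for
products and reciprocals of positive TFNs; all shipped scales are
non-negative and multiplication rejects negative supports outright.
Defuzzification is center of area, `(l + m + u)/3`. The distance between
two TFNs is the vertex metric — the root-mean-square of the three
component differences. The TOPSIS formulation used here leaves the
distance unspecified beyond "distance between two fuzzy numbers"; the
vertex method is its standard companion and is the package's declared
choice. Crisp scalars entering fuzzy operations (AHP weights in the
weighting step, ideal-solution components in the distance step) are
promoted to degenerate TFNs `(c, c, c)`.

**Fuzzy AHP.** Pairwise judgments on the nine-point Saaty-style scale
(Equal `(1,1,1)` through Extreme `(9,9,9)`, with intermediates) fill a
reciprocal matrix; per-row fuzzy geometric means, fuzzy weights
`r_i ⊗ (Σ r_k)^{-1}`, COA defuzzification and unit-sum normalisation give
the crisp criterion weights. The normalisation denominator is the sum of
the defuzzified weights — the only reading under which the weights sum to
one. A Saaty consistency ratio on the COA-defuzzified matrix is available
(`ahp.consistency_ratio`) but is not part of the screening procedure and
is off by default. The expert panel's own 31×31 judgment matrix was never
published; the panel's resulting normalised weights were, and ship as the
default weight vector (`default_weight_vector`). They print with
three-decimal rounding and sum to 0.997; the package renormalises them to
an exact unit sum.

**Fuzzy TOPSIS.** Per subject and channel, the three severity levels are
rated on each criterion through the rating map (below), multi-rater grids
are fused by (min lower, mean mode, max upper) — at screening time the
rater count is 1, since the experts' role was designing the scales, not
scoring each subject — each column is divided by its largest upper bound
(benefit-criterion form only; the formulation has no cost criteria),
weighted, and scored: FPIS is the per-criterion max upper bound, FNIS the
min lower bound, `d*`/`d−` are sums of vertex distances to the promoted
ideals, and `CC = d− / (d* + d−)`. Levels are ranked by decreasing CC with
ties broken by declared order (P1, P2, P3); the published worked example
never ties. A single alternative is rejected (both separations vanish; CC
is undefined), as is a configuration with `d* + d− = 0`.

**Fusion and indicators.** The nine-rule base is data, not code
(`data/rule_base.yaml`), so alternative clinical rule sets can be loaded;
totality over the 3×3 level pairs is enforced at construction. The shipped
default maps moderate mental-health states asymmetrically — (P1,M3) and
(P3,M3) fuse to A1 while (P2,M3) fuses to A3 — which is reproduced as
validated, not rationalised. Levels are selected purely by maximum CC; no
CC-magnitude threshold is applied. The wellness indicators are
`I_M = 100 · n{(P1 ∨ P3) ∧ A1} / n{P1 ∨ P3}` and symmetrically `I_P` over
M1/M3; both raise on an empty denominator rather than returning 0.

## Instrument, rating map, and their defaults

The published instrument states the 31 question topics and example answer
phrasings but not complete answer vocabularies. The shipped definition
(`data/instrument.yaml`) therefore fixes five ordered levels per item,
least to most symptomatic, using the standard K10 frequency anchors for
the distress items and frequency/severity anchors elsewhere. Both the
vocabularies and the group structure are configurable; the physical group
must feed 11 criteria to the PCOS channel and the other groups 20 to the
mental channel.

The expert answer→rating map is likewise unpublished. The default
(`RatingMap.monotone_default`) is monotone: answer index `i` of an
`L`-level item projects to position `round(4i/(L−1))` on the VL…VH scale;
the high-severity level reads that scale forwards, the normal level
backwards, and the moderate level through a tent (VL, M, VH, M, VL)
peaking at mid levels. This reproduces the qualitative behaviour that
severe sheets select P1/M1 and benign sheets P2/M2, and makes the
moderate level win exactly on mid-scale sheets.

## Error decomposition convention

The validation study's per-class decomposition reads FP from a class's
*actual* row and FN from its *predicted* column — swapped relative to the
textbook convention, but verifiably the convention under which its
published FP/FN tables were computed. `per_class_counts` reproduces it as
`convention="study"` (default, so the shipped regression tables
reproduce exactly) and offers `convention="standard"`. The study's
printed TN formula subtracts TP where inclusion–exclusion adds it; since
no TN values were published to contradict, TN is implemented as
`total − rowsum − colsum + TP`, which makes TP+FP+FN+TN equal the grand
total per class.

## Synthetic cohorts

The original 624-subject cohort is not public, so the generator stands in
for it. Labels are drawn from class priors (default: equal over A1–A4;
the real prevalence is unknown and equal priors exercise all four fusion
outcomes), then answers are drawn independently per criterion from
`separation · one_hot(target) + (1 − separation) · uniform`, where the
target is the most symptomatic level on channels the category affects
(A1: both; A2: physical; A3: psychological; A4: neither) and the least
symptomatic otherwise. Default `n = 624` matches the original data
collection; default `separation = 0.8` gives strong but imperfect class
structure. What the generator does *not* emulate: within-subject answer
correlations, graded/ordinal adjacency structure (noise is uniform, not
concentrated near the target level), item-specific difficulty, or
realistic prevalence. Passing tests on these cohorts therefore show the
pipeline's internal consistency and its behaviour under controlled class
structure — not field performance on clinical data.

At `separation = 1` the answers are deterministic and the default rating
map provably recovers every label, which the tests use as an end-to-end
anchor; accuracy is additionally checked to be monotone non-decreasing in
separation over {0.2, 0.5, 0.8}, averaged over three seeds at n = 600 —
sizes chosen to keep the whole simulation a few seconds of one CPU.

## Baselines

Ordinal encoding maps each answer to its 0-based index in declared level
order and labels A1–A4 to 0–3. The split is stratified 80/20 (the study
reports per-class test counts that imply all classes present in the test
set) and balancing runs on the training partition only, so no test
information leaks into the synthetic rows. The oversampler equalises all
class counts to the majority count; each synthetic row is the mean of a
randomly drawn class member and its k (default 5, clamped to class
size − 1) within-class Euclidean nearest neighbours — the anchor is
included in the mean, so k = 1 degenerates gracefully to the midpoint of
a sample and its nearest neighbour. Classifier defaults are RBF-kernel
SVM, KNN with k = 5, and an unlimited-depth decision tree; the study
states no hyperparameters, and all are exposed. The study's 167 test rows
exceed 20% of 624 (≈125), suggesting its split may have followed
augmentation; this package splits first and balances second, which is the
leakage-free order, and the row-count discrepancy is left as a documented
property of the reference tables rather than imitated.

## Reference fixtures and their limits

Three fixture families ship in `data/`: the expert weight vector, the
worked example's per-criterion separation distances for both channels,
and the two held-out confusion matrices with the test cohort's channel
composition (52+4 PCOS-positive, 83+1 mental-positive, 37 fused A1). The
worked example's raw linguistic ratings were never published, so the
distance tables anchor only the distances→CC→ranking step (P1: d*=31.33,
d−=66.93, CC=0.681; M1: CC=0.686; rankings P1>P3>P2 and M1>M3>M2); a full
forward reproduction from ratings is not possible. Likewise the D-tree
and KNN headline accuracies depend on the unpublished cohort and are not
regression targets.

## Numerical notes

Weight vectors validate a unit sum to 1e−9; oracle-equivalence tests
(independent transliterations of the AHP and TOPSIS formulas) agree with
the pipeline to 1e−12 at small sizes; CC comparisons against published
two-decimal values use ±0.01. Degenerate inputs rejected with explicit
errors: zero-support reciprocals, zero column maxima in normalisation,
single-alternative ideal solutions, empty indicator denominators,
singleton classes in splitting/balancing, and non-total rule bases.
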