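# Methods

`casel` builds binary activity classifiers for three human carbonic
anhydrase (hCA) isoforms — hCA II, the homeostatic off-target, and the
tumour-associated targets hCA IX and hCA XII — from flat bioactivity
exports, and combines the per-isoform predictions into selectivity
profiles. This note records the model, its assumptions, the tunable
parameters, and the design choices made where the procedure was genuinely
open.

## Curation

Raw exports carry one row per measurement (compound × target × endpoint ×
relation × value). Curation keeps only records that are mutually
comparable:

* endpoint Ki or IC50, value in nM, relation `=` (certain) or `>`
  (right-censored; a lower bound, treated as inactive at face value);
* molecules bearing a primary sulfonamide zinc-binding group, matched by
  the SMARTS `[#6][SX4](=[OX1])(=[OX1])[NX3H2]` — a tetravalent sulfur with
  two double-bonded oxygens, bound to carbon, carrying a free NH₂. This
  restricts the set to one mechanism of action and excludes allosteric
  binders and exotic warheads.

Replicate measurements for the same compound × isoform are merged by a
spread rule: with population standard deviation *s* and mean *m* over *n*
records,

| condition            | outcome                              |
|----------------------|--------------------------------------|
| n = 1                | value kept (`single`)                |
| s < 0.20·m           | mean kept (`mean_kept`)              |
| s ≥ 0.20·m and n > 5 | mode of reported values (`mode_replaced`) |
| s ≥ 0.20·m and n ≤ 5 | group discarded                      |

Choices the rule itself does not fix: the SD is the population SD
(configurable); the retained value for a consistent group is its mean (the
natural summary the rule already computes); the mode of continuous values
is taken over 3-significant-figure equivalence classes, ties breaking to
the lowest tied value. A group is flagged `censored` only when *every*
member record is censored; a weaker `any_censored` flag records partial
censoring. Compound identity is the export's compound id; SMILES are
canonicalised once at the sulfonamide filter.

## Features

The baseline feature space is a frozen manifest of 118 RDKit 2D
descriptors (constitutional, topological, E-state, partial-charge and
surface-area families; `fr_*` fragment counts and composite scores such as
QED are excluded). Freezing the names makes provider drift detectable — an
unknown name is a hard error, not a silent change of feature space.

Redundant descriptors are pruned by a greedy first-seen scan at a Pearson
correlation threshold: walking columns in manifest order, a column is
dropped when its |PCC| with any earlier retained column reaches the
threshold. Absolute correlation is used because anti-correlated features
are equally redundant. The retained set provably satisfies the pairwise
bound |PCC| < threshold; a different column order could give a different,
equally valid set. Constant columns (zero variance) correlate with
nothing, are retained, and are reported. Compounds with any failed
descriptor are dropped with a report rather than imputed — failures are
rare and imputation would be an unforced modelling choice. Thresholds 0.95
and 0.75 are provided alongside the unpruned baseline.

## Class construction

Activity data for these isoforms are strongly skewed towards potent
compounds, so fixed cutoffs (< 20 nM active, ≥ 100 nM inactive, the band
between excluded as intermediate) give unbalanced classes. The flexible
alternative sorts compounds by activity ascending (stable sort, compound id
as tie-break) and takes the best *N* as actives and the worst *N* as
inactives. Each sampling size *N* (default grid 150–700 in steps of 50)
yields perfectly balanced classes with data-adaptive effective thresholds;
the boundary statistics — activity of the last active, of the first
inactive, and their ratio — quantify class separation and show where
data-poor isoforms run out of genuine inactives. Censored `>` records sort
at face value; they carry large values and land in the inactive tail,
matching their automatic inactive reading.

## Learning

Ten scikit-learn classifiers with library defaults: LR, LDA, KNN, CART
(decision tree), NB (Gaussian), SVM, AdaBoost, gradient boosting, random
forest and extra trees. Scale-sensitive learners (LR, LDA, KNN, SVM) are
wrapped in a standardisation step; the SVM gains class probabilities
through an explicit calibration layer (`CalibratedClassifierCV`,
`ensemble=False`). Hyperparameter search is deliberately out of scope.

Each dataset is split 75:25 stratified. The training phase runs stratified
tenfold cross-validation on the 75 %; the testing phase trains on the 75 %
and scores the withheld 25 %. Metrics are accuracy, precision, recall and
the Matthews correlation coefficient (MCC), with "active" as the positive
class; an MCC above 0.6 is read as good performance. Any zero-denominator
metric is reported as an explicit undefined flag, never as a silent zero —
validation sets genuinely lose whole classes for data-poor isoforms.

Every prediction carries a probability score: the larger of the two class
membership probabilities, hence in [0.5, 1]. Experiments are repeated
R = 10 times with per-repeat random states drawn from one master seed via
`numpy.random.SeedSequence`; labels and scores are averaged, the final
label is the rounded mean label (an exact 0.5 tie breaks to *inactive* —
the conservative choice for screening), and the mean score is kept even
when repeat labels disagree (the disagreement is visible in the label SD).

## External validation

For each isoform and *N*, compounds outside the sampled dataset with
activity < 20 nM (true active) or > 100 nM (true inactive) form the
validation set; the intermediate band has no defined truth. Models trained
on the full sampled dataset classify these unseen compounds; a true active
predicted active is a TP, predicted inactive an FN; a true inactive
predicted active is an FP, predicted inactive a TN.

Results are stratified by probability bin {0.6, 0.7, 0.8, 0.9, 1.0}:
the mean score is rounded half-up to one decimal, and scores below 0.55 are
clamped into the lowest bin. Rounding (rather than half-open intervals)
makes per-bin confusion counts sum exactly to the overall counts. Two
scoring modes exist: the default counts one outcome per compound from its
consensus label (exact bin additivity); an alternative counts outcomes per
repeat and averages the counts before rounding, mirroring reports that
average experiments first (additivity then holds to ±1).

A second stratification splits the validation set by structural similarity
to the training set: the mean atom-pair-fingerprint Tanimoto coefficient of
each validation compound against all training compounds, thresholded at
0.336 ("similar" at or above). The mean — not the nearest neighbour — is
the primary reading because the reference procedure averages over the
training ligands; a `max` mode is available since mean similarity is
systematically low for diverse training sets.

## Selectivity

Per isoform pair (II vs IX, II vs XII) the 2×2 space of binary labels maps
bijectively onto four classes: non-selective (active on both), selective
for the tumour isoform over hCA II, selective for hCA II, and non-selective
(inactive on both). Profiles are computed only from validated consensus
labels; a compound lacking a prediction on one isoform (because it was
sampled into that model's training set) yields an incomplete profile with
no class. The confidence of a combined call is the *minimum* of the two
mean scores — the conservative extension of single-model confidence
ranking; it is reported, not thresholded.

## Synthetic studies

The generator produces ChEMBL-export-shaped studies with the statistical
structure the analysis assumes, so every stage is testable offline.

*Chemistry.* Compounds are enumerated from a benzenesulfonamide /
heteroaryl-sulfonamide scaffold grammar (~2,200 unique molecules) with a
configurable fraction of decoys lacking the warhead, to exercise the
zinc-binding-group filter. This is a chemotype mimic, not realistic
medicinal chemistry.

*Activity model.* The latent log₁₀ activity of each isoform is a sparse
linear function of true computed descriptors (logP, TPSA, molecular
weight, H-bond counts, rotatable bonds, ring count, sp³ fraction), shared
across isoforms with small per-isoform weight jitter — so the three
endpoints are correlated and descriptor-based learners can genuinely
recover the signal. Scores are standardised and mapped to the configured
location/scale per isoform (defaults: hCA II μ=1.3, σ=1.3 log units;
hCA IX 1.6/1.1; hCA XII 1.4/0.9, with coverages 1.0/0.85/0.70), chosen to
reproduce the qualitative features of the public data: most values below
100 nM, few inactives, hCA XII poorest in inactives. Per-measurement noise
(default 0.30 log units) doubles as the class-separation dial.

*Selectivity.* The selective subpopulation (default 15 %) is the top
fraction of a *second* descriptor direction, deliberately different from
the potency direction — selectivity must be a function of structure, not an
unlearnable random flag. The isoform shift (default +2 log units on hCA II,
−0.5 on IX/XII) is graded by a sigmoid of the selectivity score, so clearly
selective structures get the full shift while borderline ones get partial
shifts and fall into the intermediate band, as graded selectivity does in
real series.

*Data pathologies.* About 10 % of compound × isoform groups receive
replicate records: most consistent (within the 20 % SD rule), a small
fraction conflicting — half as small groups (constructed to be discarded)
and half with more than five records and four identical values (so the
mode rule demonstrably recovers the base value). Censored `>` records are
injected in the inactive tail (above 1,000 nM). All randomness flows from
one master seed through named substreams; a study is fully reproducible
from its config, and the truth table records latent activities, the
per-compound selectivity shift factor, true fixed-threshold labels and
true selectivity classes.

*What passing on synthetic data does not show.* The generator's activity
surface is low-dimensional and nearly linear in eight descriptors, its
chemistry is a narrow scaffold grammar, and its noise is homoscedastic
log-normal. Real assay data have inter-laboratory offsets, activity
cliffs, and chemotype-dependent noise, so performance levels observed here
bound the pipeline's correctness, not its real-world accuracy.

## Problem sizes and numerical choices

The analysis scripts and the acceptance computation run the full pipeline
on 800-compound studies with N ∈ {150, 250, 350}, ten algorithms, k = 10
folds and R = 10 repeats — sizes chosen so a complete run finishes in
minutes on one core while keeping ≥ 100 compounds per class at the largest
N. Display rounding is half-away-from-zero to two decimals, with raw
doubles kept internally. Report-level ratios are printed to two decimals.
Derived random states are reduced modulo 2³¹−1.

## Known limitations

* The 118-descriptor manifest is a fixed choice over the current
  descriptor provider; other reasonable manifests (and other column
  orders) yield different, equally valid pruned sets, so retained-count
  values are descriptive, not normative.
* Mean-similarity stratification yields few "similar" compounds for
  diverse training sets; the 0.336 threshold is a fingerprint-specific
  convention, not a calibrated boundary.
* No applicability-domain model beyond the similarity split; no salt
  stripping or tautomer standardisation beyond SMILES canonicalisation;
  no hyperparameter tuning; profiles cover three isoforms and two pairs
  only.
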