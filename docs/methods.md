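# Methods

This note documents the models, conventions and design choices behind
`foldpool`, in the order the pipeline applies them.

## Data model and filtering

A *pool* is the set of predictions one sampling plan produces for a target:
an ordered collection of parameter sets (engine, dropout, templates,
recycles), each running `n_nn_models × samples_per_model` inferences.  The
shipped plans encode the production combinatorics: 8 sets × 15 NN models ×
67 samples = 8040 predictions (each set 1005), a reduced plan of the 5
retained sets × 15 × 33 = 2475, a monomer plan (5 NN models, 201
samples/model), and the 25-prediction default-run baseline.  Records carry
ipTM/pTM (multimers) or mean pLDDT (monomers), a clash count and a CAPRI
clash flag; interface scores attach DockQ and optionally an
assessor-provided CAPRI class to a (record, interface) pair.

Clash filtering removes records with more than 300 clashes or a set CAPRI
clash flag, in that precedence order for reporting, before any statistic is
computed.  A missing clash count is treated as 0 with a logged warning:
exclusion must be opt-in on evidence.  Row order in input tables is
preserved and is the stable tie-break order for every downstream selection —
no hidden sort keys.

Ranking confidence is 0.8·ipTM + 0.2·pTM for multimers and the mean pLDDT
for monomers; score files carrying both dialect keys are rejected rather
than guessed.

## Interface summaries and CAPRI classes

Per interface the package computes DockQ_max, the third quartile Q3, the
spread DockQ_max − Q3, the pool max ipTM and CAPRI class counts.  Quantiles
use linear interpolation between order statistics (numpy `"linear"`, the
classical type-7 rule), centralised in `foldpool.metrics.QUANTILE_METHOD`
because classification near spread = 0.2 can depend on the convention.
Medians average the two central order statistics for even counts, so the
nominal 25-record baseline median is the 13th order statistic.

CAPRI classes derive from DockQ with lower-inclusive boundaries 0.23 / 0.49
/ 0.80 (acceptable / medium / high).  When the input table carries
assessor-provided classes, the provided class wins and disagreements with
the DockQ-derived class are logged, since assessors may classify from
original CAPRI criteria rather than DockQ.

A caution on an intuitive-sounding monotonicity: under interpolated
quantiles, adding a prediction *below the current Q3* can still raise the
interpolated Q3 slightly (insert 0.7 into {0, 0.5, 1}: Q3 moves from 0.75 to
0.775) and hence shrink the spread.  Only additions at or below the current
minimum are guaranteed not to; the property tests assert exactly that.

## Difficulty classification

Labels are assigned from (DockQ_max, spread) with precedence
extreme → easy → hard:

* extreme: DockQ_max < 0.4
* easy: DockQ_max > 0.6 and spread ≤ 0.2
* hard: residual.

The clauses as usually written leave DockQ_max ∈ {0.4, 0.6, 1.0} and
spread = 0.2 ambiguous or doubly matched; the residual-class precedence
keeps the classifier total and honours the easy clause's inclusive "≤ 0.2".
Consequences: DockQ_max exactly 0.4 or 0.6 is hard; a perfect maximum with
spread ≤ 0.2 is easy; spread exactly 0.2 with a high maximum is easy.  Each
label records which clause fired.

Hard and extreme interfaces form the positive "non-trivial" class for
triage.  A post-hoc flag marks likely-extreme interfaces by pool max ipTM
strictly below 0.72.

## Triage (the fitted component)

`InterfaceTriage` is the package's one model/results pair: the decision rule
"run massive sampling when the per-interface score falls below a threshold",
fitted by sweeping the ROC curve and selecting the F1-optimal threshold.
The direction — LOW score predicts non-trivial — is fixed once, centrally;
median ipTM is a confidence, so low means difficult.  The ROC is swept over
all distinct score thresholds (no point dropping) via scikit-learn's
`roc_curve`; the trapezoidal AUC then equals the pairwise-comparison
probability with ties counted ½, which the test suite verifies against a
brute-force oracle.  The F1 scan evaluates midpoints between consecutive
distinct scores plus one candidate below the minimum (predict nothing) and
one above the maximum (predict everything), breaking ties toward the smaller
threshold.  AUC and F1 are undefined for single-class truth vectors and
raise rather than return a default.

Gate comparisons in the scenarios use strict `<` ("below the threshold");
with thresholds 0.8 / 0.65 / 0.57 equality is measure-zero on real scores,
but the choice is documented because prose often writes "≤".  Any
per-interface score vector can be fitted; median ipTM is the named preset.

## Scenarios

Each scenario combines an optional gate with trimming: S1–S3 gate at 0.8 /
0.65 / 0.57 with full sampling; S4–S6 keep 5 of 8 parameter sets (dropping
the weak 3-recycle set and the two sets with redundant or poor results) and
33 of 67 samples per model, ungated or gated at 0.65 / 0.57.  Gated-out
interfaces fall back to the AF2-baseline pool rather than being dropped —
every interface is still scored, matching how a practitioner would operate
(the default run always exists).  The fallback is switchable in code.

Intensity reduction selects `sample_index < 33` deterministically, emulating
a smaller run; a seeded random-subsample mode exists for sensitivity
analysis since nothing says *which* 33 a shorter run would have produced.
Gating is per interface by default; a per-target mode (gate a target by the
minimum of its interfaces' baseline medians) is available because
multi-interface targets are sampled as a unit in practice.

Cost is Σ over retained records of a per-parameter-set weight, default 1
(cost = subset cardinality); a recycle-proportional weighting approximates
relative GPU effort but no exact GPU-time reproduction is claimed.

## Ranking

Selection happens per target (one set of ≤ 5 models by ranking confidence,
stable ties), evaluation per interface of those same models — mirroring
community-assessment submission mechanics.  A group's key statistic is the
weighted CAPRI score 3·high + 2·medium + 1·acceptable over per-interface
best classes; "incorrect" contributes 0 and is reported separately.
Cumulative DockQ sums the per-interface DockQ maximum over submitted models
by default; the DockQ of the best model *by class* is computed alongside
(`cumulative_dockq_class_best`) because bar height and bar order can
reasonably be defined either way.  Ordering is weighted score, then
cumulative DockQ, then group name.

## Synthetic generator

The generator emulates the summary structure of massive-sampling score data,
not real AlphaFold outputs: no coordinates, no MSA or template effects, no
real confidence-score distributions.  Passing tests therefore demonstrate
correctness of the pipeline's arithmetic and decision rules and the
self-consistency of the difficulty/triage machinery — not performance on
real prediction data.

Per interface a best model is planted and a DockQ bulk drawn by class:

* easy — 60% of the pool within 0.15 of the planted maximum
  (max − 0.15·Beta(2,3)), the rest a low tail (0.7·max·Beta(2,2)); the
  planted maximum is uniform on (0.68, 0.95).  Construction guarantees
  spread ≤ 0.15.
* hard — with probability 0.6 an *outlier* interface: bulk
  cap·Beta(2,4) with cap ~ U(0.32, 0.45), plus 10–40 outliers within 0.08 of
  a planted maximum ~ U(0.62, 0.88); otherwise a *mid* interface with bulk
  max·Beta(2,3), max ~ U(0.44, 0.58).
* extreme — max·Beta(1.5, 6) with max ~ U(0.15, 0.38); everything stays
  below 0.4 by construction.

ipTM is a noisy affine transform of DockQ (intercept/slope/sd per class:
easy 0.35/0.55/0.05, hard 0.33/0.60/0.05, extreme 0.20/0.50/0.04), clipped
to [0, 1]; pTM rides 0.06 above ipTM with extra noise.  This makes
confidence ranking informative but imperfect: top-confidence selection
usually, not always, retrieves the planted outliers.  The extreme settings
keep pool max ipTM typically below the 0.72 post-hoc flag.

Baseline pools (25 records, the five v3 models × 5 samples) draw an
interface-level ipTM centre from a class-dependent normal — easy
N(0.80, 0.11), hard N(0.68, 0.11), extreme N(0.48, 0.10) — with 0.04
within-interface noise; baseline DockQ comes from the class bulk (for easy,
the same top/tail mixture, so a carefully scored default run is genuinely
competitive on easy interfaces).  Baseline ipTM is deliberately uncoupled
from baseline DockQ, which reproduces the gap between the baseline's
max-ipTM pick and its best-by-DockQ model.  The centres were chosen by a
normal-theory calculation so that the median-ipTM triage AUC on a
41/17/7 benchmark has expectation ≈ 0.83–0.84 — separable but imperfect,
inside the designed 0.75–0.90 band; the per-seed sampling standard
deviation on 65 interfaces is ≈ 0.05, so the calibration test asserts the
band on the mean over 20 fixed seeds.

Two stylised modifiers, both switchable: the 3-recycle parameter set is
systematically weak (DockQ scaled by 0.65, never hosting planted models),
and the first hard interface hides all its outliers in a single parameter
set — the case where diversity trimming would discard the only good models
if that set were dropped.

All randomness flows from one seed through `numpy.random.SeedSequence`
children (one per interface), so identical (config, seed) pairs give
byte-identical output and any interface is reproducible independently.  The
ground-truth table is written to a separate file that no analysis stage
reads.

## Problem sizes in the tests

Unit tests run on 108-record pools (3 sets × 3 models × 12 samples, with the
hard outlier count scaled to 2–4 so outliers stay outliers in a small pool).
The end-to-end recovery suite and the acceptance script use the full study
layout — 65 interfaces × 8040 records — the former over 20 seeds, the
latter on the single seed passed on the command line.

## Known limitations

* The difficulty thresholds (0.4 / 0.6 / 0.2) and gate presets are constants
  of the method, not estimated quantities; only the F1-optimal threshold and
  the AUC are data-dependent.
* Real-data difficulty distributions, confidence miscalibration and
  per-target pool-size truncation are not emulated; the generator's effect
  sizes are chosen for separability and construction-guaranteed labels, not
  distributional fidelity.
* Cost accounting is a per-prediction proxy; real GPU time depends on target
  size and recycling in ways the weights only approximate.
* The spread statistic's behaviour under pool growth is convention-dependent
  (see the Q3 caution above).
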