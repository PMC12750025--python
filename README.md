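# foldpool

Analysis toolkit for **massive-sampling protein complex prediction pools**:
interface-difficulty classification from DockQ distributions, a-priori
difficulty triage from AlphaFold confidence scores, reduced-sampling scenario
simulation and CAPRI-style model-selection ranking — plus a synthetic
benchmark generator with known ground truth, so every stage is testable
without any external data.

Massive sampling runs AlphaFold2-family inference thousands of times per
target (multiple inference engines, dropout settings, template and recycle
configurations, 15 neural-network models, dozens of samples each — 8040
predictions in the standard plan of 8 parameter sets × 15 NN models × 67
samples).  That buys rare high-quality models for difficult protein–protein
interfaces, at a large compute cost and with a model-selection problem at the
end.  `foldpool` is aimed at people who assess such pools: structure
prediction groups deciding *when* deep sampling is worth it, and scoring
method developers who need calibrated benchmarks of pool-level score
distributions.

## What it computes

For each assessed interface, given DockQ values for every prediction and the
AlphaFold confidence scores (ipTM, pTM; mean pLDDT for monomers):

* **Pool summaries** — DockQ_max, the third quartile Q3 (type-7, linear
  interpolation), the top-of-distribution spread DockQ_max − Q3, pool max
  ipTM, and CAPRI class counts (DockQ ≥ 0.23 / 0.49 / 0.80 for
  acceptable / medium / high, lower-inclusive).
* **Difficulty labels** —
  *extreme*: DockQ_max < 0.4; *easy*: DockQ_max > 0.6 and spread ≤ 0.2;
  *hard*: everything else (evaluated in that order, hard as the residual
  class).
* **A-priori triage** — from the 25-prediction default-run baseline
  ("AF2-baseline"), the median ipTM predicts whether an interface is
  *non-trivial* (hard or extreme): low median ⇒ run massive sampling.
  `InterfaceTriage(...).fit()` returns the ROC curve, the AUC and the
  F1-optimal gate threshold; preset gates 0.8 / 0.65 / 0.57 define the
  scenarios below.
* **Scenarios** — MF-best (the full pool), S1–S3 (gate at 0.8 / 0.65 / 0.57,
  full sampling), S4–S6 (5 of 8 parameter sets, 33 of 67 samples per model =
  2475 predictions, ungated / gated at 0.65 / 0.57).  Gated-out interfaces
  fall back to the AF2-baseline pool.  Each scenario reports its best model
  per interface, cumulative DockQ, CAPRI class counts and compute cost.
* **Ranking** — per-target top-5 selection by ranking confidence
  (0.8·ipTM + 0.2·pTM), evaluated per interface; groups ordered by the
  weighted CAPRI score 3·high + 2·medium + 1·acceptable, ties broken by
  cumulative DockQ.  Reference pseudo-groups: oracle picks from the pool and
  from the baseline, the baseline's max-ipTM model, and the top-5-confidence
  submission.
* **Filtering** — predictions with more than 300 clashes or a CAPRI clash
  flag are excluded before any statistic, with a per-record exclusion report.

## Worked example

```python
import foldpool as fp
from foldpool.difficulty import assign_difficulty, nontrivial_mask
from foldpool.metrics import baseline_summaries, interface_target_map
from foldpool.scenarios import scenario_report, scenario_totals_frame

# a synthetic study: 41 easy / 17 hard / 7 extreme interfaces, 8040-model pools
bench = fp.generate_benchmark(fp.GeneratorConfig(seed=1))
retained, excluded = fp.filter_clashes(bench.records)

summaries = fp.summarize_interfaces(retained, bench.scores)
labelled = assign_difficulty(summaries)
print(labelled["label"].value_counts().to_dict())

targets = interface_target_map(bench.scores)
baselines = baseline_summaries(bench.baseline_records, targets)
triage = fp.InterfaceTriage(
    baselines.loc[labelled.index, "median_iptm"].to_numpy(),
    nontrivial_mask(labelled["label"])).fit()
print(triage.summary())

report = scenario_report(retained, bench.scores, bench.baseline_records,
                         bench.baseline_scores, baselines,
                         interface_targets=targets)
print(scenario_totals_frame(report).round(2).to_string())
```

prints

```
{'easy': 41, 'hard': 17, 'extreme': 7}
Interface triage (predict non-trivial when score < threshold)
==============================================================
predictor:            baseline median ipTM
interfaces:           65 (24 non-trivial, 41 trivial)
AUC:                  0.925
F1-optimal threshold: 0.697
F1 at threshold:      0.800
preset gates:         S1=0.8, S2=0.65, S3=0.57

              cumulative_dockq  total_cost  n_incorrect  n_acceptable  n_medium  n_high
scenario
MF-best                  46.29    511985.0            2             6        35      22
S1                       45.88    323549.0            2             6        36      21
S2                       43.43    142959.0            3            13        29      20
S3                       41.23     72273.0            4            17        24      20
S4                       45.78    157579.0            5             3        35      22
S5                       43.01     44857.0            6            10        29      20
S6                       40.92     23258.0            6            15        24      20
AF2-baseline             39.38      1625.0            8            16        22      19
```

Reading the table: every difficulty label was recovered from the generated
pools; the triage separates trivial from non-trivial interfaces with AUC
0.925 on this seed; and the scenario gradient shows the intended trade-off —
S5 keeps 93% of the full pool's cumulative DockQ (43.0 vs 46.3) at under a
tenth of its unit-weight cost, while the AF2-baseline alone loses most of the
medium/high-quality models on non-trivial interfaces.

The same pipeline is available from the shell:

```sh
foldpool simulate --config gen.yaml --seed 1 --out bench/
foldpool analyze --in bench/ --scenarios all --gate-level interface --out results/
```

`analyze` writes interface summaries, difficulty labels, the ROC curve,
scenario totals, a leaderboard and a run manifest with reconciled row counts.

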