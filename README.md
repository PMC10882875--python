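# trajnet

Chronic-disease trajectory-network analysis for longitudinal multi-disease
onset cohorts. From a table of participants (covariates, survey weights,
observation window) and year-resolution disease-onset events, the pipeline
derives:

1. **Cohort cleaning** — exclusion rules (no follow-up, missing
   demographics, entry-age floor) with a per-rule audit log, recall
   resolution of repeated self-reports, and first-onset records.
2. **Descriptives** — survey-weighted prevalences, multimorbidity
   distribution, per-disease onset-age medians/IQRs, and age-scale
   Kaplan–Meier cumulative incidence with left truncation.
3. **Directed disease pairs** — for each of the k(k−1)/2 unordered pairs,
   counts of strict temporal orderings (same-year onsets are excluded as
   simultaneous) and a two-sided exact binomial test against 50%, with a
   Bonferroni-across-pairs threshold (a per-pair 0.05/N policy is available
   as a config alternative).
4. **Matched odds ratios** — nested case-control sets built by
   incidence-density sampling (1:3 by default, matched on sex and baseline
   age within a caliper), a from-scratch safeguarded-Newton conditional
   logistic fitter, and set-level percentile-bootstrap confidence
   intervals. Pairs with OR > 1 and CI excluding 1 become network edges.
5. **Trajectory network** — a directed graph of selected pairs with
   start/end/hub role classification, cycle-safe path chaining, linear
   three-disease trajectories scored by strict per-person onset orderings
   (participant counts and median inter-onset gaps), and a ranked top-k
   table. Exports to a TSV edge list and GraphML.

A seeded synthetic-cohort simulator (`trajnet.simulate`) generates
CHARLS-shaped cohorts — yearly discrete-time baseline hazards on an age
scale, planted pairwise hazard-ratio dependencies that act from the year
after the predecessor's onset, survey waves with permanent dropout, and
survey weights — so every stage has parameter-recovery tests with known
ground truth.

## CLI

```bash
trajnet run-all --config examples/config.yaml --seed 1 --out out/
```

runs every stage and writes intermediate tables (`participants.csv`,
`events.csv`, `direction_tests.tsv`, `pair_estimates.tsv`,
`network_edgelist.tsv`, `network.graphml`, `top_trajectories.tsv`,
`run_report.json`) under `out/`. Each output starts with `#` header lines
recording the package version, seed, and config hash; runs with the same
config and seed are byte-identical.

Stages are also available individually (`simulate`, `clean`, `direction`,
`pairs`, `network`, `trajectories`), each reading the previous stage's
files from the output directory, plus `validate-config`.

## Library entry points

```python
from trajnet import (
    SimulationConfig, simulate_cohort,          # synthetic cohorts
    enumerate_pairs, exact_binomial_direction_test,
    MatchConfig, build_case_control, clogit_fit, bootstrap_ci,
    build_network, linear_trajectories, rank_trajectories,
)
```

`trajnet.pipeline.run_pipeline(PipelineConfig.from_dict(...))` drives the
same flow programmatically.
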