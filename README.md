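# strooprel

Reliability analysis pipeline for two-session Stroop-type interference
tasks. The package covers the full workflow for asking "how reliable is an
interference-cost measure?": trial-level screening, cost scoring,
permutation split-half internal consistency with Spearman-Brown correction,
Pearson / ICC(2,1) / ICC(3,1) test-retest reliability, and reliability as a
function of trial count — together with a hierarchical two-arm, two-session
cohort simulator whose ground-truth reliability is known in closed form, so
every estimator can be validated against an analytic oracle.

## Modules

| Module | Role |
| --- | --- |
| `strooprel.trial_data` | trial-level data model and CSV I/O |
| `strooprel.synthetic_cohort` | cohort simulator, points scoring, analytic reliability oracles |
| `strooprel.screening` | trial trimming + participant exclusion cascade with audit ledger |
| `strooprel.performance_summaries` | condition summaries, interference costs, RT shape statistics |
| `strooprel.reliability` | split-half, Fisher-z comparison, Pearson, ICCs, trial-count curves |
| `strooprel.cli_report` | config-driven end-to-end runs and the `strooprel` CLI |

## CLI

```bash
# simulate a two-arm, two-session cohort
strooprel simulate --n 50 --seed 1 --out cohort.csv

# screening cascade: per-trial 3-SD trim, 2000 ms cap, participant flags
strooprel screen cohort.csv --out kept.csv --report screen.json

# descriptive cost table per arm and session
strooprel summarize kept.csv --out table1.csv

# split-half + test-retest + trial-count curves
strooprel reliability kept.csv --splits 5000 --seed 7 --out reliability.json

# full pipeline from a YAML config
strooprel run --config config.yaml
```

A minimal `config.yaml`:

```yaml
generator:
  n_participants: 50
n_permutations: 5000
curve:
  step: 10
out_dir: results
seed: 7
```

Identical config + seed gives a byte-identical `report.json`.

## Data format

CSV with header
`participant_id,session,arm,trial_type,correct,rt_ms` (plus optional
`trial_index`; assigned from file order when absent). `arm` is `basic` or
`game` and constant per participant; `trial_type` is `congruent`, `neutral`
or `incongruent`; `correct` is 0/1; `rt_ms` is a positive reaction time in
milliseconds.
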