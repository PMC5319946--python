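# rataffect

Composite depression and anxiety rating scales for rat behavioural
phenotyping, plus the full analysis pipeline that feeds them:

* **`rataffect.scales`** — the two rating scales as data-driven interval
  tables (depression 0–25: weight, sucrose preference, open-field travel
  distance, rearing; anxiety 0–28: ID%, IT%, OT%, OE%, 0–7 each), a
  structural validator, and per-rat scorecards.  The tables ship as
  editable YAML under `src/rataffect/data/`; the validator reports the
  known narrative-vs-table conflicts (weight extremes) instead of
  silently fixing them.
* **`rataffect.indices`** — sucrose preference (%) from two-bottle
  masses and the 50% von Frey withdrawal threshold (ascending-fraction
  rule by default, staircase estimator behind a flag).
* **`rataffect.trajectories`** — open-field and elevated-plus-maze
  metrics from time-stamped x–y traces: distances, inner-zone
  time/distance with exact boundary-crossing splits, arm entries with a
  debounce, ID%/IT%/OT%/OE%.
* **`rataffect.stats`** — one-way ANOVA, Student–Newman–Keuls post-hoc
  (studentized-range quantiles computed numerically), Student's
  t-tests, and the depression–anxiety Pearson correlation.
* **`rataffect.synthetic`** — deterministic synthetic cohorts
  (4 groups × 21 days) with configurable per-endpoint effects, drinking
  and von Frey emission models, and trajectory generators.
* **`rataffect.pipeline`** / CLI — strict delimited-text I/O, config
  hashing, and orchestration of simulate → metrics → score → stats →
  report.

## CLI

```bash
# simulate a cohort with the built-in effect design and analyse it
rataffect simulate --effect-sd 1.5 --seed 1 --out runs/demo

# or run the stages separately
rataffect metrics --records runs/demo/records.csv \
    --trajectories runs/demo/trajectories --out runs/demo/indices.csv
rataffect score  --indices runs/demo/indices.csv --out runs/demo/cards.csv
rataffect stats  --indices runs/demo/indices.csv \
    --scorecards runs/demo/cards.csv --out runs/demo/stats

# inspect the scale tables (conflicts are reported, not repaired)
rataffect validate-scales
```

A full run can also be driven from a YAML config (`rataffect report
--config run.yaml`); every output file carries a hash of the effective
configuration, including the scale-table contents.

Exit codes: 0 success, 2 validation failure, 3 I/O failure.

## File formats

* Records: CSV, one row per rat × day
  (`rat_id,group,day,weight_g,sucrose_g,water_g,rearing_count,of_trajectory,epm_trajectory,von_frey_forces,von_frey_responses`);
  von Frey series are `;`-separated parallel lists.
* Trajectories: one CSV per trial with header `time_s,x_cm,y_cm`.
* Scale tables: YAML (`items: {name: {max_points, domain, bins}}`),
  bins lower-closed/upper-open unless flagged.

## Scoring conventions worth knowing

* Raw values are binned at full precision (94.999% preference scores 9,
  not 10).
* Weight extremes (<300 g, >390 g) score 1 by the printed table
  (default) or 0 by the narrative rule (`--weight-mode prose`).
* An undefined OE% (rat never entered an arm) scores 0 with a flag by
  default (maximal avoidance); configurable to "missing".

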