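# thermoclean

Artifact filtering and agreement evaluation for automated intraoperative
temperature traces.

Automated temperature probes produce artifacts — probe fall-out dips,
warm-up ramps after (re)insertion, implausible readings after recording
gaps. `thermoclean` implements two filtering algorithms plus the full
evaluation methodology used to validate them, and a seeded synthetic-trace
generator so everything is testable without patient data.

## What's inside

| Module | Purpose |
| --- | --- |
| `thermoclean.trace_model` | Domain types (`TemperatureTrace`, `LabelVector`, `FilterConfig`), CSV readers/writers, eligibility validation (≥3 readings). |
| `thermoclean.artifact_filters` | Plausibility bounds ((32, 40) °C, strict) plus the **slope** algorithm (3-point OLS windows, slope > 0.08 °C/min confirmed by a jump > 0.25 °C) and the **interval** algorithm (gaps > 5 min: short post-gap segments discarded, long ones bridge-tested at 0.35 °C/min). |
| `thermoclean.hypothermia_metrics` | Per-case mean temperature and hypothermia burden (trapezoidal area below 36 °C in minutes×°C) after artifact removal. |
| `thermoclean.agreement_stats` | Majority-rule consensus, confusion counts and classification metrics, binomial artifact rate, Gwet AC1 with conditional variance, Bland-Altman bias and 95% limits of agreement, artifact clusters, leave-one-out jackknife, and limits-of-agreement sample-size planning. |
| `thermoclean.synthetic_traces` | Seeded generator of anesthesia-typical traces (decline → plateau → rewarm, log-normal reading counts, median ≈103) with truth-labeled injected artifacts at a configurable rate (default 1%). |
| `thermoclean.cli` | `thermoclean` command with `simulate`, `filter`, `summarize`, `evaluate`, `samplesize` subcommands. |

## CLI

```bash
# generate a labeled synthetic cohort (one CSV per case + truth.csv + manifest.json)
thermoclean simulate --n-cases 50 --seed 1 -o cohort/

# label artifacts (all thresholds overridable by flags or a YAML config)
thermoclean filter --algorithm slope cohort/truth.csv -o labeled.csv
thermoclean filter --algorithm interval --gap-threshold 10 cohort/truth.csv -o labeled2.csv

# per-case summaries after artifact removal
thermoclean summarize labeled.csv --label-column label_slope -o summaries.csv

# compare predictions against a reference adjudication (single column, or
# several rater columns combined by majority rule with Gwet AC1 reported)
thermoclean evaluate labeled.csv --reference cohort/truth.csv -o report.json

# agreement-study sample size (mean difference 0.2, SD 1.02, max allowed 2.56)
thermoclean samplesize --mu 0.2 --sd 1.02 --delta 2.56 --power 0.8
# -> 147
```

Trace files are CSV with a header `case_id,time_min,temperature_c`
(ISO-8601 timestamps accepted in place of minutes); labeled files add
`label` / `label_<name>` columns. Every run serializes its effective
configuration next to its outputs.

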