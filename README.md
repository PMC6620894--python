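# hoverbayes

Analysis pipeline for Bayesian-reasoning experiments in which the task data
(a two-level tree of natural frequencies or percentages) stays hidden until
the participant hovers over it with the mouse. The package covers:

- **Task construction and scoring** (`hoverbayes.bayes`): posterior / positive
  predictive value computation, sequential (bags-and-chips style) updating,
  frequency- and percentage-tree builders, strict-rounding correctness,
  log-relative-error and log-experience-deviation metrics, and answer-strategy
  classification (correct PPV, sensitivity confusion, total-population
  denominator, other).
- **Interaction analysis** (`hoverbayes.interaction`): hover-log parsing over
  the 8 AOI codes (T, F, nF, FA, FnA, nFA, nFnA, Q), participant validity
  filtering, dwell-time percentages, and bigram transition tables over the
  56 ordered AOI pairs.
- **Group inference** (`hoverbayes.group_stats`): Hellinger-distance
  resampling test between groups of transition tables (with-replacement and
  label-permutation modes), odds-ratio screening of discriminative
  transitions with Wald CIs and a max-frequency threshold, chi-squared
  association with Bonferroni adjustment and Cramér's V, and the logistic
  (correctness) and linear (log-error) reporting regressions.
- **Synthetic cohorts** (`hoverbayes.simulate`): reproducible cohort
  generation — condition labels, Beta-distributed reported probability
  triples, strategy-mixture answers, and hover sequences from per-condition
  first-order Markov chains with log-normal dwell durations — so the whole
  pipeline is testable without any deposited data.
- **CLI** (`hoverbayes.cli`): `simulate → analyze → report` with manifests,
  fixed seeds and stable output files.

## CLI

```sh
# generate a synthetic cohort (participants.csv, events.csv, manifest.json)
hoverbayes simulate --seed 7 --n-per-cell 75 --out runs/sim

# score, filter and compare it
hoverbayes analyze --participants runs/sim/participants.csv \
    --events runs/sim/events.csv --out runs/analysis \
    --n-perm 10000 --resample-mode permutation --min-frequency 30 --seed 7

# human-readable summary (no recomputation)
hoverbayes report --results runs/analysis
```

A YAML cohort config (see `hoverbayes.simulate.CohortConfig.to_yaml`) can be
passed with `simulate --config`. Exit codes: 0 success, 2 validation error,
3 degenerate analysis (e.g. every participant excluded). All stochastic
steps use a counter-based (Philox) generator, so a fixed seed reproduces
byte-identical outputs.

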