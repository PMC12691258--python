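# bayestriage

Sequential Bayesian risk stratification for repeated imperfect diagnostic
tests.

A cohort with a known disease prevalence is split by the outcome of a cheap,
imperfect test (e.g. a faecal immunochemical test); each subcohort receives
an exactly-deduced, Bayes-updated prevalence and the procedure recurses.
Aggregating the resulting expectation tree by outcome profile (k positives
out of n tests, with binomial multiplicity) stratifies risk sharply after a
handful of rounds, so that scarce confirmatory procedures (colonoscopies)
can be prioritised for the few profiles whose posterior is high. The
package adds tier assignment, waiting-list and cost accounting, calibration
from observed confusion tables or stratum indicators, and a patient-level
Monte-Carlo oracle that validates the analytic expectations.

All internal arithmetic keeps full precision: prevalences are plain
probabilities in doubles, calibration uses exact rationals, money uses exact
decimals, and display rounding is a pure presentation layer.

## Modules

| Module                         | Responsibility |
| ------------------------------ | -------------- |
| `bayestriage.core_bayes`       | One-test machinery: rate derivation, single cohort split, closed-form posterior after any (k positives, j negatives) profile |
| `bayestriage.cohort_tree`      | Recursive expansion, profile aggregation with a dual-route (tree vs closed-form) consistency check, posterior trajectories, depth-wise counts |
| `bayestriage.stratification`   | Urgent / retest / defer tiers, integer headcounts under both floor and nearest policies, waiting-list reduction |
| `bayestriage.cost_model`       | Exact-decimal protocol costs vs full confirmatory screening |
| `bayestriage.calibration`      | Prevalence/sensitivity/specificity (plus PPV, NPV, LR±) from confusion tables; stratum-indicator rates in both conventions |
| `bayestriage.cohort_simulator` | Seeded patient-level Monte-Carlo oracle with per-profile z-scores |
| `bayestriage.cli_io`           | Config (JSON/YAML + flags), table rendering, lossless CSV/JSON, the `bayestriage` CLI |

## Command line

```bash
# full report: aggregated profiles, tiers, costs, trajectories (JSON)
bayestriage run --cohort-size 100000 --prevalence 19.6 --prevalence-unit per100k \
    --sensitivity 0.73 --specificity 0.94 --depth 4

# the same from a config file, flags override
bayestriage run --config run.yaml --depth 4 --format csv --out rows.csv

# posterior trajectory at a fixed number of negative results
bayestriage traject --prevalence 0.0334158 --sensitivity 0.962963 \
    --specificity 0.672215 --negatives 1 --max-tests 6

# calibrate from a confusion table, or from a stratum indicator
bayestriage calibrate --tp 26 --fp 256 --tn 525 --fn 1
bayestriage calibrate --cohort-size 1000 --cohort-sick 100 \
    --stratum-size 400 --stratum-sick 60

# protocol cost vs full screening
bayestriage cost --cohort-size 100000 --urgent 96 --rounds 4

# Monte-Carlo check of the analytic expectations
bayestriage simulate --n-patients 100000 --prevalence 0.03 \
    --sensitivity 0.96 --specificity 0.67 --rounds 4 --seed 7
```

Prevalence units are always explicit (`prob`, `percent`, `per100k`), never
inferred from magnitude. Exit codes: 0 ok, 1 validation problem, 2 internal
error.

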