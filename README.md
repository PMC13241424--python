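# screenbias

Monte-Carlo simulation of how **eligibility criteria bias treatment-effect
estimates in screened randomized controlled trials**.

School-based Tier 2 reading-intervention RCTs rarely enroll every screened
student. Instead, research teams apply an eligibility rule to screening
(pretest) scores — "at or below the 40th percentile", "at or below the
25th percentile", "the 4 lowest scorers per classroom" — and randomize
only the eligible students. Because these rules select directly on a model
covariate, they truncate its range and change the sample the effect is
estimated in. `screenbias` asks: holding the population and the true
effect fixed, how much do these selection rules alone distort the
estimated intervention effect, its precision, and model fit?

The package is aimed at intervention researchers and methodologists who
want to reproduce, probe, or extend this style of selection-bias
simulation.

## The model

Each replication simulates a screening sample of *n* = 5,000 students
(250 classrooms × 20) with jointly normal z-scored variables

- corr(pretest, posttest) = 0.6, corr(age, pretest) = corr(age, posttest) = 0.2,
- zero intraclass correlation by construction,

randomizes exactly half the students to treatment at the child level, and
adds an independent per-student effect draw δᵢ ~ N(0.3, 1²) to treated
posttests. Three eligibility rules then flag subsamples, and within the
full sample and each subsample the ANCOVA-style OLS model

    posttest = β₀ + β₁·condition + β₂·age + β₃·pretest + ε

is fit. β̂₁ is the standardized intervention effect; per subsample the
**percent bias** is 100·(β̂₁ − β̂₁ᶠᵘˡˡ)/β̂₁ᶠᵘˡˡ, taking the same
replication's full-sample estimate as the "true" effect. The study runs
500 independent replications and reports means, SDs, and ranges of the
estimate, its SE, percent bias, and R² per sample definition, plus
skewness and u-ratio (restriction-ratio) diagnostics of the selected
pretest distributions.

## Worked example

```python
from screenbias import SimulationConfig, run_study, render_summary_tables

result = run_study(SimulationConfig(master_seed=1))   # 500 replications, ~15 s
means, dispersion = render_summary_tables(result.summary)
print(means)
print(dispersion)
```

prints

```
                          full     method_1     method_2     method_3
Intervention (SE)  0.30 (0.03)  0.30 (0.05)  0.30 (0.06)  0.30 (0.07)
% Bias                       -           0%           1%           1%
r-squared                 0.26         0.11         0.09         0.11

                               full          method_1          method_2          method_3
Intervention (SD)  0.21–0.39 (0.03)  0.17–0.43 (0.05)  0.09–0.48 (0.06)  0.07–0.49 (0.06)
% Bias (SD)                       -  -35% – 46% (13%)  -62% – 49% (18%)  -68% – 52% (19%)
r-squared          0.23–0.29 (0.01)  0.07–0.15 (0.01)  0.06–0.14 (0.02)  0.06–0.17 (0.02)
```

Reading the output: every selection rule recovers the true effect *on
average* (mean estimate 0.30, mean bias ≈ 0%), but any *single* study
using these criteria can mis-estimate the effect by ±40–70% — the
dispersion, not the mean, is the problem. Selection also roughly doubles
the standard error (smaller n) and halves-to-thirds the variance
explained (restriction of range on pretest: R² drops from 0.26 to
0.09–0.11).

The same study is available from the shell:

```bash
screenbias run --config study.yaml --out study_out/      # replications + tables
screenbias tables --in study_out/                        # re-render summaries
screenbias export-dist --seed 1 --out dist_out/          # raincloud-ready CSV
```

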