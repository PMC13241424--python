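# Methods

## Generative model

Students are i.i.d. draws from a trivariate normal over (age, pretest,
posttest) with zero means, unit variances, and correlation matrix

```
          age  pretest  posttest
age       1.0    0.2      0.2
pretest   0.2    1.0      0.6
posttest  0.2    0.6      1.0
```

so every variable is a z-score. The matrix is validated for positive
semi-definiteness at configuration time (eigenvalue check, tolerance
1e-12) and sampled via Cholesky factorization. Classrooms are contiguous
blocks of `class_size` students by index: because rows are exchangeable,
any classroom assignment is distributionally equivalent, and blocks are
the simplest reproducible choice. The intraclass correlation is therefore
exactly zero; `SimulationConfig.icc` exists as a reserved hook and
rejects nonzero values rather than silently ignoring them.

Condition assignment is an exact half split at the child level (a uniform
random permutation), ignoring classrooms. The treatment effect is
heterogeneous: an independent draw δᵢ ~ N(effect_mean, effect_sd²) —
default N(0.3, 1) — is generated for *every* student but added only to
treated posttests, so realized effects do not depend on treated-row
ordering. Pretest and age are never modified; the configured correlations
describe the *pre-injection* posttest, and injection deliberately
perturbs them.

## Eligibility criteria

- `percentile_at_or_below(p)` — flags pretest ≤ the p-th quantile.
  With `basis="sample"` (default) the cutoff is the empirical sample
  quantile computed by linear interpolation between order statistics
  (numpy's default definition; recorded in run metadata because boundary
  counts depend on it). With continuous data this flags exactly
  `floor((n−1)p/100 + 1)` students — 2000 and 1250 at n = 5000 for
  p = 40 and 25. `basis="population"` uses the standard-normal quantile
  instead, the natural reading of a population-based screener; for
  z-scored data the two nearly coincide, and the default follows the
  sample convention.
- `lowest_k_per_classroom(k)` — flags the k smallest pretest scores in
  each classroom, always k × n_classrooms students in total (1000 at
  k = 4). Ties are broken by ascending student id; with continuous scores
  ties are measure-zero, but determinism requires a rule.

"At or below" is inclusive. Selection depends only on pretest (and
classroom membership), never on condition or posttest — a property the
test suite asserts by permuting posttest and re-flagging.

## Outcome model and extracted quantities

Within the full sample and each flagged subsample, posttest is regressed
by OLS on an intercept, a 0/1 treatment indicator, age, and pretest.
Extracted per fit: the condition coefficient (the standardized effect
estimate), its conventional homoskedastic SE, and the ordinary R².
Homoskedastic SEs are a deliberate fidelity choice: effect heterogeneity
makes treated posttest variance larger than control (2.0 vs 1.0 at the
defaults), but the plain-regression convention is what this literature
reports, and with balanced arms the nominal SE is close to the sampling
SD anyway. Constant design columns raise a `SingularDesignError` naming
the offending predictor.

**Percent bias** is 100·(estimate − reference)/reference, positive =
overestimation; the opposite sign convention is available as an option
(`reference_minus_estimate`), since both appear in the literature and
only the sign differs. The **reference ("true") effect is the same
replication's full-sample estimate**, not the generative mean 0.3: this
isolates the selection effect from sampling error shared with the full
sample (the generative value remains available for diagnostics, e.g. the
unbiasedness test against d = 0.3). The **u-ratio** is returned as
selected-sample SD over full-sample SD (< 1 under truncation); the
reciprocal convention is obtained by swapping arguments.

## Analytic oracle

`expected_full_sample_moments` gives closed-form full-sample
expectations used as an independent check on the Monte Carlo: with
b = (r_age_post, r_pre_post) and Σxx the covariate correlation matrix,
the conditional posttest variance is 1 − b′Σxx⁻¹b = 0.6333 at the
defaults; pooled residual variance adds effect_sd²/2 (half the sample is
treated) giving 1.1333; SE(condition) = √(4·residual/n) = 0.0301 at
n = 5000; total variance 1 + effect_sd²/2 + effect_mean²/4 = 1.5225
yields R² = 0.2556. The 500-replication means agree with these within
3 Monte-Carlo standard errors.

## Monte-Carlo design and seeding

The study runs `n_reps = 500` sequential replications. A master seed
feeds a `numpy.random.SeedSequence`; its i-th spawned child seeds
replication i, and each child spawns three grandchildren for the
population draw, condition assignment, and effect draws. Replications
are therefore mutually independent, individually re-runnable
(`run_replication(config, i)` reconstructs child i), and identical under
any execution order. Aggregation reports mean, sample SD (n−1
denominator), min, and max per quantity per sample definition;
percent-bias dispersion is in percentage points.

The exploratory power analysis is the standard two-sided two-sample
t-test computation via the noncentral-t distribution with noncentrality
d·√(n/4) at total sample size n (balanced arms), cross-checked in the
tests against direct simulation of t-tests. It confirms that at d = 0.3
and α = 0.05, power exceeds 0.80 from roughly n = 600 onward, so all
eligible-sample sizes (1000–2000) are comfortably powered and power
differences cannot explain between-method differences. Covariate-adjusted
power is out of scope.

## Reporting

`render_summary_tables` renders a means table (estimate with mean SE,
mean % bias, mean R²) and a dispersion table (min–max with SD) with
columns ordered full sample then criteria. Values round half-to-even at
2 decimals (whole percents for bias), making "0.30" comparisons
well-defined. `export_distributions` emits long-format
(sample_name, student_id, pretest) records plus per-sample skewness —
the moment-based g1 = m3/m2^{3/2} with population-moment denominators
(the adjusted G1 is an option) — for external raincloud/density
plotting. Rendering and export never mutate their inputs. Plot rendering
itself is intentionally out of scope; the data exports are the tested
artifact.

## What the simulation does and does not emulate

The generator reproduces the idealized study conditions: perfectly
multivariate-normal scores, exactly equal classrooms, zero ICC, and a
homogeneous-on-average effect that is independent of pretest. Passing
tests therefore demonstrate properties of *selection rules under ideal
assumptions*, not of real screening data, where skewed/kurtotic score
distributions, nonzero ICC, and pretest-moderated (compensatory) effects
are the norm. Those extensions are deliberately unimplemented (the ICC
field is a guarded hook); under them, selection effects are expected to
be larger, so the results here are best read as a lower bound on the
problem.

Single-iteration diagnostics deserve one caveat: the skewness of a
selected pretest sample is itself a random variable (per-draw SD ≈
0.07–0.11 at n = 5000; expectations ≈ −1.08 / −1.22 / −0.73 for the
three default criteria by truncated-normal theory). Published
single-iteration values scatter around those expectations, so the test
suite compares the mean over a fixed seed set at the single-draw
tolerance rather than freezing one lucky or unlucky draw.

## Problem sizes

All defaults are the study's own: n = 5000, 500 replications. A full
study is ~15 s on one core; the test suite (which runs one full study
plus property tests) completes in well under a minute.
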