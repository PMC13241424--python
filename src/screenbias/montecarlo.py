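"""Monte-Carlo orchestration of the selection-bias study.

One replication simulates a fresh screening sample, randomizes and injects
the treatment effect, applies the eligibility criteria, and fits the
outcome model on the full sample and each eligible subsample.  The study
repeats this ``n_reps`` times (500 by default) on mutually independent
seed streams and summarizes central tendency and dispersion of the effect
estimate, its standard error, percent bias, and R² per sample definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import SimulationConfig
from .eligibility import EligibilityCriterion, apply_criteria, default_criteria, sample_skewness
from .estimation import FULL_SAMPLE, ModelFit, fit_outcome_model, percent_bias, true_effect_reference
from .population import assign_conditions, inject_treatment_effect, simulate_population

#: long-format per-replication metric columns, also the CSV header
REPLICATION_COLUMNS = [
    "replication", "sample_name", "n", "estimate", "se",
    "r_squared", "percent_bias", "pretest_skewness",
]


@dataclass(frozen=True)
class ReplicationResult:
    """Everything extracted from one pipeline pass."""

    replication_index: int
    seed_record: tuple
    fits: Mapping[str, ModelFit]
    eligible_counts: Mapping[str, int]
    percent_biases: Mapping[str, float]
    pretest_skewness: Mapping[str, float]

    @property
    def sample_names(self) -> tuple[str, ...]:
        return tuple(self.fits)


@dataclass(frozen=True)
class StudySummary:
    """Across-replication aggregates, one row per sample definition.

    ``table`` is indexed by sample name with columns
    ``{estimate,pct_bias,r2}_{mean,sd,min,max}``, ``se_mean`` and
    ``n_mean``; full-sample percent-bias entries are NaN (bias is defined
    against the full sample itself).
    """

    table: pd.DataFrame
    n_reps: int

    @property
    def sample_names(self) -> list[str]:
        return list(self.table.index)


@dataclass(frozen=True)
class StudyResult:
    summary: StudySummary
    replications: pd.DataFrame
    config: SimulationConfig
    criteria: tuple[EligibilityCriterion, ...]


def _child_seed(master_seed: int, replication_index: int) -> np.random.SeedSequence:
    """Replication ``i``'s seed: child ``i`` of the master SeedSequence."""
    return np.random.SeedSequence(master_seed).spawn(replication_index + 1)[-1]


def run_replication(
    config: SimulationConfig,
    replication_index: int,
    criteria: Sequence[EligibilityCriterion] | None = None,
    child_seed: np.random.SeedSequence | None = None,
) -> ReplicationResult:
    """One full pipeline pass, deterministic given (master_seed, index).

    The replication's seed stream spawns independent grandchildren for the
    population draw, condition assignment, and effect draws, so each stage
    is individually re-runnable.
    """
    if criteria is None:
        criteria = default_criteria()
    if child_seed is None:
        child_seed = _child_seed(config.master_seed, replication_index)
    pop_seed, assign_seed, effect_seed = child_seed.spawn(3)

    table = simulate_population(config, pop_seed)
    table = assign_conditions(table, assign_seed)
    table = inject_treatment_effect(
        table, config.effect_mean, config.effect_sd, effect_seed
    )
    table = apply_criteria(table, criteria)

    fits: dict[str, ModelFit] = {}
    counts: dict[str, int] = {}
    skew: dict[str, float] = {}
    try:
        fits[FULL_SAMPLE] = fit_outcome_model(table, "all")
        skew[FULL_SAMPLE] = sample_skewness(table["pretest"])
        for crit in criteria:
            fits[crit.name] = fit_outcome_model(table, crit.flag_column)
            counts[crit.name] = int(table[crit.flag_column].sum())
            skew[crit.name] = sample_skewness(
                table.loc[table[crit.flag_column], "pretest"]
            )
    except ValueError as err:
        raise RuntimeError(
            f"replication {replication_index} (seed {child_seed.entropy}, "
            f"spawn_key {child_seed.spawn_key}) failed: {err}"
        ) from err

    reference = true_effect_reference(fits)
    biases = {
        crit.name: percent_bias(fits[crit.name].effect_estimate, reference)
        for crit in criteria
    }
    return ReplicationResult(
        replication_index=replication_index,
        seed_record=(child_seed.entropy, child_seed.spawn_key),
        fits=fits,
        eligible_counts=counts,
        percent_biases=biases,
        pretest_skewness=skew,
    )


def results_to_frame(results: Sequence[ReplicationResult]) -> pd.DataFrame:
    """Long-format per-replication metric table."""
    rows = []
    for res in results:
        for name, fit in res.fits.items():
            rows.append(
                {
                    "replication": res.replication_index,
                    "sample_name": name,
                    "n": fit.n,
                    "estimate": fit.effect_estimate,
                    "se": fit.effect_se,
                    "r_squared": fit.r_squared,
                    "percent_bias": res.percent_biases.get(name, np.nan),
                    "pretest_skewness": res.pretest_skewness.get(name, np.nan),
                }
            )
    return pd.DataFrame(rows, columns=REPLICATION_COLUMNS)


def summarize_frame(
    frame: pd.DataFrame, sample_order: Sequence[str] | None = None
) -> StudySummary:
    """Build a :class:`StudySummary` from a long-format replication table."""
    names = (
        list(sample_order)
        if sample_order is not None
        else list(frame["sample_name"].unique())
    )
    n_reps = frame["replication"].nunique()
    rows = {}
    for name in names:
        sub = frame[frame["sample_name"] == name]
        row = {"n_mean": sub["n"].mean(), "se_mean": sub["se"].mean()}
        for prefix, col in (
            ("estimate", "estimate"), ("pct_bias", "percent_bias"), ("r2", "r_squared"),
        ):
            row[f"{prefix}_mean"] = sub[col].mean()
            row[f"{prefix}_sd"] = sub[col].std(ddof=1)
            row[f"{prefix}_min"] = sub[col].min()
            row[f"{prefix}_max"] = sub[col].max()
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index").loc[names]
    return StudySummary(table=table, n_reps=n_reps)


def aggregate(results: Sequence[ReplicationResult]) -> StudySummary:
    """Mean, sample SD (n−1 denominator), min and max per quantity per sample.

    All results must share the same sample configuration; percent-bias
    dispersion is reported in percentage points.
    """
    if len(results) < 2:
        raise ValueError("aggregation needs at least 2 replications")
    names = results[0].sample_names
    if any(r.sample_names != names for r in results[1:]):
        raise ValueError("replications have heterogeneous sample configurations")
    return summarize_frame(results_to_frame(results), sample_order=list(names))


def run_study(
    config: SimulationConfig,
    criteria: Sequence[EligibilityCriterion] | None = None,
) -> StudyResult:
    """Run all replications sequentially on independent child streams."""
    if config.n_reps < 2:
        raise ValueError("a study needs at least 2 replications")
    if criteria is None:
        criteria = default_criteria()
    children = np.random.SeedSequence(config.master_seed).spawn(config.n_reps)
    results = [
        run_replication(config, i, criteria, child_seed=children[i])
        for i in range(config.n_reps)
    ]
    return StudyResult(
        summary=aggregate(results),
        replications=results_to_frame(results),
        config=config,
        criteria=tuple(criteria),
    )


def power_curve(effect: float, alpha: float, n_grid: Sequence[int]) -> np.ndarray:
    """Two-sided two-sample t-test power at each total sample size.

    Balanced arms (n/2 each); power comes from the noncentral-t
    distribution with noncentrality ``d·sqrt(n/4)``.  Monotone
    nondecreasing in n; at ``effect=0`` power equals alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if effect < 0:
        raise ValueError("effect must be non-negative")
    power = []
    for n in n_grid:
        if n < 4:
            raise ValueError("total n must be at least 4")
        df = n - 2
        ncp = effect * np.sqrt(n / 4.0)
        tcrit = sps.t.ppf(1 - alpha / 2, df)
        power.append(
            1 - sps.nct.cdf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
        )
    return np.asarray(power)
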