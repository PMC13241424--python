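"""Synthetic student population: the study's data-generating process.

A screening sample of ``n_students`` is drawn from a trivariate normal over
(age, pretest, posttest) with unit variances and the configured pairwise
correlations, so all variables are z-scores.  Students are laid out in
contiguous classroom blocks (independence across students means classroom
membership carries no information: the intraclass correlation is zero by
construction).  Half the students are then randomized to treatment at the
child level, and each treated student's posttest is shifted by an
independent Normal(effect_mean, effect_sd^2) draw.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig

CONTROL = "control"
TREATMENT = "treatment"

#: canonical column order for CSV round-trips; eligibility flags follow
BASE_COLUMNS = ["student_id", "classroom_id", "age", "pretest", "posttest", "condition"]

SeedLike = "int | np.random.SeedSequence | np.random.Generator"


def build_correlation_matrix(config: SimulationConfig) -> np.ndarray:
    """Correlation matrix over (age, pretest, posttest).

    Unit diagonal, symmetric, off-diagonals equal the configured
    correlations.  Raises :class:`ConfigurationError` naming the offending
    correlations if the matrix is not positive semi-definite (the config
    constructor enforces the same check, so this can only trip on a
    hand-built config that bypassed validation).
    """
    corr = config.correlation_matrix()
    eigvals = np.linalg.eigvalsh(corr)
    if eigvals.min() < -1e-12:
        raise ConfigurationError(
            f"correlations (r_pre_post={config.r_pre_post}, "
            f"r_age_pre={config.r_age_pre}, r_age_post={config.r_age_post}) "
            f"do not form a positive-semi-definite matrix"
        )
    return corr


def simulate_population(config: SimulationConfig, seed) -> pd.DataFrame:
    """Draw one screening sample; no conditions assigned yet.

    Rows are i.i.d. draws from the zero-mean multivariate normal with the
    built correlation matrix; ``classroom_id`` is assigned in contiguous
    blocks of ``class_size`` (1-based), which is distributionally
    equivalent to any other assignment because rows are exchangeable.
    """
    rng = np.random.default_rng(seed)
    corr = build_correlation_matrix(config)
    draws = rng.multivariate_normal(
        mean=np.zeros(3), cov=corr, size=config.n_students, method="cholesky"
    )
    classroom = np.repeat(
        np.arange(1, config.n_classrooms + 1), config.class_size
    )
    return pd.DataFrame(
        {
            "student_id": np.arange(config.n_students),
            "classroom_id": classroom,
            "age": draws[:, 0],
            "pretest": draws[:, 1],
            "posttest": draws[:, 2],
        }
    )


def assign_conditions(table: pd.DataFrame, seed) -> pd.DataFrame:
    """Randomize students to control/treatment in an exact half split.

    Assignment is at the child level: a uniformly random permutation of the
    rows sends the first half to treatment, ignoring classroom membership.
    Raises ``ValueError`` on an odd row count.
    """
    n = len(table)
    if n % 2 != 0:
        raise ValueError(f"cannot split {n} students exactly in half")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    condition = np.full(n, CONTROL, dtype=object)
    condition[perm[: n // 2]] = TREATMENT
    out = table.copy()
    out["condition"] = condition
    return out


def inject_treatment_effect(
    table: pd.DataFrame, effect_mean: float, effect_sd: float, seed
) -> pd.DataFrame:
    """Add a per-student Normal(effect_mean, effect_sd^2) draw to treated posttests.

    An effect draw is generated for every student but applied only to
    treated rows, so the realized effects do not depend on how treated rows
    are ordered.  Control posttests, pretests and ages are bit-identical to
    their input values.
    """
    if effect_sd < 0:
        raise ValueError("effect_sd must be non-negative")
    if "condition" not in table.columns:
        raise ValueError("conditions must be assigned before effect injection")
    rng = np.random.default_rng(seed)
    effects = rng.normal(effect_mean, effect_sd, size=len(table))
    treated = (table["condition"] == TREATMENT).to_numpy()
    out = table.copy()
    out["posttest"] = np.where(
        treated, table["posttest"].to_numpy() + effects, table["posttest"].to_numpy()
    )
    return out


def write_csv(table: pd.DataFrame, path) -> None:
    """Write a student table with the fixed column order (flags last)."""
    flags = [c for c in table.columns if c.startswith("eligible_")]
    cols = [c for c in BASE_COLUMNS if c in table.columns] + flags
    table[cols].to_csv(path, index=False)


def read_csv(path) -> pd.DataFrame:
    """Re-read a student table written by :func:`write_csv`."""
    table = pd.read_csv(path)
    for col in table.columns:
        if col.startswith("eligible_"):
            table[col] = table[col].astype(bool)
    return table
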