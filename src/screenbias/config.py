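"""Study configuration.

All generative parameters of the simulated screening study live in
:class:`SimulationConfig`.  The defaults are the study conditions: 5,000
students in 250 classrooms of 20, variables expressed as z-scores with
corr(pretest, posttest) = 0.6 and corr(age, pretest) = corr(age, posttest)
= 0.2, a heterogeneous treatment effect drawn per student from
Normal(0.3, 1), and 500 Monte-Carlo replications.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generative and study parameters for one simulation study.

    Parameters
    ----------
    n_students
        Total screening-sample size. Must equal ``n_classrooms * class_size``
        and be even (condition assignment is exactly balanced).
    n_classrooms, class_size
        Classroom layout; every classroom has exactly ``class_size`` students.
    r_pre_post, r_age_pre, r_age_post
        Pairwise correlations of the jointly normal z-scored variables
        (age, pretest, posttest) before effect injection.
    effect_mean, effect_sd
        Mean and SD of the per-student treatment-effect draws added to
        treated posttests (standardized units).
    n_reps
        Number of Monte-Carlo replications.
    master_seed
        Root of the seed tree; every replication derives independent
        streams from it.
    icc
        Intraclass correlation of classrooms. Reserved hook: only 0.0
        (independent students) is implemented.
    """

    n_students: int = 5000
    n_classrooms: int = 250
    class_size: int = 20
    r_pre_post: float = 0.6
    r_age_pre: float = 0.2
    r_age_post: float = 0.2
    effect_mean: float = 0.3
    effect_sd: float = 1.0
    n_reps: int = 500
    master_seed: int = 0
    icc: float = 0.0

    def __post_init__(self) -> None:
        if self.n_classrooms * self.class_size != self.n_students:
            raise ConfigurationError(
                f"n_classrooms ({self.n_classrooms}) x class_size "
                f"({self.class_size}) != n_students ({self.n_students})"
            )
        if self.n_students % 2 != 0:
            raise ConfigurationError(
                "n_students must be even for exactly balanced assignment"
            )
        for name in ("r_pre_post", "r_age_pre", "r_age_post"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ConfigurationError(f"{name}={r} outside [-1, 1]")
        if self.effect_sd < 0:
            raise ConfigurationError("effect_sd must be non-negative")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be positive")
        if self.icc != 0.0:
            raise ConfigurationError(
                "nonzero intraclass correlation is a reserved hook, "
                "not implemented"
            )
        # fail fast on a non-PSD correlation matrix
        eigvals = np.linalg.eigvalsh(self.correlation_matrix())
        if eigvals.min() < -1e-12:
            raise ConfigurationError(
                "correlations (r_pre_post={}, r_age_pre={}, r_age_post={}) "
                "imply a non-positive-semi-definite correlation matrix "
                "(min eigenvalue {:.4g})".format(
                    self.r_pre_post, self.r_age_pre, self.r_age_post,
                    eigvals.min(),
                )
            )

    def correlation_matrix(self) -> np.ndarray:
        """3x3 correlation matrix over (age, pretest, posttest)."""
        return np.array(
            [
                [1.0, self.r_age_pre, self.r_age_post],
                [self.r_age_pre, 1.0, self.r_pre_post],
                [self.r_age_post, self.r_pre_post, 1.0],
            ]
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        """Load from a YAML file; missing fields take the study defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw.get("simulation", raw))
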